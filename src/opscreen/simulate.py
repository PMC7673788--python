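"""Synthetic colony-screen generator with a planted ground truth.

Generates complete screens — 1536-format plates, an array key, optional
two-channel fluorescence and a truth table — with the statistical
structure the analysis assumes: four adjacent colonies per strain in a
2x2 pinning block, duplicate experiments, two media conditions, an
overproduction-construct panel, planted interaction effects added to
baseline fitness (W_AB = W_A + epsilon, matching the additive form of
the score when the query fitness is fixed at 1), linear row/column
gradients plus a radial bowl, an edge growth advantage on the outer two
rows/columns, multiplicative log-normal colony noise, marker-pathway
strains with carryover-level growth, and planted expression-level shifts
in the GFP channel.  The outer border (and any unused block) is filled
with control colonies, as on real SGA arrays.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CONDITIONS,
    CONSTRUCTS,
    DEFAULT_PLATE_FORMAT,
    ArrayKey,
    PlateGrid,
    ScreenError,
)
from .normalization import EDGE_DEPTH, edge_mask

CONTROL_STRAIN = "control"


@dataclasses.dataclass
class SimConfig:
    """Study-design parameters of a synthetic screen."""

    n_strains: int = 308
    plate_format: tuple[int, int] = DEFAULT_PLATE_FORMAT
    colonies_per_strain: int = 4          # one 2x2 pinning block
    experiment_replicates: int = 2
    conditions: tuple[str, ...] = CONDITIONS
    constructs: tuple[str, ...] = CONSTRUCTS
    baseline_mean: float = 1.0
    baseline_sd: float = 0.0
    #: (strain_id, construct, condition, epsilon) planted on normalized fitness
    planted_interactions: list[tuple[str, str, str, float]] = dataclasses.field(
        default_factory=list)
    #: (strain_id, multiplicative GFP expression factor)
    planted_expression: list[tuple[str, float]] = dataclasses.field(
        default_factory=list)
    #: (strain_id, additive W shift under -Leu/Ura, all constructs)
    condition_shifts: list[tuple[str, float]] = dataclasses.field(
        default_factory=list)
    gradient: tuple[float, float, float] = (0.0, 0.0, 0.0)  # row, col, radial
    edge_factor: float = 1.0
    noise_sd: float = 0.0                 # log-scale multiplicative sd
    marker_strains: list[str] = dataclasses.field(default_factory=list)
    marker_carryover_range: tuple[float, float] = (0.08, 0.35)
    marker_op_boost: float = 0.25         # carryover artifact on op plates
    ts_fraction: float = 0.0              # fraction flagged temperature-sensitive
    dropout_rate: float = 0.0
    pixel_scale: float = 500.0
    fluor_gain488: float = 1000.0
    fluor_gain532: float = 800.0
    fluor_gain_sd: float = 0.3            # per-plate log-scale gain spread
    fluor_noise_sd: float = 0.0
    background_expression: float = 0.01   # GFP channel on vector plates
    seed: int = 0

    def __post_init__(self) -> None:
        if "vector" not in self.constructs:
            raise ScreenError("constructs must include the vector control")
        for _, construct, _, eps in self.planted_interactions:
            if construct == "vector":
                raise ScreenError("cannot plant interactions on the vector")
            if not (-1.0 < eps < 1.0):
                raise ScreenError(f"planted epsilon {eps} outside (-1, 1)")
        if self.colonies_per_strain != 4:
            raise ScreenError("the pinning layout is fixed at 2x2 blocks")


@dataclasses.dataclass
class SimTruth:
    """Planted ground truth of a simulated screen."""

    strains: pd.DataFrame       # strain_id, gene, allele, flags, w_baseline, g_true
    interactions: pd.DataFrame  # strain_id, construct, condition, eps_true

    def eps_lookup(self) -> dict[tuple[str, str, str], float]:
        return {(s, c, d): e for s, c, d, e in zip(
            self.interactions["strain_id"], self.interactions["construct"],
            self.interactions["condition"], self.interactions["eps_true"])}


def default_strain_ids(n: int) -> list[str]:
    return [f"yfg{i + 1:04d}" for i in range(n)]


def _interior_blocks(plate_format: tuple[int, int]) -> list[tuple[int, int]]:
    """2x2 block anchors (0-based) fully inside the edge-depth-2 interior."""
    n_rows, n_cols = plate_format
    blocks = []
    for br in range(1, n_rows // 2 - 1):
        for bc in range(1, n_cols // 2 - 1):
            blocks.append((br, bc))
    return blocks


def _all_blocks(plate_format: tuple[int, int]) -> list[tuple[int, int]]:
    n_rows, n_cols = plate_format
    return [(br, bc) for br in range(n_rows // 2) for bc in range(n_cols // 2)]


def strains_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-strain baselines, flags and expression factors."""
    strain_ids = default_strain_ids(config.n_strains)
    n = len(strain_ids)
    base = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    base = np.clip(base, 0.1, None)
    marker_set = set(config.marker_strains)
    unknown = marker_set - set(strain_ids)
    if unknown:
        raise ScreenError(f"marker strains not in the array: {sorted(unknown)}")
    marker_flags = []
    cycle = ("his", "lys", "arg")
    j = 0
    for sid in strain_ids:
        if sid in marker_set:
            marker_flags.append(cycle[j % 3])
            j += 1
        else:
            marker_flags.append("none")
    n_ts = int(round(config.ts_fraction * n))
    essentiality = np.array(["deletion"] * n, dtype=object)
    if n_ts:
        ts_idx = rng.choice(n, size=n_ts, replace=False)
        essentiality[ts_idx] = "temperature_sensitive"
    genes = [sid.upper() for sid in strain_ids]
    alleles = [f"{sid}-ts1" if ess == "temperature_sensitive" else f"{sid}-d"
               for sid, ess in zip(strain_ids, essentiality)]
    # marker strains only show carryover-level growth on the vector
    carry_lo, carry_hi = config.marker_carryover_range
    is_marker = np.array([f != "none" for f in marker_flags])
    base = np.where(is_marker,
                    rng.uniform(carry_lo, carry_hi, size=n), base)
    g_true = np.ones(n)
    planted_g = dict(config.planted_expression)
    for i, sid in enumerate(strain_ids):
        if sid in planted_g:
            g_true[i] = planted_g[sid]
    return pd.DataFrame({
        "strain_id": strain_ids,
        "gene": genes,
        "allele": alleles,
        "marker_flag": marker_flags,
        "essentiality": essentiality,
        "is_control": False,
        "w_baseline": base,
        "g_true": g_true,
    })


def gradient_field(plate_format: tuple[int, int],
                   gradient: tuple[float, float, float],
                   edge_factor: float) -> np.ndarray:
    """Multiplicative spatial artifact field over the plate."""
    n_rows, n_cols = plate_format
    row_slope, col_slope, radial_amp = gradient
    y = (np.arange(n_rows) - (n_rows - 1) / 2) / ((n_rows - 1) / 2)
    x = (np.arange(n_cols) - (n_cols - 1) / 2) / ((n_cols - 1) / 2)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    field = (1.0 + row_slope * yy) * (1.0 + col_slope * xx)
    field *= 1.0 + radial_amp * (xx ** 2 + yy ** 2) / 2.0
    if np.any(field <= 0):
        raise ScreenError("gradient too steep: non-positive field values")
    field = field * np.where(edge_mask(n_rows, n_cols, EDGE_DEPTH),
                             edge_factor, 1.0)
    return field


def _layout_frames(config: SimConfig,
                   strains: pd.DataFrame) -> list[pd.DataFrame]:
    """Assign strains to 2x2 blocks across layout plates.

    Returns one frame per layout plate with 0-based ``row0``/``col0`` and
    the strain metadata of every position; border and unused blocks hold
    control colonies.
    """
    interior = _interior_blocks(config.plate_format)
    per_plate = len(interior)
    n_plates = max(1, math.ceil(len(strains) / per_plate))
    if len(strains) > per_plate * n_plates:
        raise ScreenError("more strains than interior array positions")
    frames = []
    records = strains.to_dict("records")
    for plate_index in range(n_plates):
        chunk = records[plate_index * per_plate:(plate_index + 1) * per_plate]
        rows = []
        assigned = {}
        for block, strain in zip(interior, chunk):
            assigned[block] = strain
        for block_no, (br, bc) in enumerate(_all_blocks(config.plate_format)):
            strain = assigned.get((br, bc))
            if strain is None:
                strain = {
                    "strain_id": CONTROL_STRAIN, "gene": CONTROL_STRAIN,
                    "allele": CONTROL_STRAIN, "marker_flag": "none",
                    "essentiality": "deletion", "is_control": True,
                    "w_baseline": 1.0, "g_true": 1.0,
                }
            for dr in range(2):
                for dc in range(2):
                    rows.append({
                        "row0": 2 * br + dr,
                        "col0": 2 * bc + dc,
                        "block": block_no,
                        **{k: strain[k] for k in (
                            "strain_id", "gene", "allele", "marker_flag",
                            "essentiality", "is_control", "w_baseline",
                            "g_true")},
                    })
        frames.append(pd.DataFrame(rows))
    return frames


def simulate_screen(config: SimConfig) -> tuple[list[PlateGrid], ArrayKey, SimTruth]:
    """Generate plates, array key and ground truth for one screen."""
    rng = np.random.default_rng(config.seed)
    strains = strains_table(config, rng)
    layouts = _layout_frames(config, strains)
    truth_interactions = pd.DataFrame(
        config.planted_interactions,
        columns=["strain_id", "construct", "condition", "eps_true"])
    unknown = set(truth_interactions["strain_id"]) - set(strains["strain_id"])
    if unknown:
        raise ScreenError(f"planted strains not in the array: {sorted(unknown)}")
    truth = SimTruth(strains=strains, interactions=truth_interactions)
    eps = truth.eps_lookup()
    shifts = dict(self_check_shifts(config, strains))

    n_rows, n_cols = config.plate_format
    field = gradient_field(config.plate_format, config.gradient,
                           config.edge_factor)

    plates: list[PlateGrid] = []
    key_frames: list[pd.DataFrame] = []
    reps = [f"rep{i + 1}" for i in range(config.experiment_replicates)]
    for construct in config.constructs:
        for condition in config.conditions:
            for rep in reps:
                for plate_index, layout in enumerate(layouts):
                    plate_id = (f"{construct}__{condition}__{rep}"
                                f"__p{plate_index + 1:02d}")
                    expected = np.zeros((n_rows, n_cols))
                    r0 = layout["row0"].to_numpy()
                    c0 = layout["col0"].to_numpy()
                    w = layout["w_baseline"].to_numpy().astype(float).copy()
                    sid = layout["strain_id"].to_numpy()
                    is_marker = (layout["marker_flag"] != "none").to_numpy()
                    if construct != "vector":
                        w = w + np.array([
                            eps.get((s, construct, condition), 0.0)
                            for s in sid])
                        w = w + np.where(is_marker, config.marker_op_boost, 0.0)
                    if condition == "leu_ura_minus" and shifts:
                        w = w + np.array([shifts.get(s, 0.0) for s in sid])
                    expected[r0, c0] = np.clip(w, 0.0, None)
                    noise = np.exp(rng.normal(0.0, config.noise_sd,
                                              size=(n_rows, n_cols))) \
                        if config.noise_sd > 0 else 1.0
                    size = expected * field * noise * config.pixel_scale
                    present = np.ones((n_rows, n_cols), dtype=bool)
                    if config.dropout_rate > 0:
                        present &= rng.uniform(size=(n_rows, n_cols)) \
                            >= config.dropout_rate
                    size = np.where(present, size, 0.0)
                    plates.append(PlateGrid(
                        plate_id=plate_id, size=size, present=present,
                        construct=construct, condition=condition,
                        experiment_replicate=rep))
                    key = layout.copy()
                    key["plate_id"] = plate_id
                    key["row"] = key.pop("row0") + 1
                    key["col"] = key.pop("col0") + 1
                    key["replicate_group"] = (
                        plate_id + "__b" + key.pop("block").astype(str))
                    key["experiment_replicate"] = rep
                    key_frames.append(key.drop(columns=["w_baseline", "g_true"]))
    key = ArrayKey(pd.concat(key_frames, ignore_index=True))
    return plates, key, truth


def self_check_shifts(config: SimConfig,
                      strains: pd.DataFrame) -> list[tuple[str, float]]:
    unknown = {s for s, _ in config.condition_shifts} - set(strains["strain_id"])
    if unknown:
        raise ScreenError(f"shifted strains not in the array: {sorted(unknown)}")
    return config.condition_shifts


def simulate_fluorescence(config: SimConfig,
                          plates: Sequence[PlateGrid],
                          key: ArrayKey,
                          truth: SimTruth) -> list[PlateGrid]:
    """Attach F488/F532 colony medians to existing plates.

    F532 tracks colony biomass through a per-plate scanner gain; F488 is
    the same signal scaled by the strain's planted expression factor (a
    small constant background on vector plates).  Per-plate gains emulate
    scan-to-scan variation and cancel under plate normalization.
    """
    rng = np.random.default_rng([config.seed, 488532])
    g_by_strain = dict(zip(truth.strains["strain_id"], truth.strains["g_true"]))
    g_by_strain[CONTROL_STRAIN] = 1.0
    out = []
    for plate in plates:
        new = plate.copy()
        sub = key.for_plate(plate.plate_id)
        g_grid = np.ones(new.size.shape)
        g_grid[sub["row"].to_numpy() - 1, sub["col"].to_numpy() - 1] = [
            g_by_strain.get(s, 1.0) for s in sub["strain_id"]]
        if plate.construct == "vector":
            g_grid = np.full(new.size.shape, config.background_expression)
        gain488 = config.fluor_gain488 * float(
            np.exp(rng.normal(0.0, config.fluor_gain_sd)))
        gain532 = config.fluor_gain532 * float(
            np.exp(rng.normal(0.0, config.fluor_gain_sd)))
        shape = new.size.shape
        noise488 = np.exp(rng.normal(0.0, config.fluor_noise_sd, size=shape)) \
            if config.fluor_noise_sd > 0 else 1.0
        noise532 = np.exp(rng.normal(0.0, config.fluor_noise_sd, size=shape)) \
            if config.fluor_noise_sd > 0 else 1.0
        biomass = new.size
        new.f532 = np.where(new.present, biomass * gain532 * noise532, 0.0)
        new.f488 = np.where(new.present, g_grid * biomass * gain488 * noise488,
                            0.0)
        out.append(new)
    return out


def paper_shaped_scenario(seed: int = 0,
                          n_deletion: int = 4323,
                          n_ts: int = 1016,
                          interaction_rate: float = 0.03,
                          shared_hit_fraction: float = 0.2,
                          marker_fraction: float = 0.01,
                          noise_sd: float = 0.05,
                          baseline_sd: float = 0.1) -> SimConfig:
    """A config mimicking the study's screen design.

    ~4,300 deletion-like plus ~1,000 temperature-sensitive-like strains,
    the three overproduction constructs and the vector, both media
    conditions, duplicate experiments.  The planted interaction spectrum
    covers a few percent of strains, is negative-skewed, and is
    correlated — not identical — between conditions (high- and low-copy
    overproduction share mechanism but differ in dose).  A fraction of
    hits is drawn from a pool shared by all three constructs (burden-like
    processes common to every overproduced protein); the rest are
    construct-specific.  Reporter expression varies continuously across
    mutants with a left tail of production-reducing mutants, and marker
    strains show carryover-level growth.  Scale the strain counts down
    for quick runs.
    """
    n = n_deletion + n_ts
    rng = np.random.default_rng([seed, 1915])
    ids = default_strain_ids(n)
    n_hits = int(round(interaction_rate * n))
    n_shared = int(round(shared_hit_fraction * n_hits))

    def _draw_effects(hit_ids):
        signs = rng.uniform(size=len(hit_ids)) < 0.65  # negative skew
        mags = np.clip(np.abs(rng.normal(0.25, 0.1, size=len(hit_ids))),
                       0.05, 0.9)
        return {sid: float(-m if neg else m)
                for sid, neg, m in zip(hit_ids, signs, mags)}

    shared = _draw_effects(rng.choice(ids, size=n_shared, replace=False))
    planted: list[tuple[str, str, str, float]] = []
    for construct in ("GFP", "tGFP", "NES_tGFP"):
        own = _draw_effects(rng.choice(
            sorted(set(ids) - set(shared)), size=n_hits - n_shared,
            replace=False))
        for sid, e in {**shared, **own}.items():
            e_low = float(np.clip(0.7 * e + rng.normal(0.0, 0.06),
                                  -0.95, 0.95))
            planted.append((sid, construct, "leu_ura_minus", e))
            planted.append((sid, construct, "ura_minus", e_low))
    n_markers = int(round(marker_fraction * n))
    markers = sorted(rng.choice(ids, size=n_markers, replace=False))
    # continuous expression spread with a left tail of reduced producers
    g = np.exp(rng.normal(0.0, 0.15, size=n))
    reducers = rng.uniform(size=n) < 0.08
    g[reducers] *= rng.uniform(0.3, 0.7, size=int(reducers.sum()))
    return SimConfig(
        n_strains=n,
        planted_interactions=planted,
        planted_expression=[(s, float(f)) for s, f in zip(ids, g)],
        gradient=(0.15, 0.1, 0.2),
        edge_factor=1.3,
        noise_sd=noise_sd,
        baseline_sd=baseline_sd,
        fluor_noise_sd=0.05,
        marker_strains=markers,
        ts_fraction=n_ts / n,
        dropout_rate=0.002,
        seed=seed,
    )


def simulate_annotations(truth: SimTruth, seed: int,
                         n_terms: int = 40,
                         term_size_range: tuple[int, int] = (5, 40),
                         enriched_in: set[str] | None = None,
                         n_enriched_terms: int = 2) -> "AnnotationSets":
    """Random GMT-style gene sets over the simulated genome.

    Optionally plants ``n_enriched_terms`` terms drawn mostly from
    ``enriched_in`` (gene-level ids) so over-representation is detectable
    downstream.
    """
    from .containers import AnnotationSets

    rng = np.random.default_rng([seed, 60331])
    genes = sorted(set(truth.strains.loc[~truth.strains["is_control"], "gene"]))
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    lo, hi = term_size_range
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        terms[f"SIM:{i + 1:04d}"] = (f"random process {i + 1}",
                                     frozenset(members))
    if enriched_in:
        pool = sorted(set(enriched_in) & set(genes))
        for i in range(n_enriched_terms):
            if len(pool) < 3:
                break
            size = min(len(pool), max(3, int(rng.integers(lo, hi + 1))))
            members = set(rng.choice(pool, size=size, replace=False))
            # mix in a few background genes
            extras = rng.choice(genes, size=max(1, size // 5), replace=False)
            terms[f"SIM:E{i + 1:03d}"] = (
                f"planted enriched process {i + 1}",
                frozenset(members | set(extras)))
    return AnnotationSets(terms)
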
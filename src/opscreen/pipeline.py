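"""End-to-end orchestration: normalize -> score -> call -> classify -> enrich.

One declarative :class:`RunConfig` drives the whole analysis; every
effective value is echoed into the run manifest, and each stage logs its
record counts so filter attrition is auditable.  All outputs are TSV with
deterministic ordering.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ArrayKey, PlateGrid, ScreenError
from . import classify as _classify
from . import enrichment as _enrichment
from . import fluorescence as _fluorescence
from . import io as _io
from . import normalization as _norm
from . import scoring as _scoring
from . import simulate as _simulate

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (caught before any computation)."""


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: str = "opscreen_run"
    # inputs: either file paths or a simulation config
    plate_table: str | None = None
    array_key: str | None = None
    annotations: str | None = None
    simulate: _simulate.SimConfig | None = None
    # thresholds (see the scoring and classification modules)
    eps_symmetric: float = 0.08
    eps_hi: float = 0.16
    eps_lo: float = -0.12
    asymmetric_constructs: tuple[str, ...] = ("tGFP", "NES_tGFP")
    strong_cut: float = 0.2
    strong_condition: str = "leu_ura_minus"
    p_max: float = 0.05
    control_size_cut: float = 0.39
    dead_floor: float = 0.05
    cluster_k: int = 15
    # normalization parameters
    edge_depth: int = 2
    spatial_window: int = 7
    polish_max_iter: int = 20
    polish_tol: float = 1e-9
    # fluorescence measurement set (two colonies, one replicate, -Ura)
    fluorescence_condition: str = "ura_minus"
    fluorescence_replicate: str = "rep1"
    plate_statistic: str = "mean"
    # enrichment
    min_term_size: int = 3
    gene_level: bool = True
    float_precision: int = 6
    seed: int = 0

    def validate(self) -> None:
        for name in ("eps_symmetric", "eps_hi", "strong_cut"):
            value = getattr(self, name)
            if not (0 < value < 1):
                raise ConfigError(f"{name} must lie in (0, 1), got {value}")
        if not (-1 < self.eps_lo < 0):
            raise ConfigError(f"eps_lo must lie in (-1, 0), got {self.eps_lo}")
        if not (0 < self.p_max <= 1):
            raise ConfigError(f"p_max must lie in (0, 1], got {self.p_max}")
        if self.cluster_k < 1:
            raise ConfigError("cluster_k must be >= 1")
        if self.simulate is None:
            for path_attr in ("plate_table", "array_key"):
                path = getattr(self, path_attr)
                if path is None:
                    raise ConfigError(f"{path_attr} required without simulation")
                if not os.path.exists(path):
                    raise ConfigError(f"{path_attr} does not exist: {path}")
            if self.annotations is not None and not os.path.exists(self.annotations):
                raise ConfigError(f"annotations do not exist: {self.annotations}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        sim = raw.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        if sim is not None:
            sim_known = {f.name for f in dataclasses.fields(_simulate.SimConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ConfigError(f"unknown simulate keys: {sorted(sim_unknown)}")
            for key in ("planted_interactions", "planted_expression",
                        "condition_shifts"):
                if key in sim:
                    sim[key] = [tuple(item) for item in sim[key]]
            for key in ("plate_format", "conditions", "constructs",
                        "gradient", "marker_carryover_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            config.simulate = _simulate.SimConfig(**sim)
        return config

    def manifest_items(self) -> list[tuple[str, Any]]:
        items: list[tuple[str, Any]] = []
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if field.name == "simulate":
                if value is None:
                    items.append(("simulate", "none"))
                else:
                    for sub in dataclasses.fields(value):
                        sub_value = getattr(value, sub.name)
                        if isinstance(sub_value, list) and len(sub_value) > 20:
                            sub_value = f"<{len(sub_value)} entries>"
                        items.append((f"simulate.{sub.name}", sub_value))
            else:
                items.append((field.name, value))
        items.append(("opscreen_version", __version__))
        items.append(("numpy_version", np.__version__))
        items.append(("pandas_version", pd.__version__))
        return items


def _acquire(config: RunConfig):
    """Load or simulate the screen inputs."""
    if config.simulate is not None:
        plates, key, truth = _simulate.simulate_screen(config.simulate)
        plates = _simulate.simulate_fluorescence(config.simulate, plates,
                                                 key, truth)
        neg_genes = set(
            truth.strains.set_index("strain_id").loc[
                [s for s, c, d, e in config.simulate.planted_interactions
                 if e < 0 and d == config.strong_condition], "gene"]
        ) if config.simulate.planted_interactions else set()
        annotations = _simulate.simulate_annotations(
            truth, seed=config.simulate.seed, enriched_in=neg_genes)
        return plates, key, annotations, truth
    plates = _io.read_plate_table(config.plate_table)
    key = _io.read_array_key(config.array_key)
    annotations = (_io.read_annotation_gmt(config.annotations)
                   if config.annotations else None)
    return plates, key, annotations, None


def thresholds_for(config: RunConfig, construct: str) -> tuple[float, float]:
    """(upper, lower) epsilon thresholds for one construct."""
    if construct in config.asymmetric_constructs:
        return config.eps_hi, config.eps_lo
    return config.eps_symmetric, -config.eps_symmetric


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the in-memory tables.

    Writes, in order: fitness table, vector condition-sensitivity table,
    GI table, per-construct/condition call tables, reproducibility
    report, GFPunit table, quadrant table, carryover-rejects table,
    cluster assignments, enrichment tables and the run manifest.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    write = lambda frame, name: _io.write_results_table(  # noqa: E731
        frame, os.path.join(config.out_dir, name),
        float_precision=config.float_precision)
    outputs: dict[str, Any] = {}

    plates, key, annotations, truth = _acquire(config)
    log.info("stage acquire: %d plates, %d key rows", len(plates), len(key))

    # --- normalization -> fitness ---------------------------------------
    normalized = []
    for plate in plates:
        marker = key.marker_mask(plate)
        gids = _norm.group_id_grid(key, plate)
        normalized.append(_norm.normalize_plate(
            plate, marker, depth=config.edge_depth,
            polish_max_iter=config.polish_max_iter,
            polish_tol=config.polish_tol, window=config.spatial_window,
            group_ids=gids))
    colonies = _norm.colony_table(normalized, key)
    fitness = _norm.collapse_replicates(normalized, key)
    log.info("stage normalize: %d plates -> %d fitness records",
             len(normalized), len(fitness))
    write(fitness, "fitness.tsv")
    outputs["fitness"] = fitness

    delta = _norm.vector_condition_delta(fitness)
    write(delta, "vector_condition_delta.tsv")
    outputs["vector_condition_delta"] = delta

    # --- GI scoring and calling -----------------------------------------
    per_rep = _scoring.score_screen(colonies, fitness,
                                    dead_floor=config.dead_floor)
    gi_wide = _scoring.widen_gi(per_rep)
    log.info("stage score: %d per-replicate records -> %d complete pairs",
             len(per_rep), len(gi_wide))
    write(gi_wide, "gi_scores.tsv")
    outputs["gi_scores"] = gi_wide

    called_frames = []
    for construct, sub in gi_wide.groupby("construct"):
        hi, lo = thresholds_for(config, construct)
        called_frames.append(_scoring.call_interactions(
            sub, threshold_hi=hi, threshold_lo=lo, p_max=config.p_max,
            strong_cut=config.strong_cut))
    calls = (pd.concat(called_frames, ignore_index=True)
             if called_frames else gi_wide.assign(call="none"))
    outputs["calls"] = calls
    for (construct, condition), sub in calls.groupby(["construct", "condition"]):
        write(sub, f"calls_{construct}_{condition}.tsv")
    n_called = int((calls["call"] != "none").sum())
    log.info("stage call: %d records, %d called", len(calls), n_called)

    # --- reproducibility report ------------------------------------------
    rows = []
    for (construct, condition), sub in gi_wide.groupby(["construct", "condition"]):
        for rule in ("all", "passed_variability", "passed_threshold"):
            r, n = _scoring.replicate_correlation(
                sub, rule, threshold=thresholds_for(config, construct)[0],
                p_max=config.p_max)
            rows.append({"construct": construct, "condition": condition,
                         "subset": rule, "pearson_r": r, "n_pairs": n})
    for construct in sorted(calls["construct"].unique()):
        r, n = _scoring.cross_condition_correlation(calls, construct)
        rows.append({"construct": construct, "condition": "cross_condition",
                     "subset": "called_both", "pearson_r": r, "n_pairs": n})
    reproducibility = pd.DataFrame(rows)
    write(reproducibility, "reproducibility.tsv")
    outputs["reproducibility"] = reproducibility

    # --- fluorescence -> GFPunits ----------------------------------------
    fluor_plates = [p for p in normalized
                    if p.has_fluorescence and p.construct != "vector"
                    and p.condition == config.fluorescence_condition
                    and p.experiment_replicate == config.fluorescence_replicate]
    if fluor_plates:
        # GFPunits are ratios of raw channel medians; reuse original plates
        raw_by_id = {p.plate_id: p for p in plates}
        units = _fluorescence.compute_gfp_units(
            [raw_by_id[p.plate_id] for p in fluor_plates], key,
            statistic=config.plate_statistic)
        levels = _fluorescence.classify_expression(units)
    else:
        log.warning("no fluorescence plates; GFPunit stage skipped")
        levels = pd.DataFrame(columns=["strain_id", "gene", "construct",
                                       "unit_colony1", "unit_colony2",
                                       "gfp_unit", "n_colonies",
                                       "level_class"])
    write(levels, "gfp_units.tsv")
    outputs["gfp_units"] = levels
    log.info("stage fluorescence: %d GFPunit records", len(levels))

    # --- carryover filter and quadrants ----------------------------------
    vec = fitness[(fitness["construct"] == "vector")
                  & (fitness["condition"] == config.strong_condition)
                  & ~fitness["is_control"] & ~fitness["excluded"]]
    vector_w = vec.groupby("strain_id")["W"].mean()
    strong_calls = calls[calls["condition"] == config.strong_condition]
    retained_pos, rejects = _classify.marker_carryover_filter(
        strong_calls, vector_w, size_threshold=config.control_size_cut)
    write(rejects, "carryover_rejects.tsv")
    outputs["carryover_rejects"] = rejects
    filtered_calls = pd.concat([
        strong_calls[strong_calls["call"] != "positive"],
        retained_pos.drop(columns=["vector_w"]),
    ], ignore_index=True)
    log.info("stage carryover: %d positive calls -> %d retained",
             int((strong_calls["call"] == "positive").sum()), len(retained_pos))

    quadrants = _classify.quadrant_table(filtered_calls, levels,
                                         condition=config.strong_condition)
    write(quadrants, "quadrants.tsv")
    outputs["quadrants"] = quadrants

    advantage = _classify.fitness_advantage_candidates(
        filtered_calls[filtered_calls["condition"] == config.strong_condition],
        levels, vector_w)
    write(advantage, "fitness_advantage.tsv")
    outputs["fitness_advantage"] = advantage

    # --- clustering -------------------------------------------------------
    profile_constructs = tuple(
        c for c in _classify.PROFILE_CONSTRUCTS
        if c in set(filtered_calls["construct"]))
    clusters = pd.DataFrame(columns=["strain_id", "cluster_id"])
    if len(profile_constructs) >= 2:
        profiles = _classify.build_profiles(
            filtered_calls, constructs=profile_constructs,
            condition=config.strong_condition)
        if len(profiles) >= config.cluster_k:
            clusters = _classify.cluster_gi_profiles(profiles,
                                                     k=config.cluster_k)
        else:
            log.warning("only %d profiles (< k=%d); clustering skipped",
                        len(profiles), config.cluster_k)
    else:
        log.warning("fewer than 2 op constructs; clustering skipped")
    write(clusters, "clusters.tsv")
    outputs["clusters"] = clusters

    shared = _classify.shared_interaction_stats({
        construct: sub for construct, sub in filtered_calls.groupby("construct")})
    write(shared, "shared_interactions.tsv")
    outputs["shared_interactions"] = shared

    # --- enrichment --------------------------------------------------------
    enrichment_tables: dict[str, pd.DataFrame] = {}
    if annotations is not None and len(annotations):
        gene_map = dict(zip(key.frame["strain_id"], key.frame["gene"])) \
            if config.gene_level else None
        # positives enter enrichment after the carryover filter (paper-style
        # attrition is logged at the carryover stage)
        strong = _scoring.strong_subset(filtered_calls,
                                        strong_cut=config.strong_cut,
                                        condition=config.strong_condition)
        for construct, sets in sorted(strong.items()):
            scored = set(gi_wide.loc[
                (gi_wide["construct"] == construct)
                & (gi_wide["condition"] == config.strong_condition),
                "strain_id"])
            for direction, query in sorted(sets.items()):
                if not query:
                    continue
                result = _enrichment.enrich(
                    query, annotations, scored,
                    min_term_size=config.min_term_size, gene_map=gene_map)
                name = f"enrichment_{construct}_{direction}"
                enrichment_tables[name] = result
                write(result, f"{name}.tsv")
    outputs["enrichment"] = enrichment_tables
    log.info("stage enrich: %d tables", len(enrichment_tables))

    # --- manifest ----------------------------------------------------------
    manifest_path = os.path.join(config.out_dir, "manifest.txt")
    with open(manifest_path, "w") as handle:
        for key_name, value in config.manifest_items():
            handle.write(f"{key_name}={value}\n")
    outputs["manifest"] = manifest_path
    if truth is not None:
        outputs["truth"] = truth
    return outputs
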
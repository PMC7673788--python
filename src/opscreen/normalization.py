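"""Colony-size normalization: raw pixel sizes -> per-strain fitness (U).

The chain has three fixed stages, each dividing sizes by a robust local
statistic computed over *interior, present, non-marker* colonies only:

1. plate-median scaling (interior median becomes exactly 1 — the "U" unit),
2. alternating row/column median polish (linear print/nutrient gradients),
3. moving 2-D median correction (smooth spatial artifacts, e.g. a radial
   bowl), with window neighborhoods truncated at plate borders.

The outer two rows/columns of a 1536-format plate usually hold control
colonies and suffer the well-known edge growth advantage, so edge
positions never contribute to any median (depth configurable).  The four
adjacent colonies of each strain are then collapsed to a mean fitness W
with a dispersion estimate.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import ArrayKey, PlateGrid, ScreenError

log = logging.getLogger(__name__)

EDGE_DEPTH = 2
DEAD_STRAIN_FLOOR = 0.05  # vector-control W below this cannot be scored


def edge_mask(n_rows: int, n_cols: int, depth: int = EDGE_DEPTH) -> np.ndarray:
    """Boolean grid marking the outer ``depth`` rows and columns."""
    if depth < 0:
        raise ScreenError("edge depth must be >= 0")
    if depth and depth >= min(n_rows, n_cols) / 2:
        raise ScreenError("edge depth leaves no interior")
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    if depth:
        mask[:depth, :] = True
        mask[-depth:, :] = True
        mask[:, :depth] = True
        mask[:, -depth:] = True
    return mask


def _nanmedian(arr: np.ndarray, axis: int) -> np.ndarray:
    """nanmedian without the all-NaN slice warning (empty support -> NaN)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(arr, axis=axis)


def _support(grid: PlateGrid, marker: np.ndarray | None,
             depth: int) -> np.ndarray:
    """Cells allowed to contribute to median statistics."""
    support = grid.present & ~edge_mask(grid.n_rows, grid.n_cols, depth)
    if marker is not None:
        support &= ~marker
    return support


def plate_median_normalize(grid: PlateGrid,
                           marker: np.ndarray | None = None,
                           depth: int = EDGE_DEPTH) -> PlateGrid:
    """Divide all sizes by the interior non-marker median.

    After this call the interior non-marker median is exactly 1; every
    other size is expressed in these plate-median units ("U").
    """
    support = _support(grid, marker, depth)
    if not support.any():
        raise ScreenError(
            f"plate {grid.plate_id}: no interior colonies to normalize against")
    med = float(np.median(grid.size[support]))
    if med <= 0:
        raise ScreenError(f"plate {grid.plate_id}: non-positive interior median")
    out = grid.copy()
    out.size = np.where(out.present, out.size / med, 0.0)
    return out


def rowcol_polish(grid: PlateGrid,
                  marker: np.ndarray | None = None,
                  depth: int = EDGE_DEPTH,
                  max_iter: int = 20,
                  tol: float = 1e-9) -> PlateGrid:
    """Alternating row- and column-median division until medians converge.

    Rows/columns without any supporting colony (e.g. the edge band, or an
    all-absent lane) are left unchanged.
    """
    out = grid.copy()
    support = _support(out, marker, depth)
    corrected = out.size.copy()
    for _ in range(max_iter):
        work = np.where(support, corrected, np.nan)
        row_med = _nanmedian(work, axis=1)
        row_fac = np.where(np.isfinite(row_med) & (row_med > 0), row_med, 1.0)
        row_dev = np.max(np.abs(row_fac - 1.0))
        corrected = corrected / row_fac[:, None]
        work = np.where(support, corrected, np.nan)
        col_med = _nanmedian(work, axis=0)
        col_fac = np.where(np.isfinite(col_med) & (col_med > 0), col_med, 1.0)
        col_dev = np.max(np.abs(col_fac - 1.0))
        corrected = corrected / col_fac[None, :]
        if row_dev < tol and col_dev < tol:
            break
    out.size = np.where(out.present, corrected, 0.0)
    return out


def spatial_smooth_correct(grid: PlateGrid,
                           marker: np.ndarray | None = None,
                           depth: int = EDGE_DEPTH,
                           window: int = 7,
                           group_ids: np.ndarray | None = None) -> PlateGrid:
    """Divide each size by the moving 2-D median of its neighborhood.

    The neighborhood median is computed over present, non-marker,
    non-edge colonies; windows are truncated at plate borders.  When
    ``group_ids`` (an integer grid of replicate-group codes, -1 for
    unassigned) is given, cells sharing the center cell's group are
    excluded from its neighborhood: the four colonies of a strain sit in
    one 2x2 block, and letting a strain's own colonies vote on its local
    reference would bias its correction toward its own phenotype.  Cells
    whose neighborhood has no support are left unchanged.
    """
    if window % 2 == 0 or window < 3:
        raise ScreenError("spatial window must be odd and >= 3")
    support = _support(grid, marker, depth)
    half = window // 2
    vals = np.where(support, grid.size, np.nan)
    padded = np.pad(vals, half, mode="constant", constant_values=np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    flat = windows.reshape(grid.n_rows, grid.n_cols, -1)
    if group_ids is not None:
        gids = np.asarray(group_ids)
        if gids.shape != grid.size.shape:
            raise ScreenError("group_ids shape mismatch")
        padded_g = np.pad(gids, half, mode="constant", constant_values=-1)
        win_g = np.lib.stride_tricks.sliding_window_view(
            padded_g, (window, window)).reshape(grid.n_rows, grid.n_cols, -1)
        own = (win_g == gids[:, :, None]) & (gids[:, :, None] >= 0)
        flat = np.where(own, np.nan, flat)
    med = _nanmedian(flat, axis=2)
    med = np.where(np.isfinite(med) & (med > 0), med, 1.0)
    out = grid.copy()
    out.size = np.where(out.present, out.size / med, 0.0)
    return out


def group_id_grid(key: ArrayKey, plate: PlateGrid) -> np.ndarray:
    """Integer replicate-group codes per position (-1 where unassigned)."""
    gids = np.full((plate.n_rows, plate.n_cols), -1, dtype=int)
    sub = key.for_plate(plate.plate_id)
    codes = pd.factorize(sub["replicate_group"])[0]
    gids[sub["row"].to_numpy() - 1, sub["col"].to_numpy() - 1] = codes
    return gids


def normalize_plate(grid: PlateGrid,
                    marker: np.ndarray | None = None,
                    depth: int = EDGE_DEPTH,
                    polish_max_iter: int = 20,
                    polish_tol: float = 1e-9,
                    window: int = 7,
                    group_ids: np.ndarray | None = None) -> PlateGrid:
    """Full fixed-order chain: plate median -> row/col polish -> spatial.

    Closes with a second plate-median scaling so corrected sizes are in
    plate-median units ("U") with the interior median exactly 1: the
    polish and spatial stages preserve the median only approximately.
    """
    out = plate_median_normalize(grid, marker, depth)
    out = rowcol_polish(out, marker, depth, polish_max_iter, polish_tol)
    out = spatial_smooth_correct(out, marker, depth, window,
                                 group_ids=group_ids)
    return plate_median_normalize(out, marker, depth)


def collapse_replicates(plates: list[PlateGrid], key: ArrayKey) -> pd.DataFrame:
    """Collapse the four adjacent colonies of each strain to fitness W.

    Returns one row per replicate group with ``W`` (mean of present
    colony sizes), ``W_sd`` (sample standard deviation, defined when at
    least two colonies are present) and ``n_colonies``.  Groups with no
    present colony are kept with ``W`` = NaN and ``excluded`` = True.
    """
    colonies = colony_table(plates, key)
    grouped = colonies[colonies["present"]].groupby("replicate_group")["size"]
    stats = grouped.agg(W="mean", W_sd=lambda s: s.std(ddof=1), n_colonies="count")
    meta_cols = ["replicate_group", "strain_id", "gene", "allele",
                 "construct", "condition", "experiment_replicate",
                 "marker_flag", "essentiality", "is_control"]
    meta = colonies[meta_cols].drop_duplicates("replicate_group")
    fitness = meta.merge(stats, on="replicate_group", how="left")
    fitness["n_colonies"] = fitness["n_colonies"].fillna(0).astype(int)
    fitness["excluded"] = fitness["n_colonies"] == 0
    fitness.loc[fitness["n_colonies"] < 2, "W_sd"] = np.nan
    return fitness.sort_values(
        ["strain_id", "construct", "condition", "experiment_replicate"],
        kind="mergesort").reset_index(drop=True)


def colony_table(plates: list[PlateGrid], key: ArrayKey) -> pd.DataFrame:
    """Per-colony long table joined with the array key.

    Raises if any plate position is not covered by the key (a colony
    whose replicate group is unknown cannot be scored).
    """
    frames = []
    for plate in plates:
        frame = plate.to_frame(include_absent=True)
        for field in ("construct", "condition", "experiment_replicate"):
            if field not in frame.columns:
                raise ScreenError(
                    f"plate {plate.plate_id} lacks {field}; scoring needs it")
        frames.append(frame)
    colonies = pd.concat(frames, ignore_index=True)
    merged = colonies.merge(
        key.frame.drop(columns=["experiment_replicate"]),
        on=["plate_id", "row", "col"], how="left", validate="one_to_one")
    unmapped = merged["replicate_group"].isna() & merged["present"]
    if unmapped.any():
        offender = merged.loc[unmapped.idxmax()]
        raise ScreenError(
            "colony not covered by array key: "
            f"{offender.plate_id}:({offender.row},{offender.col})")
    merged = merged[~merged["replicate_group"].isna()]
    return merged


def vector_condition_delta(fitness: pd.DataFrame,
                           threshold: float = -2.0) -> pd.DataFrame:
    """Vector-control colony-size change between conditions, in U.

    ``delta_u`` = W(-Leu/Ura) - W(-Ura) per strain and experiment
    replicate; strains dropping by more than 2 U are flagged
    condition-sensitive (they respond to plasmid copy number itself, not
    to the overproduced protein).
    """
    vec = fitness[(fitness["construct"] == "vector")
                  & ~fitness["is_control"] & ~fitness["excluded"]]
    wide = vec.pivot_table(index=["strain_id", "experiment_replicate"],
                           columns="condition", values="W", aggfunc="mean")
    missing = wide.index[wide.isna().any(axis=1)]
    for strain, rep in missing[:5]:
        log.warning("strain %s %s missing a condition; skipped", strain, rep)
    wide = wide.dropna()
    if not {"ura_minus", "leu_ura_minus"} <= set(wide.columns):
        return pd.DataFrame(columns=["strain_id", "experiment_replicate",
                                     "delta_u", "condition_sensitive"])
    out = wide.reset_index()
    out["delta_u"] = out["leu_ura_minus"] - out["ura_minus"]
    out["condition_sensitive"] = out["delta_u"] < threshold
    return out[["strain_id", "experiment_replicate", "delta_u",
                "condition_sensitive"]]
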
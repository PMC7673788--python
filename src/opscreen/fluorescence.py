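"""Reporter-fluorescence quantification: colony medians -> GFPunits.

Each colony carries two channel medians: F488 (GFP) and F532
(constitutively expressed E2-Crimson, a biomass proxy).  Per plate and
channel, medians are divided by the plate average so scanner gain drops
out; the per-colony ratio F488/F532 then cancels colony size, and the
average over (up to) two colonies is the strain's GFPunit.  Mutants with
GFPunit below the across-mutant average are GFP_L, the rest GFP_H.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ArrayKey, PlateGrid, ScreenError

log = logging.getLogger(__name__)

MAX_FLUOR_COLONIES = 2


def channel_plate_normalize(plates: list[PlateGrid],
                            statistic: str = "mean") -> list[PlateGrid]:
    """Divide each colony's channel median by the plate-level average.

    ``statistic`` selects the plate-level average of the per-colony
    medians: ``mean`` (default reading of "plate average median") or
    ``median``.  Channels are normalized independently, so any per-plate,
    per-channel scan gain cancels.
    """
    if statistic not in ("mean", "median"):
        raise ScreenError(f"unknown plate statistic {statistic!r}")
    agg = np.mean if statistic == "mean" else np.median
    out = []
    for plate in plates:
        if not plate.has_fluorescence:
            raise ScreenError(
                f"plate {plate.plate_id} has no fluorescence channels")
        new = plate.copy()
        for ch in ("f488", "f532"):
            arr = getattr(new, ch)
            vals = arr[new.present]
            if vals.size == 0:
                raise ScreenError(f"plate {plate.plate_id}: no present colonies")
            center = float(agg(vals))
            if center <= 0:
                raise ScreenError(
                    f"plate {plate.plate_id}: non-positive {ch} plate average")
            setattr(new, ch, np.where(new.present, arr / center, 0.0))
        out.append(new)
    return out


def gfp_unit(f488_norm, f532_norm) -> float:
    """Mean per-colony F488/F532 ratio over the available (<= 2) colonies.

    Colonies with zero F532 are dropped with a warning; NaN when no
    colony survives.
    """
    f488 = np.atleast_1d(np.asarray(f488_norm, dtype=float))
    f532 = np.atleast_1d(np.asarray(f532_norm, dtype=float))
    if f488.shape != f532.shape or f488.size == 0 or f488.size > MAX_FLUOR_COLONIES:
        raise ScreenError("gfp_unit expects 1 or 2 matched colony values")
    keep = f532 > 0
    if not keep.all():
        log.warning("dropping %d colony ratios with zero F532", (~keep).sum())
    if not keep.any():
        return float("nan")
    return float(np.mean(f488[keep] / f532[keep]))


def compute_gfp_units(plates: list[PlateGrid], key: ArrayKey,
                      statistic: str = "mean") -> pd.DataFrame:
    """Per-strain GFPunits from fluorescence plates of one construct set.

    For each replicate group the first two present colonies in (row, col)
    order are used, matching the two-colonies-per-strain measurement
    design.  Returns one row per strain and construct with
    ``unit_colony1``, ``unit_colony2`` and their mean ``gfp_unit``.
    """
    normed = channel_plate_normalize(plates, statistic=statistic)
    frames = []
    for plate in normed:
        frame = plate.to_frame()
        if "construct" not in frame.columns:
            raise ScreenError(f"plate {plate.plate_id} lacks construct metadata")
        frames.append(frame)
    colonies = pd.concat(frames, ignore_index=True)
    merged = colonies.merge(key.frame.drop(columns=["experiment_replicate"]),
                            on=["plate_id", "row", "col"], how="inner")
    merged = merged[~merged["is_control"]]
    merged = merged.sort_values(["plate_id", "row", "col"], kind="mergesort")
    records = []
    grouped = merged.groupby(["strain_id", "gene", "construct",
                              "replicate_group"], sort=True)
    for (strain, gene, construct, _), grp in grouped:
        grp = grp.head(MAX_FLUOR_COLONIES)
        usable = grp[grp["f532"] > 0]
        n_dropped = len(grp) - len(usable)
        if n_dropped:
            log.warning("strain %s: %d colony ratios dropped (zero F532)",
                        strain, n_dropped)
        units = (usable["f488"] / usable["f532"]).to_list()
        records.append({
            "strain_id": strain,
            "gene": gene,
            "construct": construct,
            "unit_colony1": units[0] if len(units) > 0 else np.nan,
            "unit_colony2": units[1] if len(units) > 1 else np.nan,
            "gfp_unit": float(np.mean(units)) if units else np.nan,
            "n_colonies": len(units),
        })
    out = pd.DataFrame.from_records(records)
    if len(out):
        # one measurement per strain x construct (strains sit in one block)
        out = out.groupby(["strain_id", "gene", "construct"], as_index=False).agg(
            unit_colony1=("unit_colony1", "first"),
            unit_colony2=("unit_colony2", "first"),
            gfp_unit=("gfp_unit", "mean"),
            n_colonies=("n_colonies", "sum"))
    return out.sort_values(["strain_id", "construct"],
                           kind="mergesort").reset_index(drop=True)


def classify_expression(units: pd.DataFrame) -> pd.DataFrame:
    """Split mutants into GFP_L / GFP_H around the per-construct average.

    The reference is the arithmetic mean of all defined GFPunits for the
    construct; units strictly below it are GFP_L, the rest (ties
    included) GFP_H.
    """
    out = units.copy()
    out["level_class"] = pd.NA
    for construct, grp in out.groupby("construct"):
        defined = grp["gfp_unit"].dropna()
        if len(defined) < 2:
            log.warning("construct %s: fewer than 2 defined GFPunits; "
                        "no classification", construct)
            continue
        reference = float(defined.mean())
        mask = (out["construct"] == construct) & out["gfp_unit"].notna()
        out.loc[mask, "level_class"] = np.where(
            out.loc[mask, "gfp_unit"] < reference, "GFP_L", "GFP_H")
        out.loc[mask, "reference_mean"] = reference
    return out
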
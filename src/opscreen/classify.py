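"""Interpretation of called mutants: quadrants, filters, profile clustering.

Combining the sign of a mutant's genetic interaction with its expression
class yields four interpretive quadrants: a negative interactor producing
less reporter is *sensitive to overproduction*; one producing more is
*production enhancing*; a positive interactor producing less *reduces
production* (and thereby escapes the burden); one producing more is
genuinely *resistant to overproduction*.  Two filters de-noise the
positive set (marker-pathway carryover; fitness advantage), and GI
profiles across constructs are clustered by average-linkage hierarchical
clustering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

CARRYOVER_SIZE_THRESHOLD = 0.39  # vector-control W must exceed this (strict)
CLUSTER_K = 15
PROFILE_CONSTRUCTS = ("GFP", "tGFP", "NES_tGFP")

QUADRANTS = {
    ("negative", "GFP_L"): "sensitive_to_overproduction",
    ("negative", "GFP_H"): "production_enhancing",
    ("positive", "GFP_L"): "production_reducing",
    ("positive", "GFP_H"): "resistant_to_overproduction",
}


def quadrant_interpretation(gi_call: str, level_class: str) -> str:
    """Map (GI call, expression class) to the four-quadrant interpretation."""
    try:
        return QUADRANTS[(gi_call, level_class)]
    except KeyError:
        raise ValueError(f"undefined quadrant ({gi_call!r}, {level_class!r})")


def quadrant_table(calls: pd.DataFrame, levels: pd.DataFrame,
                   condition: str = "leu_ura_minus") -> pd.DataFrame:
    """Join called mutants with expression classes and attach quadrants."""
    called = calls[(calls["call"] != "none") & (calls["condition"] == condition)]
    merged = called.merge(
        levels[["strain_id", "construct", "gfp_unit", "level_class"]],
        on=["strain_id", "construct"], how="inner")
    merged = merged[merged["level_class"].notna()].copy()
    merged["interpretation"] = [
        quadrant_interpretation(c, l)
        for c, l in zip(merged["call"], merged["level_class"])
    ]
    cols = ["strain_id", "gene", "construct", "condition", "call",
            "eps_mean", "gfp_unit", "level_class", "interpretation"]
    return merged[cols].sort_values(["strain_id", "construct"],
                                    kind="mergesort").reset_index(drop=True)


def marker_carryover_filter(positive_calls: pd.DataFrame,
                            vector_w: pd.Series,
                            size_threshold: float = CARRYOVER_SIZE_THRESHOLD
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop positive calls whose vector-control colonies are carryover-small.

    Marker-pathway (his/lys/arg) deletions cannot grow under SGA
    selection; their vector-control colonies are carried-over cell
    material, and apparent positive GIs from them are artifacts.  A
    positive call is retained only when the strain's vector-control W is
    strictly greater than ``size_threshold``.

    Parameters
    ----------
    positive_calls
        Called records with ``call == "positive"``.
    vector_w
        Per-strain vector-control fitness (indexed by strain_id).

    Returns
    -------
    (retained, rejects) — rejects carry a ``reason`` column
    (``small_control`` or ``no_control``) and the strain's marker flag.
    """
    pos = positive_calls[positive_calls["call"] == "positive"].copy()
    pos["vector_w"] = pos["strain_id"].map(vector_w)
    no_control = pos["vector_w"].isna()
    small = ~no_control & (pos["vector_w"] <= size_threshold)
    pos["reason"] = np.select([no_control, small],
                              ["no_control", "small_control"], default="")
    retained = pos[pos["reason"] == ""].drop(columns="reason")
    rejects = pos[pos["reason"] != ""]
    return (retained.reset_index(drop=True), rejects.reset_index(drop=True))


def fitness_advantage_candidates(calls: pd.DataFrame,
                                 levels: pd.DataFrame,
                                 vector_w: pd.Series,
                                 advantage_cut: float | None = None
                                 ) -> pd.DataFrame:
    """Positive, GFP_H mutants whose vector-control fitness is already high.

    Candidates for mutations that confer a growth advantage further
    enhanced by overproduction.  ``advantage_cut`` defaults to
    mean + 1 sd of the supplied vector-control W distribution.
    """
    if advantage_cut is None:
        advantage_cut = float(vector_w.mean() + vector_w.std(ddof=1))
    pos = calls[calls["call"] == "positive"]
    high = levels[levels["level_class"] == "GFP_H"]
    merged = pos.merge(high[["strain_id", "construct", "gfp_unit"]],
                       on=["strain_id", "construct"], how="inner").copy()
    merged["vector_w"] = merged["strain_id"].map(vector_w)
    out = merged[merged["vector_w"] > advantage_cut]
    out = out.assign(advantage_cut=advantage_cut)
    cols = [c for c in ("strain_id", "gene", "construct", "condition",
                        "eps_mean", "gfp_unit", "vector_w", "advantage_cut")
            if c in out.columns]
    return out[cols].sort_values(["strain_id", "construct"],
                                 kind="mergesort").reset_index(drop=True)


def build_profiles(calls: pd.DataFrame,
                   constructs: tuple[str, ...] = PROFILE_CONSTRUCTS,
                   condition: str = "leu_ura_minus") -> pd.DataFrame:
    """GI-score profiles over constructs for strains called at least once.

    A strain enters if it was called in >= 1 of the constructs and was
    scored (record present) in all of them; a scored-but-uncalled
    construct contributes epsilon = 0 (no measured interaction), flagged
    in ``imputed_<construct>``.
    """
    sub = calls[(calls["condition"] == condition)
                & calls["construct"].isin(constructs)]
    eps = sub.pivot_table(index="strain_id", columns="construct",
                          values="eps_mean", aggfunc="first")
    scored = sub.pivot_table(index="strain_id", columns="construct",
                             values="eps_rep1", aggfunc="first")
    for c in constructs:
        if c not in eps.columns:
            eps[c] = np.nan
        if c not in scored.columns:
            scored[c] = np.nan
    eps = eps[list(constructs)]
    scored = scored[list(constructs)]
    called_any = eps.notna().any(axis=1)
    scored_all = scored.notna().all(axis=1)
    keep = called_any & scored_all
    profiles = eps.loc[keep.reindex(eps.index, fill_value=False)].copy()
    flags = profiles.isna()
    profiles = profiles.fillna(0.0)
    for c in constructs:
        profiles[f"imputed_{c}"] = flags[c]
    return profiles.sort_index()


def cluster_gi_profiles(profiles: pd.DataFrame,
                        k: int = CLUSTER_K,
                        metric: str = "euclidean",
                        linkage: str = "average") -> pd.DataFrame:
    """Cut an average-linkage tree over GI profiles into exactly k clusters.

    Rows are sorted by strain id before linkage and cluster ids are
    relabelled 1..k by the lexicographically smallest member strain, so
    the assignment is invariant to input row order.
    """
    value_cols = [c for c in profiles.columns if not c.startswith("imputed_")]
    data = profiles[value_cols].sort_index()
    if len(data) < k:
        raise ValueError(f"cannot cut {len(data)} profiles into {k} clusters")
    dist = pdist(data.to_numpy(), metric=metric)
    tree = hierarchy.linkage(dist, method=linkage)
    raw = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    # relabel clusters contiguously by their lexicographic minimum strain
    order = {}
    strains = data.index.to_numpy()
    for label in np.unique(raw):
        order[label] = strains[raw == label].min()
    ranking = sorted(order, key=lambda lab: order[lab])
    relabel = {old: new + 1 for new, old in enumerate(ranking)}
    assignment = pd.DataFrame({
        "strain_id": strains,
        "cluster_id": [relabel[lab] for lab in raw],
    })
    for col in value_cols:
        assignment[f"eps_{col}"] = data[col].to_numpy()
    return assignment.sort_values(["cluster_id", "strain_id"],
                                  kind="mergesort").reset_index(drop=True)


def shared_interaction_stats(called_sets: dict[str, pd.DataFrame]
                             ) -> pd.DataFrame:
    """Pairwise overlap of called mutants between constructs.

    ``called_sets`` maps construct -> called records (``call`` != none).
    Emits, per construct pair and per category (any/negative/positive),
    the intersection, union and Jaccard fraction.
    """
    sets: dict[str, dict[str, set[str]]] = {}
    for construct, frame in called_sets.items():
        frame = frame[frame["call"] != "none"]
        sets[construct] = {
            "any": set(frame["strain_id"]),
            "negative": set(frame.loc[frame["call"] == "negative", "strain_id"]),
            "positive": set(frame.loc[frame["call"] == "positive", "strain_id"]),
        }
    rows = []
    names = sorted(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for category in ("any", "negative", "positive"):
                inter = sets[a][category] & sets[b][category]
                union = sets[a][category] | sets[b][category]
                rows.append({
                    "pair": f"{a}|{b}",
                    "category": category,
                    "n_intersection": len(inter),
                    "n_union": len(union),
                    "fraction_shared": (len(inter) / len(union)) if union else 0.0,
                })
    return pd.DataFrame(rows)
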
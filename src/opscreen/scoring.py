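"""Genetic-interaction scoring, confidence testing and calling.

The GI score of a mutant x construct pair is the deviation of the double
perturbation from the multiplicative expectation,

    epsilon = W_AB - W_A * W_B,

with the query fitness W_B fixed at 1, so epsilon = W_AB - W_A: the
difference between the mutant's normalized colony size under the
overproduction plasmid and under the empty vector.  Confidence comes from
a variance-floored Welch-type test on the replicate colonies; the floor is
the across-array median per-strain colony variance for the same construct
and condition, which propagates array-wide variability into strains whose
four colonies happen to agree by chance.  A mutant is *called* when both
duplicate experiments clear the epsilon threshold with the same sign and
both tests are significant.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

EPS_THRESHOLD = 0.08        # per-replicate |epsilon| cut
P_MAX = 0.05                # per-replicate confidence level
STRONG_CUT = 0.2            # strong-GI cut on the replicate average
ASYMMETRIC_THRESHOLDS = (0.16, -0.12)  # upper/lower cut for tGFP / NES-tGFP


def gi_score(w_ab, w_a, w_b=1.0):
    """epsilon = W_AB - W_A x W_B (vectorized)."""
    return np.asarray(w_ab, dtype=float) - np.asarray(w_a, dtype=float) * w_b


def welch_pvalue_from_stats(mean1, var1, n1, mean2, var2, n2,
                            var_floor: float = 0.0) -> np.ndarray:
    """Two-sided unequal-variance t-type p-value from summary statistics.

    Each sample's variance is floored at ``var_floor`` before forming the
    Welch statistic, so a strain whose colonies agree suspiciously well is
    still judged against the array-typical dispersion.
    """
    mean1 = np.asarray(mean1, dtype=float)
    mean2 = np.asarray(mean2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    v1 = np.maximum(np.asarray(var1, dtype=float), var_floor)
    v2 = np.maximum(np.asarray(var2, dtype=float), var_floor)
    se2 = v1 / n1 + v2 / n2
    diff = mean1 - mean2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, diff / np.sqrt(se2), np.where(diff == 0, 0.0, np.inf))
        df = np.where(
            se2 > 0,
            se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)),
            1.0,
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.minimum(p, 1.0)


def interaction_pvalue(colonies_ab: Sequence[float],
                       colonies_a: Sequence[float],
                       pooled_sd: float) -> float:
    """Confidence p-value for one strain from its replicate colonies.

    ``pooled_sd`` is the array-level dispersion used as a variance floor
    (its square floors each sample variance).  Requires at least two
    colonies on each side.
    """
    x = np.asarray(colonies_ab, dtype=float)
    y = np.asarray(colonies_a, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("interaction_pvalue needs >= 2 colonies per sample")
    return float(welch_pvalue_from_stats(
        x.mean(), x.var(ddof=1), len(x),
        y.mean(), y.var(ddof=1), len(y),
        var_floor=pooled_sd ** 2))


def permutation_pvalue(colonies_ab: Sequence[float],
                       colonies_a: Sequence[float]) -> float:
    """Exact two-sided label-permutation p-value (small-sample oracle).

    Enumerates every reassignment of the pooled colony values to the two
    groups and reports the fraction with |mean difference| at least as
    large as observed.  Independent of the Welch-type statistic; intended
    for validating it on 4+4 colonies.
    """
    x = np.asarray(colonies_ab, dtype=float)
    y = np.asarray(colonies_a, dtype=float)
    pooled = np.concatenate([x, y])
    n = len(x)
    observed = abs(x.mean() - y.mean())
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        diff = abs(pooled[sel].mean() - pooled[~sel].mean())
        count += diff >= observed - 1e-12
        total += 1
    return count / total


def variance_floor(colonies: pd.DataFrame) -> pd.Series:
    """Across-array median per-strain colony variance per construct/condition.

    Uses all non-control replicate groups with >= 2 present colonies,
    pooling both experiment replicates.
    """
    usable = colonies[colonies["present"] & ~colonies["is_control"]]
    per_group = usable.groupby(
        ["construct", "condition", "replicate_group"])["size"].agg(
            var=lambda s: s.var(ddof=1), n="count")
    per_group = per_group[per_group["n"] >= 2]
    return per_group.groupby(["construct", "condition"])["var"].median()


def score_screen(colonies: pd.DataFrame,
                 fitness: pd.DataFrame,
                 dead_floor: float = 0.05) -> pd.DataFrame:
    """Per-replicate GI scores and p-values for every op construct.

    Pairs each mutant's overproduction fitness with its vector-control
    fitness within the same condition and experiment replicate.  Strains
    whose vector-control W falls below ``dead_floor`` (no measurable
    growth) are dropped, as are control positions and groups with fewer
    than two colonies on either side.
    """
    floors = variance_floor(colonies)
    usable = fitness[~fitness["is_control"] & (fitness["n_colonies"] >= 2)]
    vec = usable[usable["construct"] == "vector"]
    ops = usable[usable["construct"] != "vector"]
    merged = ops.merge(
        vec[["strain_id", "condition", "experiment_replicate",
             "W", "W_sd", "n_colonies"]],
        on=["strain_id", "condition", "experiment_replicate"],
        suffixes=("_ab", "_a"))
    n_dead = int((merged["W_a"] < dead_floor).sum())
    if n_dead:
        log.info("dropping %d records below the dead-strain floor", n_dead)
    merged = merged[merged["W_a"] >= dead_floor].copy()
    merged["eps"] = gi_score(merged["W_ab"], merged["W_a"])
    floor_vals = floors.reindex(
        pd.MultiIndex.from_frame(merged[["construct", "condition"]])
    ).to_numpy()
    floor_vals = np.where(np.isfinite(floor_vals), floor_vals, 0.0)
    # the variance floor is per (construct, condition), so apply it row-wise
    merged["p"] = welch_pvalue_from_stats(
        merged["W_ab"].to_numpy(),
        np.maximum(merged["W_sd_ab"].fillna(0.0).to_numpy() ** 2, floor_vals),
        merged["n_colonies_ab"].to_numpy(),
        merged["W_a"].to_numpy(),
        np.maximum(merged["W_sd_a"].fillna(0.0).to_numpy() ** 2, floor_vals),
        merged["n_colonies_a"].to_numpy(),
        var_floor=0.0)
    out = merged[["strain_id", "gene", "allele", "marker_flag", "essentiality",
                  "construct", "condition", "experiment_replicate",
                  "W_ab", "W_a", "eps", "p"]]
    return out.sort_values(
        ["strain_id", "construct", "condition", "experiment_replicate"],
        kind="mergesort").reset_index(drop=True)


def widen_gi(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-replicate GI records to one row per strain/construct/condition.

    Keeps only strains scored in both experiment replicates (complete-case
    analysis).
    """
    idx = ["strain_id", "gene", "allele", "marker_flag", "essentiality",
           "construct", "condition"]
    wide = per_replicate.pivot_table(
        index=idx, columns="experiment_replicate",
        values=["eps", "p", "W_ab", "W_a"], aggfunc="first")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index()
    needed = ["eps_rep1", "eps_rep2", "p_rep1", "p_rep2"]
    for col in needed:
        if col not in wide.columns:
            wide[col] = np.nan
    complete = wide.dropna(subset=needed).reset_index(drop=True)
    return complete


def call_interactions(gi_wide: pd.DataFrame,
                      threshold_hi: float = EPS_THRESHOLD,
                      threshold_lo: float = -EPS_THRESHOLD,
                      p_max: float = P_MAX,
                      strong_cut: float = STRONG_CUT) -> pd.DataFrame:
    """Attach calls: positive/negative/none per strain/construct/condition.

    A call requires both replicate epsilons beyond the threshold on the
    same side and both p-values under ``p_max``; ``eps_mean`` (the
    replicate average) is attached to called records only, and ``strong``
    flags |eps_mean| > ``strong_cut``.
    """
    if threshold_lo >= 0 or threshold_hi <= 0:
        raise ValueError("threshold_lo must be < 0 and threshold_hi > 0")
    out = gi_wide.copy()
    confident = (out["p_rep1"] < p_max) & (out["p_rep2"] < p_max)
    pos = confident & (out["eps_rep1"] > threshold_hi) & (out["eps_rep2"] > threshold_hi)
    neg = confident & (out["eps_rep1"] < threshold_lo) & (out["eps_rep2"] < threshold_lo)
    out["call"] = np.select([neg, pos], ["negative", "positive"], default="none")
    mean_eps = (out["eps_rep1"] + out["eps_rep2"]) / 2.0
    out["eps_mean"] = np.where(out["call"] != "none", mean_eps, np.nan)
    out["strong"] = (out["call"] != "none") & (np.abs(out["eps_mean"]) > strong_cut)
    return out


def strong_subset(calls: pd.DataFrame,
                  strong_cut: float = STRONG_CUT,
                  condition: str = "leu_ura_minus") -> dict[str, dict[str, set[str]]]:
    """Strains with strong GIs per construct under the given condition.

    Returns ``{construct: {"op_negative": set, "op_positive": set}}``.
    """
    sub = calls[calls["condition"] == condition]
    out: dict[str, dict[str, set[str]]] = {}
    for construct, grp in sub.groupby("construct"):
        out[construct] = {
            "op_negative": set(grp.loc[(grp["call"] == "negative")
                                       & (grp["eps_mean"] < -strong_cut),
                                       "strain_id"]),
            "op_positive": set(grp.loc[(grp["call"] == "positive")
                                       & (grp["eps_mean"] > strong_cut),
                                       "strain_id"]),
        }
    return out


def replicate_correlation(gi_wide: pd.DataFrame,
                          subset_rule: str = "all",
                          threshold: float = EPS_THRESHOLD,
                          p_max: float = P_MAX) -> tuple[float, int]:
    """Pearson r between duplicate GI scores over a chosen strain subset.

    ``subset_rule``: ``all`` (every complete pair), ``passed_variability``
    (both replicate p-values significant) or ``passed_threshold`` (both
    |epsilon| beyond the threshold).  Returns ``(r, n)``; r is NaN with a
    warning when fewer than 3 pairs remain.
    """
    sub = gi_wide
    if subset_rule == "passed_variability":
        sub = sub[(sub["p_rep1"] < p_max) & (sub["p_rep2"] < p_max)]
    elif subset_rule == "passed_threshold":
        sub = sub[(sub["eps_rep1"].abs() > threshold)
                  & (sub["eps_rep2"].abs() > threshold)]
    elif subset_rule != "all":
        raise ValueError(f"unknown subset rule {subset_rule!r}")
    if len(sub) < 3:
        log.warning("replicate correlation undefined for %d pairs", len(sub))
        return float("nan"), len(sub)
    r = float(np.corrcoef(sub["eps_rep1"], sub["eps_rep2"])[0, 1])
    return r, len(sub)


def cross_condition_correlation(calls: pd.DataFrame,
                                construct: str | None = None) -> tuple[float, int]:
    """Pearson r of called eps_mean between -Ura and -Leu/Ura conditions."""
    sub = calls[calls["call"] != "none"]
    if construct is not None:
        sub = sub[sub["construct"] == construct]
    wide = sub.pivot_table(index=["strain_id", "construct"],
                           columns="condition", values="eps_mean",
                           aggfunc="first").dropna()
    if not {"ura_minus", "leu_ura_minus"} <= set(wide.columns) or len(wide) < 3:
        log.warning("cross-condition correlation undefined (%d shared strains)",
                    len(wide))
        return float("nan"), len(wide)
    r = float(np.corrcoef(wide["ura_minus"], wide["leu_ura_minus"])[0, 1])
    return r, len(wide)
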
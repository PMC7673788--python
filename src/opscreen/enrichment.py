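"""Hypergeometric over-representation testing with FDR control.

For a query set of n genes drawn from a universe of N, a term annotating
K universe genes and hitting k query genes is scored by the upper tail
P(X >= k) of Hypergeometric(N, K, n).  The tail is accumulated in log
space for numerical stability.  Benjamini-Hochberg adjustment is applied
across the tested family.  The universe defaults to the genes actually
scored in the screen — only a scored gene could have been called.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .containers import AnnotationSets, ScreenError

log = logging.getLogger(__name__)

MIN_TERM_SIZE = 3


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log space."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ScreenError(f"inconsistent hypergeometric counts "
                          f"(k={k}, K={K}, n={n}, N={N})")
    if k <= max(0, n + K - N):
        return 1.0  # k at or below the support minimum: the tail is certain
    support = np.arange(k, min(K, n) + 1)
    logs = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logs))))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ScreenError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def enrich(query: set[str], sets: AnnotationSets, universe: set[str],
           min_term_size: int = MIN_TERM_SIZE,
           gene_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Over-representation of each annotation term in ``query``.

    Query and terms are intersected with the universe first; terms
    annotating fewer than ``min_term_size`` universe genes are dropped.
    ``gene_map`` optionally collapses allele-level identifiers to genes
    (several alleles of one gene count once) before testing; omit it for
    allele-level counting.

    Returns one row per tested term, sorted by p then term id, with the
    BH-adjusted ``q`` attached across the tested family.
    """
    if gene_map:
        query = {gene_map.get(s, s) for s in query}
        universe = {gene_map.get(s, s) for s in universe}
    universe = set(universe)
    query = set(query) & universe
    if not query:
        raise ScreenError("query is empty after intersection with the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for term_id, (term_name, genes) in sets:
        term_in_universe = genes & universe
        if not term_in_universe:
            log.info("term %s entirely outside the universe; dropped", term_id)
            continue
        K = len(term_in_universe)
        if K < min_term_size:
            continue
        k = len(term_in_universe & query)
        rows.append({
            "term_id": term_id,
            "term_name": term_name,
            "k": k, "K": K, "n": n, "N": N,
            "p": hypergeometric_upper(k, K, n, N),
        })
    result = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K",
                                         "n", "N", "p"])
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
        result = result.sort_values(["p", "term_id"],
                                    kind="mergesort").reset_index(drop=True)
    else:
        result["q"] = pd.Series(dtype=float)
    return result
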
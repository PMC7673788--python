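"""GI score arithmetic, confidence p-values, calling and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from opscreen.scoring import (
    call_interactions,
    cross_condition_correlation,
    gi_score,
    interaction_pvalue,
    permutation_pvalue,
    replicate_correlation,
    score_screen,
    strong_subset,
    widen_gi,
)
from opscreen.normalization import colony_table


# ------------------------------------------------------------- score basics

@pytest.mark.parametrize("w_ab,w_a,w_b,expected", [
    (0.7, 0.9, 1.0, -0.2),
    (1.0, 1.0, 1.0, 0.0),
    (1.2, 0.9, 1.0, 0.3),
])
def test_gi_score_examples(w_ab, w_a, w_b, expected):
    assert gi_score(w_ab, w_a, w_b) == pytest.approx(expected)


@settings(derandomize=True, max_examples=100)
@given(w_a=st.floats(0, 5, allow_nan=False),
       d=st.floats(-1, 1, allow_nan=False))
def test_gi_score_additive_identity(w_a, d):
    """With W_B = 1, a fitness difference d maps to epsilon = d exactly."""
    assert gi_score(w_a + d, w_a) == pytest.approx(d, abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(w_a=st.floats(0, 5, allow_nan=False),
       w1=st.floats(0, 5, allow_nan=False),
       w2=st.floats(0, 5, allow_nan=False))
def test_gi_score_monotone_in_w_ab(w_a, w1, w2):
    lo, hi = sorted((w1, w2))
    assert gi_score(lo, w_a) <= gi_score(hi, w_a)
    # conservation: eps + W_A == W_AB with W_B = 1
    assert gi_score(w1, w_a) + w_a == pytest.approx(w1, abs=1e-9)


# ------------------------------------------------------------------ p-value

def test_pvalue_identical_samples_is_one():
    p = interaction_pvalue([1, 1, 1, 1], [1, 1, 1, 1], pooled_sd=0.05)
    assert p == pytest.approx(1.0, abs=1e-9)


def test_pvalue_matches_permutation_oracle_for_separated_samples():
    """The exact permutation null on 4+4 colonies is 2/70 for full separation."""
    ab, a = [0.5] * 4, [1.0] * 4
    oracle = permutation_pvalue(ab, a)
    assert oracle == pytest.approx(2 / 70)
    p = interaction_pvalue(ab, a, pooled_sd=1e-6)
    assert p < 1e-3  # Welch with a tiny floor is far out in the tail


def test_pvalue_symmetric_under_sample_swap():
    rng = np.random.default_rng(1)
    x = rng.normal(1.0, 0.05, 4)
    y = rng.normal(0.8, 0.05, 4)
    assert interaction_pvalue(x, y, 0.05) == pytest.approx(
        interaction_pvalue(y, x, 0.05))


def test_pvalue_rank_agrees_with_permutation_oracle():
    """Welch-type and permutation p-values order effect sizes identically."""
    rng = np.random.default_rng(7)
    cases = []
    for shift in (0.0, 0.05, 0.15, 0.4):
        x = rng.normal(1.0, 0.05, 4)
        cases.append((x + shift, rng.normal(1.0, 0.05, 4)))
    welch = [interaction_pvalue(x, y, 0.02) for x, y in cases]
    perm = [permutation_pvalue(x, y) for x, y in cases]
    assert np.argsort(welch).tolist() == np.argsort(perm).tolist()


def test_pvalue_requires_two_colonies_per_side():
    with pytest.raises(ValueError):
        interaction_pvalue([1.0], [1.0, 1.0], 0.05)


def test_variance_floor_suppresses_overconfident_calls():
    """Zero within-strain variance must not yield p ~ 0 under a real floor."""
    tight = interaction_pvalue([0.95] * 4, [1.0] * 4, pooled_sd=1e-9)
    floored = interaction_pvalue([0.95] * 4, [1.0] * 4, pooled_sd=0.05)
    assert tight < 1e-6
    assert floored > 0.05


# ------------------------------------------------------------------ calling

def _wide(eps1, eps2, p1=0.01, p2=0.01, **kw):
    row = {"strain_id": "s", "gene": "S", "allele": "s-d",
           "marker_flag": "none", "essentiality": "deletion",
           "construct": "GFP", "condition": "leu_ura_minus",
           "eps_rep1": eps1, "eps_rep2": eps2, "p_rep1": p1, "p_rep2": p2}
    row.update(kw)
    return pd.DataFrame([row])


def test_call_positive_with_mean_attached():
    out = call_interactions(_wide(0.10, 0.09, 0.01, 0.02))
    assert out.loc[0, "call"] == "positive"
    assert out.loc[0, "eps_mean"] == pytest.approx(0.095)


def test_call_requires_threshold_in_each_replicate():
    out = call_interactions(_wide(0.10, 0.05))
    assert out.loc[0, "call"] == "none"
    assert np.isnan(out.loc[0, "eps_mean"])


def test_call_asymmetric_thresholds():
    out = call_interactions(_wide(-0.13, -0.14), threshold_hi=0.16,
                            threshold_lo=-0.12)
    assert out.loc[0, "call"] == "negative"


def test_call_discordant_signs_never_called():
    out = call_interactions(_wide(0.2, -0.2))
    assert out.loc[0, "call"] == "none"


def test_call_requires_significance_in_both_replicates():
    out = call_interactions(_wide(0.2, 0.2, p1=0.01, p2=0.2))
    assert out.loc[0, "call"] == "none"


def test_call_invalid_thresholds_rejected():
    with pytest.raises(ValueError):
        call_interactions(_wide(0.1, 0.1), threshold_lo=0.1)
    with pytest.raises(ValueError):
        call_interactions(_wide(0.1, 0.1), threshold_hi=-0.1)


def test_strong_subset_splits_by_sign_and_magnitude():
    frames = []
    for sid, e in (("a", -0.25), ("b", -0.15), ("c", 0.21)):
        frames.append(_wide(e, e, strain_id=sid))
    calls = call_interactions(pd.concat(frames, ignore_index=True))
    sets = strong_subset(calls, strong_cut=0.2)["GFP"]
    assert sets["op_negative"] == {"a"}
    assert sets["op_positive"] == {"c"}  # b called but not strong


# ------------------------------------------------------------- correlations

def _wide_many(eps1, eps2, p=0.01):
    return pd.DataFrame({
        "strain_id": [f"s{i}" for i in range(len(eps1))],
        "construct": "GFP", "condition": "leu_ura_minus",
        "eps_rep1": eps1, "eps_rep2": eps2,
        "p_rep1": p, "p_rep2": p,
    })


def test_replicate_correlation_identity_and_sign():
    eps = np.array([0.1, 0.2, 0.3, -0.1])
    r, n = replicate_correlation(_wide_many(eps, eps))
    assert r == pytest.approx(1.0)
    r, _ = replicate_correlation(_wide_many(eps, -eps))
    assert r == pytest.approx(-1.0)
    r, _ = replicate_correlation(_wide_many([1, 2, 3], [2, 4, 6]))
    assert r == pytest.approx(1.0)


def test_replicate_correlation_threshold_subset():
    eps1 = np.array([0.10, 0.02, 0.30, -0.20])
    eps2 = np.array([0.12, 0.30, 0.25, -0.25])
    wide = _wide_many(eps1, eps2)
    _, n_all = replicate_correlation(wide, "all")
    _, n_thr = replicate_correlation(wide, "passed_threshold")
    assert n_all == 4
    assert n_thr == 3  # s1 fails |eps| > 0.08 in replicate 1


def test_replicate_correlation_undefined_below_three_pairs(caplog):
    with caplog.at_level("WARNING"):
        r, n = replicate_correlation(_wide_many([0.1, 0.2], [0.1, 0.2]))
    assert np.isnan(r) and n == 2


def test_cross_condition_correlation_identity():
    frames = []
    for cond in ("ura_minus", "leu_ura_minus"):
        for sid, e in (("a", 0.2), ("b", -0.3), ("c", 0.4)):
            frames.append(_wide(e, e, strain_id=sid, condition=cond))
    calls = call_interactions(pd.concat(frames, ignore_index=True))
    r, n = cross_condition_correlation(calls)
    assert n == 3
    assert r == pytest.approx(1.0)


def test_cross_condition_independent_effects_uncorrelated():
    """Independent planted epsilon in the two conditions -> r near 0."""
    rng = np.random.default_rng(42)
    n = 500
    frames = []
    for cond in ("ura_minus", "leu_ura_minus"):
        eps = rng.uniform(0.1, 0.5, n) * rng.choice([-1, 1], n)
        frame = _wide_many(eps, eps)
        frame["condition"] = cond
        frames.append(frame)
    calls = call_interactions(pd.concat(frames, ignore_index=True))
    r, n_shared = cross_condition_correlation(calls)
    assert n_shared > 300
    assert abs(r) < 0.15


# ------------------------------------------------- end-to-end on simulation

def test_planted_interactions_recovered_and_called(small_screen_scored):
    data = small_screen_scored
    per_rep = score_screen(data["colonies"], data["fitness"])
    calls = call_interactions(widen_gi(per_rep))
    calls = calls[calls["condition"] == "leu_ura_minus"].set_index("strain_id")
    ids = {"negative": "yfg0006", "positive": "yfg0010", "weak": "yfg0016"}
    assert calls.loc[ids["negative"], "call"] == "negative"
    assert calls.loc[ids["negative"], "eps_mean"] == pytest.approx(-0.3, abs=0.06)
    assert calls.loc[ids["positive"], "call"] == "positive"
    assert calls.loc[ids["positive"], "eps_mean"] == pytest.approx(0.3, abs=0.06)
    # a 0.05 planted effect sits below the 0.08 per-replicate threshold
    assert calls.loc[ids["weak"], "call"] == "none"


def test_dead_strains_never_scored(small_screen_scored):
    """Marker strains sit below 0.39 but above the dead floor; a truly dead
    strain (vector W < 0.05) must be dropped before scoring."""
    data = small_screen_scored
    fitness = data["fitness"].copy()
    dead = fitness["strain_id"] == "yfg0002"
    fitness.loc[dead & (fitness["construct"] == "vector"), "W"] = 0.01
    per_rep = score_screen(data["colonies"], fitness)
    assert "yfg0002" not in set(per_rep["strain_id"])
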
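"""Colony-size normalization: medians, polish, spatial correction, collapse."""

import numpy as np
import pandas as pd
import pytest

from opscreen import ScreenError, SimConfig, simulate_screen
from opscreen.normalization import (
    collapse_replicates,
    edge_mask,
    group_id_grid,
    normalize_plate,
    plate_median_normalize,
    rowcol_polish,
    spatial_smooth_correct,
    vector_condition_delta,
)

from conftest import make_plate, simple_key


# ---------------------------------------------------------------- edge mask

@pytest.mark.parametrize("shape,depth,expected", [
    ((32, 48), 2, 304),   # 2x(2x48) + 2x(2x28), counted by enumeration
    ((32, 48), 0, 0),
    ((4, 4), 1, 12),
])
def test_edge_mask_counts(shape, depth, expected):
    mask = edge_mask(*shape, depth=depth)
    # independent enumeration over the grid
    count = sum(
        1 for r in range(shape[0]) for c in range(shape[1])
        if r < depth or r >= shape[0] - depth
        or c < depth or c >= shape[1] - depth
    )
    assert count == expected
    assert int(mask.sum()) == expected


def test_edge_mask_too_deep_rejected():
    with pytest.raises(ScreenError):
        edge_mask(4, 4, depth=2)


# ---------------------------------------------------- plate median normalize

def test_uniform_plate_normalizes_to_one():
    plate = make_plate(np.full((6, 6), 500.0))
    out = plate_median_normalize(plate, depth=1)
    np.testing.assert_allclose(out.size, 1.0)


def test_median_scaling_is_exact_arithmetic():
    size = np.zeros((3, 5))
    size[1, 1:4] = [2.0, 4.0, 6.0]
    present = size > 0
    out = plate_median_normalize(make_plate(size, present=present), depth=1)
    np.testing.assert_allclose(out.size[1, 1:4], [0.5, 1.0, 1.5])


def test_marker_colonies_excluded_from_median():
    size = np.zeros((3, 5))
    size[1, 1:4] = [4.0, 4.0, 4.0]
    size[1, 2] = 0.0  # a dead marker colony amid the interior
    marker = np.zeros_like(size, dtype=bool)
    marker[1, 2] = True
    size[1, 1] = 4.0
    size[1, 3] = 4.0
    plate = make_plate(size, present=size >= 0)
    out = plate_median_normalize(plate, marker=marker, depth=1)
    assert out.size[1, 1] == 1.0 and out.size[1, 3] == 1.0


def test_interior_median_exactly_one_after_normalization():
    rng = np.random.default_rng(0)
    size = rng.lognormal(6.0, 0.3, size=(32, 48))
    out = plate_median_normalize(make_plate(size))
    interior = out.size[~edge_mask(32, 48, 2)]
    assert abs(np.median(interior) - 1.0) < 1e-12


def test_all_absent_interior_is_hard_error():
    size = np.zeros((4, 4))
    present = np.zeros((4, 4), dtype=bool)
    present[0, :] = True  # only edge colonies
    size[0, :] = 5.0
    with pytest.raises(ScreenError, match="p1"):
        plate_median_normalize(make_plate(size, present=present), depth=1)


# ----------------------------------------------------------- row/col polish

def test_polish_flattens_pure_row_gradient():
    base = np.ones((12, 16))
    factors = 1.0 + 0.1 * np.arange(12)
    plate = make_plate(base * factors[:, None])
    out = rowcol_polish(plate, depth=1, tol=1e-12)
    interior = out.size[1:-1, 1:-1]
    np.testing.assert_allclose(interior, interior[0, 0], rtol=1e-9)


def test_polish_is_fixed_point_on_flat_plate():
    plate = make_plate(np.ones((8, 8)))
    out = rowcol_polish(plate, depth=1)
    np.testing.assert_allclose(out.size, plate.size, atol=1e-12)


def test_polish_single_colony_unchanged():
    size = np.zeros((5, 5))
    size[2, 2] = 3.0
    plate = make_plate(size, present=size > 0)
    out = rowcol_polish(plate, depth=1)
    # its own row/col median is itself, so it is rescaled to 1 and stays flat
    assert out.size[2, 2] > 0
    again = rowcol_polish(out, depth=1)
    np.testing.assert_allclose(again.size, out.size, atol=1e-12)


# ------------------------------------------------------- spatial correction

def test_spatial_correction_reduces_radial_gradient_cv():
    rows, cols = 32, 48
    y = (np.arange(rows) - (rows - 1) / 2) / ((rows - 1) / 2)
    x = (np.arange(cols) - (cols - 1) / 2) / ((cols - 1) / 2)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    radius = np.sqrt((xx ** 2 + yy ** 2) / 2)
    size = 1.0 + 0.2 * radius
    plate = make_plate(size)
    out = spatial_smooth_correct(plate)
    interior = ~edge_mask(rows, cols, 2)
    cv_before = size[interior].std() / size[interior].mean()
    cv_after = out.size[interior].std() / out.size[interior].mean()
    assert cv_after <= 0.5 * cv_before


def test_spatial_correction_identity_on_flat_plate():
    plate = make_plate(np.ones((10, 12)))
    out = spatial_smooth_correct(plate, depth=1, window=3)
    np.testing.assert_allclose(out.size, 1.0, atol=1e-9)


def test_spatial_outlier_survives_median_correction():
    size = np.ones((16, 16))
    size[8, 8] = 10.0
    out = spatial_smooth_correct(make_plate(size), depth=1)
    # the outlier is judged against its neighborhood, not against itself
    assert out.size[8, 8] > 5.0


def test_spatial_even_window_rejected():
    with pytest.raises(ScreenError):
        spatial_smooth_correct(make_plate(np.ones((8, 8))), window=4)


# --------------------------------------------------------- chain properties

def test_full_chain_idempotent_on_separable_gradient():
    """Re-applying the chain must not change already-corrected sizes."""
    rows, cols = 16, 20
    factors_r = 1.0 + 0.08 * np.arange(rows)
    factors_c = 1.0 + 0.05 * np.arange(cols)
    size = 400.0 * np.outer(factors_r, factors_c)
    size[7:9, 9:11] *= 0.7  # a planted 2x2 strain effect
    plate = make_plate(size)
    once = normalize_plate(plate, depth=2)
    twice = normalize_plate(once, depth=2)
    np.testing.assert_allclose(twice.size, once.size, atol=1e-6)


def test_chain_recovers_planted_effects_under_gradients():
    """Gradient + edge artifacts removed: recovered sizes match planting."""
    config = SimConfig(n_strains=308, constructs=("vector", "GFP"),
                       conditions=("leu_ura_minus",),
                       planted_interactions=[
                           ("yfg0006", "GFP", "leu_ura_minus", -0.3)],
                       gradient=(0.2, 0.15, 0.2), edge_factor=1.4,
                       noise_sd=0.0, baseline_sd=0.0, seed=5)
    plates, key, truth = simulate_screen(config)
    for plate in plates:
        out = normalize_plate(plate, key.marker_mask(plate),
                              group_ids=group_id_grid(key, plate))
        sub = key.for_plate(plate.plate_id)
        scored = sub[~sub["is_control"]]
        expected = np.where(
            (scored["strain_id"] == "yfg0006") & (plate.construct == "GFP"),
            0.7, 1.0)
        got = out.size[scored["row"].to_numpy() - 1,
                       scored["col"].to_numpy() - 1]
        np.testing.assert_allclose(got, expected, rtol=0.02)


# ------------------------------------------------------- replicate collapse

def test_collapse_replicates_mean_sd_and_counts():
    sizes = np.array([[0.9, 1.0], [1.1, 1.0]])
    plate = make_plate(sizes, construct="vector", condition="ura_minus",
                       experiment_replicate="rep1")
    key = pd.DataFrame({
        "plate_id": "p1", "row": [1, 1, 2, 2], "col": [1, 2, 1, 2],
        "strain_id": "A", "replicate_group": "g1",
        "experiment_replicate": "rep1",
    })
    from opscreen import ArrayKey
    fitness = collapse_replicates([plate], ArrayKey(key))
    assert len(fitness) == 1
    assert fitness.loc[0, "W"] == pytest.approx(1.0)
    assert fitness.loc[0, "n_colonies"] == 4
    assert fitness.loc[0, "W_sd"] == pytest.approx(np.std(sizes, ddof=1))


def test_collapse_partial_and_fully_absent_groups():
    sizes = np.array([[1.0, 1.0], [0.0, 0.0]])
    present = np.array([[True, True], [False, False]])
    plate = make_plate(sizes, present=present, construct="vector",
                       condition="ura_minus", experiment_replicate="rep1")
    from opscreen import ArrayKey
    key = ArrayKey(pd.DataFrame({
        "plate_id": "p1", "row": [1, 1, 2, 2], "col": [1, 2, 1, 2],
        "strain_id": ["A", "A", "B", "B"],
        "replicate_group": ["gA", "gA", "gB", "gB"],
        "experiment_replicate": "rep1",
    }))
    fitness = collapse_replicates([plate], key).set_index("strain_id")
    assert fitness.loc["A", "W"] == pytest.approx(1.0)
    assert fitness.loc["A", "n_colonies"] == 2
    assert bool(fitness.loc["B", "excluded"]) is True
    assert np.isnan(fitness.loc["B", "W"])


def test_collapse_identical_values_zero_dispersion():
    plate = make_plate(np.full((1, 4), 1.3), construct="vector",
                       condition="ura_minus", experiment_replicate="rep1")
    from opscreen import ArrayKey
    key = ArrayKey(pd.DataFrame({
        "plate_id": "p1", "row": 1, "col": [1, 2, 3, 4],
        "strain_id": "A", "replicate_group": "gA",
        "experiment_replicate": "rep1",
    }))
    fitness = collapse_replicates([plate], key)
    assert fitness.loc[0, "W"] == pytest.approx(1.3)
    assert fitness.loc[0, "W_sd"] == pytest.approx(0.0)


def test_unmapped_present_colony_is_hard_error():
    plate = make_plate(np.ones((2, 2)), construct="vector",
                       condition="ura_minus", experiment_replicate="rep1")
    from opscreen import ArrayKey
    key = ArrayKey(pd.DataFrame({
        "plate_id": "p1", "row": [1], "col": [1], "strain_id": "A",
        "replicate_group": "gA", "experiment_replicate": "rep1",
    }))
    with pytest.raises(ScreenError, match="not covered"):
        collapse_replicates([plate], key)


# --------------------------------------------------- condition sensitivity

def test_vector_condition_delta_flags_only_large_drops():
    rows = []
    for strain, w_ura, w_lu in (("stable", 1.0, 1.0),
                                ("dropper", 3.1, 1.0),
                                ("riser", 1.0, 1.5)):
        for cond, w in (("ura_minus", w_ura), ("leu_ura_minus", w_lu)):
            rows.append({"strain_id": strain, "construct": "vector",
                         "condition": cond, "experiment_replicate": "rep1",
                         "W": w, "is_control": False, "excluded": False})
    fitness = pd.DataFrame(rows)
    delta = vector_condition_delta(fitness).set_index("strain_id")
    assert delta.loc["stable", "delta_u"] == pytest.approx(0.0)
    assert not delta.loc["stable", "condition_sensitive"]
    assert delta.loc["dropper", "delta_u"] == pytest.approx(-2.1)
    assert bool(delta.loc["dropper", "condition_sensitive"])
    assert delta.loc["riser", "delta_u"] == pytest.approx(0.5)
    assert not delta.loc["riser", "condition_sensitive"]
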
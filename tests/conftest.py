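"""Shared fixtures: tiny hand-built plates and small simulated screens."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from opscreen import ArrayKey, PlateGrid, SimConfig, simulate_screen
from opscreen.normalization import (
    collapse_replicates,
    colony_table,
    group_id_grid,
    normalize_plate,
)
from opscreen.simulate import default_strain_ids


def make_plate(size, plate_id="p1", present=None, **meta) -> PlateGrid:
    """Build a PlateGrid from a 2-D array (absent where present=False)."""
    size = np.asarray(size, dtype=float)
    if present is None:
        present = np.ones_like(size, dtype=bool)
    return PlateGrid(plate_id=plate_id, size=size, present=present, **meta)


def simple_key(plate_ids, n_rows, n_cols, strain_prefix="s") -> ArrayKey:
    """One strain per position (replicate groups of size 1), no markers."""
    rows = []
    for pid in plate_ids:
        for r in range(1, n_rows + 1):
            for c in range(1, n_cols + 1):
                sid = f"{strain_prefix}{r:02d}_{c:02d}"
                rows.append({
                    "plate_id": pid, "row": r, "col": c, "strain_id": sid,
                    "replicate_group": f"{pid}:{sid}",
                    "experiment_replicate": "rep1",
                })
    return ArrayKey(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def planted_ids():
    ids = default_strain_ids(308)
    return {
        "negative": ids[5],
        "positive": ids[9],
        "weak": ids[15],
        "marker": ids[20],
        "low_expr": ids[30],
        "high_expr": ids[31],
        "all": ids,
    }


@pytest.fixture(scope="session")
def small_screen(planted_ids):
    """One-layout-plate screen: vector+GFP, both conditions, mild noise."""
    ids = planted_ids
    planted = []
    for cond, scale in (("leu_ura_minus", 1.0), ("ura_minus", 0.7)):
        planted += [
            (ids["negative"], "GFP", cond, -0.3 * scale),
            (ids["positive"], "GFP", cond, 0.3 * scale),
            (ids["weak"], "GFP", cond, -0.05 * scale),
        ]
    config = SimConfig(
        n_strains=308,
        constructs=("vector", "GFP"),
        planted_interactions=planted,
        planted_expression=[(ids["low_expr"], 0.5), (ids["high_expr"], 2.0)],
        marker_strains=[ids["marker"]],
        noise_sd=0.02,
        baseline_sd=0.05,
        gradient=(0.1, 0.08, 0.15),
        edge_factor=1.25,
        seed=11,
    )
    plates, key, truth = simulate_screen(config)
    return {"config": config, "plates": plates, "key": key, "truth": truth}


@pytest.fixture(scope="session")
def small_screen_scored(small_screen):
    """Normalized fitness + colony table for the small screen."""
    plates, key = small_screen["plates"], small_screen["key"]
    normalized = [
        normalize_plate(p, key.marker_mask(p), group_ids=group_id_grid(key, p))
        for p in plates
    ]
    return {
        **small_screen,
        "normalized": normalized,
        "colonies": colony_table(normalized, key),
        "fitness": collapse_replicates(normalized, key),
    }
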
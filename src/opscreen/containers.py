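"""In-memory containers for colony-array screens.

A screen is a set of plates, each a dense grid of colony measurements
(pixel size plus optional two-channel fluorescence medians), together with
an array key that maps grid positions to mutant strains, replicate groups
and marker flags.  Plates carry their experimental identity (construct,
selection condition, experiment replicate) so downstream joins never rely
on file naming.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: overproduction constructs handled by the pipeline
CONSTRUCTS = ("vector", "GFP", "tGFP", "NES_tGFP")
#: selective media conditions (low / high plasmid copy number)
CONDITIONS = ("ura_minus", "leu_ura_minus")
REPLICATES = ("rep1", "rep2")
MARKER_FLAGS = ("none", "his", "lys", "arg")
ESSENTIALITY = ("deletion", "temperature_sensitive")

DEFAULT_PLATE_FORMAT = (32, 48)


class ScreenError(ValueError):
    """Raised for schema or invariant violations in screen data."""


@dataclasses.dataclass
class PlateGrid:
    """One plate's per-position colony measurements.

    Parameters
    ----------
    plate_id
        Unique plate identifier.
    size
        ``(n_rows, n_cols)`` array of colony sizes in pixels (or in
        normalized units after correction).  Absent colonies are 0.
    present
        Boolean array marking positions where a colony was pinned and
        detected.
    f488, f532
        Optional per-colony fluorescence channel medians (GFP at 488 nm,
        E2-Crimson at 532 nm).  ``None`` for size-only screens.
    construct, condition, experiment_replicate
        Experimental identity of the plate; optional for raw tables but
        required by the scoring stages.
    """

    plate_id: str
    size: np.ndarray
    present: np.ndarray
    f488: np.ndarray | None = None
    f532: np.ndarray | None = None
    construct: str | None = None
    condition: str | None = None
    experiment_replicate: str | None = None

    def __post_init__(self) -> None:
        self.size = np.asarray(self.size, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.size.ndim != 2:
            raise ScreenError(f"plate {self.plate_id}: size must be 2-D")
        if self.present.shape != self.size.shape:
            raise ScreenError(f"plate {self.plate_id}: present/size shape mismatch")
        if np.any(self.size < 0):
            raise ScreenError(f"plate {self.plate_id}: negative colony size")
        # absent colonies carry size 0 by invariant
        self.size = np.where(self.present, self.size, 0.0)
        for ch in ("f488", "f532"):
            arr = getattr(self, ch)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.size.shape:
                    raise ScreenError(f"plate {self.plate_id}: {ch} shape mismatch")
                if np.any(arr[self.present] < 0):
                    raise ScreenError(f"plate {self.plate_id}: negative {ch}")
                setattr(self, ch, arr)

    @property
    def n_rows(self) -> int:
        return self.size.shape[0]

    @property
    def n_cols(self) -> int:
        return self.size.shape[1]

    @property
    def has_fluorescence(self) -> bool:
        return self.f488 is not None and self.f532 is not None

    def copy(self) -> "PlateGrid":
        return PlateGrid(
            plate_id=self.plate_id,
            size=self.size.copy(),
            present=self.present.copy(),
            f488=None if self.f488 is None else self.f488.copy(),
            f532=None if self.f532 is None else self.f532.copy(),
            construct=self.construct,
            condition=self.condition,
            experiment_replicate=self.experiment_replicate,
        )

    def to_frame(self, include_absent: bool = False) -> pd.DataFrame:
        """Long one-row-per-colony view with 1-based ``row``/``col``."""
        rows, cols = np.indices(self.size.shape)
        mask = np.ones_like(self.present) if include_absent else self.present
        out = {
            "plate_id": self.plate_id,
            "row": rows[mask] + 1,
            "col": cols[mask] + 1,
            "size": self.size[mask],
            "present": self.present[mask],
        }
        if self.f488 is not None:
            out["f488"] = self.f488[mask]
        if self.f532 is not None:
            out["f532"] = self.f532[mask]
        frame = pd.DataFrame(out)
        for field in ("construct", "condition", "experiment_replicate"):
            value = getattr(self, field)
            if value is not None:
                frame[field] = value
        return frame


#: canonical array-key columns; ``gene`` and ``is_control`` are package
#: extensions (gene-level collapse for enrichment; border/filler controls).
KEY_COLUMNS = [
    "plate_id",
    "row",
    "col",
    "strain_id",
    "gene",
    "allele",
    "replicate_group",
    "experiment_replicate",
    "marker_flag",
    "essentiality",
    "is_control",
]

_KEY_DEFAULTS: Mapping[str, object] = {
    "marker_flag": "none",
    "essentiality": "deletion",
    "is_control": False,
}


class ArrayKey:
    """Grid-position -> strain mapping with replicate groups.

    Wraps a DataFrame with :data:`KEY_COLUMNS`.  ``replicate_group`` ties
    together the (up to four) adjacent colonies of one strain on one plate;
    ``marker_flag`` marks deletions in the His/Lys/Arg marker pathways that
    only show carryover growth under SGA selection; ``is_control`` marks
    border and filler positions excluded from scoring.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "gene" not in frame.columns and "strain_id" in frame.columns:
            frame["gene"] = frame["strain_id"]
        if "allele" not in frame.columns and "strain_id" in frame.columns:
            frame["allele"] = frame["strain_id"]
        for col, default in _KEY_DEFAULTS.items():
            if col not in frame.columns:
                frame[col] = default
        missing = [c for c in KEY_COLUMNS if c not in frame.columns]
        if missing:
            raise ScreenError(f"array key missing columns: {missing}")
        frame = frame[KEY_COLUMNS].reset_index(drop=True)
        frame["row"] = frame["row"].astype(int)
        frame["col"] = frame["col"].astype(int)
        frame["is_control"] = frame["is_control"].astype(bool)
        bad_flags = set(frame["marker_flag"]) - set(MARKER_FLAGS)
        if bad_flags:
            raise ScreenError(f"unknown marker_flag values: {sorted(bad_flags)}")
        dup = frame.duplicated(subset=["plate_id", "row", "col"])
        if dup.any():
            offender = frame.loc[dup.idxmax()]
            raise ScreenError(
                "duplicate key position "
                f"{offender.plate_id}:({offender.row},{offender.col})"
            )
        counts = frame.groupby("replicate_group")["strain_id"].nunique()
        conflicted = counts[counts > 1]
        if len(conflicted):
            raise ScreenError(
                f"replicate_group maps to multiple strains: "
                f"{list(conflicted.index[:5])}"
            )
        sizes = frame.groupby("replicate_group").size()
        too_big = sizes[sizes > 4]
        if len(too_big):
            raise ScreenError(
                f"replicate_group larger than 4 positions: {list(too_big.index[:5])}"
            )
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def for_plate(self, plate_id: str) -> pd.DataFrame:
        return self.frame[self.frame["plate_id"] == plate_id]

    def marker_mask(self, plate: PlateGrid) -> np.ndarray:
        """Boolean grid marking marker-pathway (his/lys/arg) positions."""
        mask = np.zeros((plate.n_rows, plate.n_cols), dtype=bool)
        sub = self.for_plate(plate.plate_id)
        flagged = sub[sub["marker_flag"] != "none"]
        mask[flagged["row"].to_numpy() - 1, flagged["col"].to_numpy() - 1] = True
        return mask

    def plate_ids(self) -> list[str]:
        return sorted(self.frame["plate_id"].unique())


@dataclasses.dataclass
class AnnotationSets:
    """Named gene sets (GMT-style) for over-representation testing."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ScreenError(f"annotation term {term_id} has an empty gene set")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(sorted(self.terms.items()))

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, (_, gs) in self.terms.items():
            out |= gs
        return frozenset(out)

    def restricted_to(self, universe: Iterable[str]) -> "AnnotationSets":
        """Intersect every term with ``universe``; drop emptied terms."""
        uni = frozenset(universe)
        kept = {}
        for term_id, (name, gs) in self.terms.items():
            inter = gs & uni
            if inter:
                kept[term_id] = (name, inter)
        return AnnotationSets(kept)
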
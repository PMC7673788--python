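"""Readers and writers for every table the pipeline touches.

All inputs are delimiter-separated text with a header line (TSV by
default); annotation sets use the GMT dialect.  Output tables are written
with a fixed sort order and fixed float rendering so repeated runs are
byte-identical.
"""

from __future__ import annotations

import logging
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_PLATE_FORMAT,
    AnnotationSets,
    ArrayKey,
    PlateGrid,
    ScreenError,
)

log = logging.getLogger(__name__)

#: canonical plate-table columns; a schema map can rename any of them to
#: match third-party exports (the source-data adapter is config-driven).
PLATE_COLUMNS = ("plate_id", "row", "col", "size")
PLATE_OPTIONAL = ("f488", "f532", "present", "construct", "condition",
                  "experiment_replicate")


def _apply_schema(frame: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    if schema:
        rename = {v: k for k, v in schema.items()}
        frame = frame.rename(columns=rename)
    return frame


def read_plate_table(
    path: str,
    schema: Mapping[str, str] | None = None,
    plate_format: tuple[int, int] = DEFAULT_PLATE_FORMAT,
    sep: str = "\t",
) -> list[PlateGrid]:
    """Read a colony table (one colony per line) into :class:`PlateGrid` s.

    Parameters
    ----------
    schema
        Optional map from canonical column names (``plate_id``, ``row``,
        ``col``, ``size``, ...) to the file's column names, for adapting
        external exports without code changes.
    plate_format
        ``(n_rows, n_cols)`` of the dense grid; positions not listed in
        the file are marked absent.
    """
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=list(PLATE_COLUMNS))
    frame = _apply_schema(frame, schema)
    if frame.empty:
        log.warning("plate table %s is empty", path)
        return []
    missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ScreenError(f"plate table {path} missing columns: {missing}")

    frame["row"] = frame["row"].astype(int)
    frame["col"] = frame["col"].astype(int)
    dup = frame.duplicated(subset=["plate_id", "row", "col"])
    if dup.any():
        offender = frame.loc[dup.idxmax()]
        raise ScreenError(
            f"duplicate colony position {offender.plate_id}:"
            f"({offender.row},{offender.col}) in {path}"
        )
    if (frame["size"] < 0).any():
        offender = frame.loc[(frame["size"] < 0).idxmax()]
        raise ScreenError(
            f"negative colony size at {offender.plate_id}:"
            f"({offender.row},{offender.col}) in {path}"
        )

    n_rows, n_cols = plate_format
    observed_max = (frame["row"].max(), frame["col"].max())
    if observed_max[0] > n_rows or observed_max[1] > n_cols:
        # accept larger grids than the default if the data demand it
        n_rows = max(n_rows, int(observed_max[0]))
        n_cols = max(n_cols, int(observed_max[1]))
    if (frame["row"] < 1).any() or (frame["col"] < 1).any():
        raise ScreenError(f"rows/cols must be 1-based in {path}")

    plates: list[PlateGrid] = []
    has_fluor = "f488" in frame.columns and "f532" in frame.columns
    for plate_id, sub in frame.groupby("plate_id", sort=True):
        size = np.zeros((n_rows, n_cols))
        present = np.zeros((n_rows, n_cols), dtype=bool)
        r = sub["row"].to_numpy() - 1
        c = sub["col"].to_numpy() - 1
        size[r, c] = sub["size"].to_numpy()
        if "present" in sub.columns:
            present[r, c] = sub["present"].astype(bool).to_numpy()
        else:
            present[r, c] = True
        f488 = f532 = None
        if has_fluor:
            f488 = np.zeros((n_rows, n_cols))
            f532 = np.zeros((n_rows, n_cols))
            f488[r, c] = sub["f488"].to_numpy()
            f532[r, c] = sub["f532"].to_numpy()
        meta = {}
        for field in ("construct", "condition", "experiment_replicate"):
            if field in sub.columns:
                values = sub[field].unique()
                if len(values) > 1:
                    raise ScreenError(
                        f"plate {plate_id} has conflicting {field} values in {path}"
                    )
                meta[field] = values[0]
        plates.append(
            PlateGrid(plate_id=str(plate_id), size=size, present=present,
                      f488=f488, f532=f532, **meta)
        )
    return plates


def write_plate_table(plates: Sequence[PlateGrid], path: str,
                      include_absent: bool = True,
                      float_precision: int = 6) -> None:
    frames = [p.to_frame(include_absent=include_absent) for p in plates]
    frame = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(PLATE_COLUMNS))
    frame = frame.sort_values(["plate_id", "row", "col"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False,
                 float_format=f"%.{float_precision}g")


def read_array_key(path: str, sep: str = "\t") -> ArrayKey:
    """Read the position -> strain mapping; see :class:`ArrayKey`."""
    frame = pd.read_csv(path, sep=sep)
    required = ["plate_id", "row", "col", "strain_id", "replicate_group",
                "experiment_replicate"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ScreenError(f"array key {path} missing columns: {missing}")
    if "marker_flag" in frame.columns:
        frame["marker_flag"] = frame["marker_flag"].fillna("none")
    return ArrayKey(frame)


def write_array_key(key: ArrayKey, path: str) -> None:
    frame = key.frame.sort_values(["plate_id", "row", "col"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False)


def read_annotation_gmt(path: str) -> AnnotationSets:
    """Read GMT: ``term_id<TAB>term_name<TAB>gene1<TAB>gene2...`` per line.

    Lines with fewer than three fields (no genes) are skipped with a
    warning; duplicate gene ids within a line are collapsed.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                log.warning("%s:%d: GMT line without genes skipped", path, lineno)
                continue
            term_id, term_name = fields[0], fields[1]
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if term_id in terms:
                log.warning("%s:%d: duplicate term %s, keeping first", path,
                            lineno, term_id)
                continue
            terms[term_id] = (term_name, genes)
    return AnnotationSets(terms)


def write_annotation_gmt(sets: AnnotationSets, path: str) -> None:
    with open(path, "w") as handle:
        for term_id, (name, genes) in sets:
            handle.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


#: preferred sort keys for result tables, applied in this order when present
_SORT_PRIORITY = ["strain_id", "gene", "construct", "condition",
                  "experiment_replicate", "term_id", "cluster_id",
                  "plate_id", "row", "col", "subset", "pair"]


def write_results_table(records: pd.DataFrame, path: str,
                        float_precision: int = 6) -> None:
    """Write any pipeline output table deterministically.

    Rows are sorted by the available keys of ``strain_id``, ``construct``,
    ``condition`` (then any further identity columns); floats are rendered
    at a fixed precision, so two runs on identical inputs produce
    byte-identical files.
    """
    frame = records.copy()
    keys = [c for c in _SORT_PRIORITY if c in frame.columns]
    if keys:
        frame = frame.sort_values(keys, kind="mergesort")
    directory = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(directory):
        raise ScreenError(f"output directory does not exist: {directory}")
    frame.to_csv(path, sep="\t", index=False,
                 float_format=f"%.{float_precision}g")


def read_results_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
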
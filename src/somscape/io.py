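"""Readers and writers for the formats the workflow touches.

Matrices travel as TSV/CSV with a header row and row ids in the first
column (delimiter sniffed from the extension); gene-set collections as
GMT (set name, description, then member ids, tab-separated); lattices
and trained maps as JSON.  Every writer round-trips through its reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection
from .overlay import OverlayMatrix
from .som import TrainedMap, TrainingMatrix


def _delimiter(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(path, kind: str = "training", impute_mean: bool = False):
    """Read a TSV/CSV matrix as a TrainingMatrix or OverlayMatrix.

    ``kind`` selects the returned container ("training" or "overlay").
    Duplicate row ids and non-numeric cells are errors naming the
    offending row/column.
    """
    if kind not in ("training", "overlay"):
        raise ValueError("kind must be 'training' or 'overlay'")
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing file: {path}")
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    if df.empty:
        raise ValueError(f"empty matrix in {path}")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate row id(s) in {path.name}: {dup[:5]}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rid = df.index[bad.argmax()]
            raise ValueError(
                f"non-numeric cell in {path.name} at row {rid!r}, column {col!r}"
            )
        df[col] = coerced
    if kind == "training":
        return TrainingMatrix.from_frame(df, impute_mean=impute_mean)
    return OverlayMatrix.from_frame(df)


def write_matrix(obj, path) -> None:
    """Write a Training/OverlayMatrix (or codebook frame) as TSV/CSV."""
    df = obj.to_frame() if hasattr(obj, "to_frame") else obj
    df.to_csv(path, sep=_delimiter(path), lineterminator="\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set collection.

    Each line: set name, description (ignored), then gene ids; blank
    gene fields are dropped; fewer than 3 fields or a repeated set name
    is an error with the line number.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path.name}:{lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            genes = {g for g in fields[2:] if g.strip()}
            sets[name] = genes
    return GeneSetCollection(sets, collection_name=path.stem)


def write_gmt(coll: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(coll.sets):
            genes = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def save_map(tm: TrainedMap, path) -> None:
    with open(path, "w") as fh:
        json.dump(tm.to_dict(), fh)


def load_map(path) -> TrainedMap:
    with open(path) as fh:
        return TrainedMap.from_dict(json.load(fh))


def write_hits(hits, path) -> None:
    hits.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_hits(path, n_nodes: int):
    from .som import HitAssignment

    df = pd.read_csv(path, sep="\t")
    bmu = {str(r): int(n) for r, n in zip(df["row_id"], df["node"])}
    counts = np.bincount(list(bmu.values()), minlength=n_nodes)
    return HitAssignment(bmu=bmu, hit_counts=counts)
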
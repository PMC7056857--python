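"""Overlaying non-training data onto a trained map.

Once a map is trained, any other quantity keyed by the same row ids — a
0/1 status vector (e.g. loss-of-function intolerance), expression levels,
per-item phenotype counts — can be projected through the item-to-node
assignment: each node receives the kernel-weighted mean of the overlay
values of the rows whose BMUs lie near it.  The result is an *overlaid
codebook* on the same lattice, directly comparable, node by node, with
the trained codebook; the agreement between two such landscapes is
measured as Pearson's correlation over nodes.

With ``smoothing_sigma = 0`` the overlay degenerates to the plain
per-BMU mean and nodes that received no rows carry NaN (the undefined
marker) — never a silent zero.  Binary overlays are treated as reals, so
a node's value is the occupancy-weighted probability of the status.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import Lattice
from .som import HitAssignment, TrainedMap

logger = logging.getLogger(__name__)


@dataclass
class OverlayMatrix:
    """Rows x overlay-columns of finite reals keyed like the training rows."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("id lengths do not match values shape")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite overlay values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OverlayMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class OverlaidMap:
    """Lattice plus the node-by-overlay-column codebook and coverage."""

    lattice: Lattice
    overlaid_codebook: np.ndarray  # (M, k); NaN marks undefined nodes
    col_ids: list[str]
    coverage: np.ndarray  # (M,) kernel mass behind each node's value
    smoothing_sigma: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.overlaid_codebook,
            index=pd.RangeIndex(self.lattice.n_nodes, name="node"),
            columns=self.col_ids,
        )

    def column(self, name: str) -> np.ndarray:
        if name not in self.col_ids:
            raise KeyError(f"unknown overlay column {name!r}")
        return self.overlaid_codebook[:, self.col_ids.index(name)]


def overlay_map(
    tm: TrainedMap,
    hits: HitAssignment,
    extra: OverlayMatrix,
    smoothing_sigma: float | None = None,
) -> OverlaidMap:
    """Project overlay columns onto the trained map through the BMUs.

    Node value for column c is

        sum_rows h(node, bmu(row)) * extra[row, c] / sum_rows h(node, bmu(row))

    with h a Gaussian kernel over Euclidean map distance of width
    ``smoothing_sigma`` (default: the final fine-tune sigma of the
    training schedule).  ``smoothing_sigma = 0`` gives the plain per-BMU
    mean with NaN on empty nodes.  Overlay rows absent from ``hits`` are
    dropped with a logged count; an overlay sharing no rows with the map
    is an error.
    """
    if smoothing_sigma is None:
        smoothing_sigma = tm.schedule.final_sigma
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be non-negative")

    keep = [i for i, rid in enumerate(extra.row_ids) if rid in hits.bmu]
    if not keep:
        raise ValueError("no overlay rows match the trained map's rows")
    dropped = len(extra.row_ids) - len(keep)
    if dropped:
        logger.info("dropped %d overlay rows absent from the trained map", dropped)

    V = extra.values[keep]
    bmu = np.array([hits.bmu[extra.row_ids[i]] for i in keep], dtype=int)
    M = tm.lattice.n_nodes

    counts = np.bincount(bmu, minlength=M).astype(float)
    sums = np.zeros((M, V.shape[1]))
    np.add.at(sums, bmu, V)

    if smoothing_sigma == 0:
        den = counts
        num = sums
    else:
        pos = tm.lattice.positions
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        H = np.exp(-d2 / (2.0 * smoothing_sigma**2))
        num = H @ sums
        den = H @ counts

    values = np.full((M, V.shape[1]), np.nan)
    ok = den > 0
    values[ok] = num[ok] / den[ok, None]
    return OverlaidMap(
        lattice=tm.lattice,
        overlaid_codebook=values,
        col_ids=list(extra.col_ids),
        coverage=den,
        smoothing_sigma=float(smoothing_sigma),
    )


def map_correspondence(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two node-value columns.

    Nodes undefined (NaN) in either column are excluded pairwise; at
    least 3 defined nodes are required.  A zero-variance column yields
    NaN with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("columns must share the lattice (equal length)")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly defined nodes")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in a correspondence column", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cluster_summary(om: OverlaidMap, clusters, statistic: str = "mean") -> pd.DataFrame:
    """Per-cluster summary of the overlaid node values.

    Returns a DataFrame indexed by cluster id with one column per
    overlay column plus ``n_nodes``; NaN nodes are excluded, and a
    cluster whose nodes are all undefined yields NaN.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if len(clusters.node_labels) != om.lattice.n_nodes:
        raise ValueError("cluster assignment does not match the overlay lattice")
    labels = np.asarray(clusters.node_labels)
    rows = {}
    fn = np.nanmean if statistic == "mean" else np.nanmedian
    for cid in sorted(set(labels.tolist())):
        sel = om.overlaid_codebook[labels == cid]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cluster
            stats = fn(sel, axis=0)
        rows[cid] = list(stats) + [int((labels == cid).sum())]
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(om.col_ids) + ["n_nodes"]
    )
    out.index.name = "cluster"
    return out
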
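"""Batch self-organising map training constrained by a shaped lattice.

The map is a codebook of prototype vectors, one per lattice node, fitted
so that lattice-adjacent nodes carry similar prototypes.  Training is the
classical batch scheme: every row of the training matrix is assigned to
its best-matching unit (BMU, nearest prototype in Euclidean feature
space), then every prototype is replaced by the neighbourhood-kernel
weighted mean of all rows, with a Gaussian kernel over Euclidean *map*
distance whose width sigma shrinks linearly over two phases (rough, then
fine-tune).  Because the lattice is shaped, prototypes exist only for
nodes inside the shape mask — masked-out grid positions are never
represented.

A PCA diagnostic (:func:`pca_shape_hint`) summarises what the data cloud
looks like (boundary, number of density centres) to guide the choice of
map shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.decomposition import PCA

from .lattice import Lattice

logger = logging.getLogger(__name__)

#: nodes whose total kernel mass falls below this keep their old weights
_MIN_KERNEL_MASS = 1e-12


# ------------------------------------------------------------ containers
@dataclass
class TrainingMatrix:
    """Items (e.g. genes) in rows, measures (e.g. tissues) in columns.

    Values must be finite; rows with missing values are rejected unless
    constructed through :meth:`from_frame` with ``impute_mean=True``.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        n, d = self.values.shape
        if n < 2 or d < 1:
            raise ValueError("need at least 2 rows and 1 column")
        if len(self.row_ids) != n or len(self.col_ids) != d:
            raise ValueError("id lengths do not match values shape")
        if len(set(self.row_ids)) != n:
            raise ValueError("duplicate row ids")
        if len(set(self.col_ids)) != d:
            raise ValueError("duplicate column ids")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite values in matrix (use impute_mean to fill)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, impute_mean: bool = False) -> "TrainingMatrix":
        values = df.to_numpy(dtype=float)
        if impute_mean and not np.isfinite(values).all():
            n_bad = int((~np.isfinite(values)).sum())
            logger.info("imputing %d missing cells with column means", n_bad)
            col_mean = np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=0)
            bad = ~np.isfinite(values)
            values[bad] = np.take(col_mean, np.nonzero(bad)[1])
        return cls(values, list(df.index), list(df.columns))


@dataclass
class Codebook:
    """Prototype matrix: one weight vector per lattice node."""

    weights: np.ndarray  # (M, d)
    feature_ids: list[str]

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2D")
        if self.weights.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length does not match weights")
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite codebook weights")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights,
            index=pd.RangeIndex(self.weights.shape[0], name="node"),
            columns=self.feature_ids,
        )


@dataclass
class TrainingSchedule:
    """Metadata of a completed training run."""

    rough_radius: tuple[float, float]
    finetune_radius: tuple[float, float]
    rough_iters: int
    finetune_iters: int
    seed: int
    init: str
    standardize: bool
    diameter: float

    @property
    def final_sigma(self) -> float:
        return self.finetune_radius[1]


@dataclass
class TrainedMap:
    lattice: Lattice
    codebook: Codebook
    schedule: TrainingSchedule
    qe_trace: list[float] = field(default_factory=list)
    #: per-column (mean, sd) applied to training data when standardize=True
    scaling: tuple[np.ndarray, np.ndarray] | None = None

    def to_dict(self) -> dict:
        d = {
            "lattice": self.lattice.to_dict(),
            "codebook": {
                "feature_ids": self.codebook.feature_ids,
                "weights": self.codebook.weights.tolist(),
            },
            "schedule": {
                "rough_radius": list(self.schedule.rough_radius),
                "finetune_radius": list(self.schedule.finetune_radius),
                "rough_iters": self.schedule.rough_iters,
                "finetune_iters": self.schedule.finetune_iters,
                "seed": self.schedule.seed,
                "init": self.schedule.init,
                "standardize": self.schedule.standardize,
                "diameter": self.schedule.diameter,
            },
            "qe_trace": self.qe_trace,
        }
        if self.scaling is not None:
            d["scaling"] = [self.scaling[0].tolist(), self.scaling[1].tolist()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedMap":
        sch = d["schedule"]
        scaling = None
        if d.get("scaling") is not None:
            scaling = (np.array(d["scaling"][0]), np.array(d["scaling"][1]))
        return cls(
            lattice=Lattice.from_dict(d["lattice"]),
            codebook=Codebook(
                np.array(d["codebook"]["weights"], dtype=float),
                list(d["codebook"]["feature_ids"]),
            ),
            schedule=TrainingSchedule(
                rough_radius=tuple(sch["rough_radius"]),
                finetune_radius=tuple(sch["finetune_radius"]),
                rough_iters=int(sch["rough_iters"]),
                finetune_iters=int(sch["finetune_iters"]),
                seed=int(sch["seed"]),
                init=sch["init"],
                standardize=bool(sch["standardize"]),
                diameter=float(sch["diameter"]),
            ),
            qe_trace=list(d["qe_trace"]),
            scaling=scaling,
        )


@dataclass
class HitAssignment:
    """Item -> node mapping and per-node hit counts."""

    bmu: dict[str, int]
    hit_counts: np.ndarray

    def __post_init__(self):
        self.hit_counts = np.asarray(self.hit_counts, dtype=int)
        if int(self.hit_counts.sum()) != len(self.bmu):
            raise ValueError("hit counts do not sum to the number of rows")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"row_id": list(self.bmu.keys()), "node": list(self.bmu.values())}
        )


# ------------------------------------------------------------ diagnostics
@dataclass
class ShapeHint:
    """PCA summary of a data cloud used to pick a map shape."""

    scores: np.ndarray  # (n, 2)
    explained_variance_ratio: np.ndarray  # (2,)
    n_modes: int


def pca_shape_hint(data: TrainingMatrix, n_components: int = 2) -> ShapeHint:
    """Project rows on the top principal components and count density modes.

    The projection is on centred (not scaled) data.  Density modes are
    estimated on a 32x32 2D histogram of the scores, smoothed with a
    fixed-bandwidth Gaussian filter (2 bins): a smoothed bin is a mode
    if it strictly exceeds all 8 neighbours and holds at least 5% of
    the maximum smoothed density.  The smoothing is what makes the count
    reflect density centres rather than sampling noise — a raw histogram
    of a few hundred points has many spurious local maxima.

    Raises ``ValueError("zero variance")`` for a constant matrix.
    """
    if data.shape[0] < 3:
        raise ValueError("need at least 3 rows for a shape hint")
    X = data.values
    if np.all(X == X[0]):
        raise ValueError("zero variance")
    k = min(n_components, X.shape[1], X.shape[0] - 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    if k < 2:  # pad a zero second axis so downstream always sees 2D scores
        scores = np.column_stack([scores, np.zeros(len(scores))])
        evr = np.array([pca.explained_variance_ratio_[0], 0.0])
    else:
        evr = pca.explained_variance_ratio_[:2].copy()

    hist, _, _ = np.histogram2d(scores[:, 0], scores[:, 1], bins=32)
    sm = gaussian_filter(hist, sigma=2.0, mode="constant")
    ps = np.pad(sm, 1)
    is_max = np.ones_like(sm, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_max &= sm > ps[1 + di : 33 + di, 1 + dj : 33 + dj]
    is_max &= sm >= 0.05 * sm.max()
    return ShapeHint(scores=scores, explained_variance_ratio=evr, n_modes=int(is_max.sum()))


# --------------------------------------------------------- initialisation
def init_codebook(
    data: TrainingMatrix, lattice: Lattice, method: str = "linear", seed: int = 0
) -> Codebook:
    """Initial codebook, either PCA-linear or sampled rows.

    ``linear``: each node weight is the data mean plus the node's centred
    map position projected along the first two principal components, the
    map axes scaled so their extremes reach +-2 standard deviations of
    the corresponding component scores.  Falls back to ``random`` (with a
    logged notice) when the data has a single column.  ``random``: rows
    sampled with replacement using ``seed``.
    """
    if method not in ("linear", "random"):
        raise ValueError("method must be 'linear' or 'random'")
    X = data.values
    M = lattice.n_nodes
    if method == "linear" and X.shape[1] < 2:
        logger.info("linear initialisation needs >=2 columns; falling back to random")
        method = "random"
    if method == "random":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, X.shape[0], size=M)
        return Codebook(X[idx].copy(), list(data.col_ids))

    mean = X.mean(axis=0)
    M_tiled = np.tile(mean, (M, 1))
    if np.all(X == X[0]):  # degenerate cloud: every prototype is the mean
        return Codebook(M_tiled, list(data.col_ids))
    k = min(2, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    weights = np.tile(mean, (M, 1))
    pos = lattice.positions
    pos_c = pos - pos.mean(axis=0)
    for axis in range(min(k, 2)):
        span = np.abs(pos_c[:, axis]).max()
        sd = scores[:, axis].std()
        if span <= 0 or sd <= 0:
            continue
        coef = pos_c[:, axis] / span * 2.0 * sd
        weights += coef[:, None] * pca.components_[axis][None, :]
    return Codebook(weights, list(data.col_ids))


# --------------------------------------------------------------- training
def _kernel(lattice: Lattice, sigma: float) -> np.ndarray:
    """(M, M) Gaussian neighbourhood kernel over map distance."""
    pos = lattice.positions
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    if sigma <= 0:
        return np.eye(len(pos))
    return np.exp(-d2 / (2.0 * sigma * sigma))


def _phase_sigmas(start: float, end: float, iters: int) -> np.ndarray:
    if iters == 1:
        return np.array([start], dtype=float)
    return np.linspace(start, end, iters)


def _bmu_indices(weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Nearest prototype per row; ties resolved to the lowest node index."""
    # ||x - m||^2 = ||x||^2 - 2 x.m + ||m||^2 ; argmin ignores ||x||^2.
    # Computed from exact squared distances to keep the tie rule faithful.
    d2 = (
        (X * X).sum(1)[:, None]
        - 2.0 * X @ weights.T
        + (weights * weights).sum(1)[None, :]
    )
    return np.argmin(d2, axis=1)


def batch_update(
    weights: np.ndarray, X: np.ndarray, H: np.ndarray, bmu: np.ndarray
) -> np.ndarray:
    """One batch step: kernel-weighted mean of the rows, per node.

    ``H`` is the node-by-node kernel matrix; nodes receiving almost no
    kernel mass keep their previous weights.
    """
    M = weights.shape[0]
    counts = np.bincount(bmu, minlength=M).astype(float)
    sums = np.zeros_like(weights)
    np.add.at(sums, bmu, X)
    num = H @ sums
    den = H @ counts
    new = weights.copy()
    ok = den >= _MIN_KERNEL_MASS
    new[ok] = num[ok] / den[ok, None]
    return new


def smoothed_distortion(
    weights: np.ndarray, X: np.ndarray, H: np.ndarray, bmu: np.ndarray | None = None
) -> float:
    """Kernel-smoothed distortion sum_i sum_j h(j, bmu_i) ||x_i - m_j||^2."""
    if bmu is None:
        bmu = _bmu_indices(weights, X)
    d2 = (
        (X * X).sum(1)[:, None]
        - 2.0 * X @ weights.T
        + (weights * weights).sum(1)[None, :]
    )
    return float((H[bmu] * np.maximum(d2, 0.0)).sum())


def train_som(
    data: TrainingMatrix,
    lattice: Lattice,
    rough_radius: tuple[float, float] | None = None,
    finetune_radius: tuple[float, float] | None = None,
    rough_iters: int = 10,
    finetune_iters: int = 20,
    seed: int = 0,
    init: str = "linear",
    standardize: bool = False,
) -> TrainedMap:
    """Train a batch SOM on ``data`` constrained to ``lattice``.

    Default radii derive from the lattice's Euclidean diameter D:
    rough phase D/4 -> D/16, fine-tune D/16 -> 0.5.  Sigma decays
    linearly within each phase.  ``qe_trace`` holds the mean row-to-BMU
    distance at the start of every iteration plus one final evaluation
    after the last update (length ``rough_iters + finetune_iters + 1``).
    """
    X = data.values
    if not np.isfinite(X).all():
        raise ValueError("non-finite training data")
    scaling = None
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd
        scaling = (mu, sd)
        data = TrainingMatrix(X, data.row_ids, data.col_ids)

    D = lattice.diameter()
    if rough_radius is None:
        rough_radius = (max(D / 4.0, 0.5), max(D / 16.0, 0.5))
    if finetune_radius is None:
        finetune_radius = (max(D / 16.0, 0.5), 0.5)
    for name, (s, e) in (("rough", rough_radius), ("finetune", finetune_radius)):
        if s <= 0 or e <= 0 or s < e:
            raise ValueError(f"{name} radii must be positive with start >= end")

    cb = init_codebook(data, lattice, method=init, seed=seed)
    weights = cb.weights.copy()
    sigmas = np.concatenate(
        [
            _phase_sigmas(*rough_radius, rough_iters),
            _phase_sigmas(*finetune_radius, finetune_iters),
        ]
    )
    qe_trace: list[float] = []
    for sigma in sigmas:
        H = _kernel(lattice, float(sigma))
        bmu = _bmu_indices(weights, X)
        qe_trace.append(float(np.linalg.norm(X - weights[bmu], axis=1).mean()))
        weights = batch_update(weights, X, H, bmu)
    bmu = _bmu_indices(weights, X)
    qe_trace.append(float(np.linalg.norm(X - weights[bmu], axis=1).mean()))

    return TrainedMap(
        lattice=lattice,
        codebook=Codebook(weights, list(data.col_ids)),
        schedule=TrainingSchedule(
            rough_radius=tuple(map(float, rough_radius)),
            finetune_radius=tuple(map(float, finetune_radius)),
            rough_iters=rough_iters,
            finetune_iters=finetune_iters,
            seed=seed,
            init=init,
            standardize=standardize,
            diameter=D,
        ),
        qe_trace=qe_trace,
        scaling=scaling,
    )


def best_matching_unit(codebook: Codebook, row: np.ndarray) -> int:
    """Index of the nearest prototype (Euclidean; ties -> lowest index)."""
    row = np.asarray(row, dtype=float)
    if row.shape != (codebook.weights.shape[1],):
        raise ValueError("row length does not match codebook features")
    if not np.isfinite(row).all():
        raise ValueError("non-finite row")
    return int(_bmu_indices(codebook.weights, row[None, :])[0])


def map_assignments(tm: TrainedMap, data: TrainingMatrix) -> HitAssignment:
    """Assign every row of ``data`` to its BMU on the trained map.

    Columns are matched by id (reordered if needed); data is scaled by
    the map's stored standardisation, if any.
    """
    if set(data.col_ids) != set(tm.codebook.feature_ids):
        raise ValueError("column ids do not match the trained map's features")
    df = data.to_frame()[tm.codebook.feature_ids]
    X = df.to_numpy(dtype=float)
    if tm.scaling is not None:
        mu, sd = tm.scaling
        X = (X - mu) / sd
    bmu = _bmu_indices(tm.codebook.weights, X)
    counts = np.bincount(bmu, minlength=tm.lattice.n_nodes)
    return HitAssignment(
        bmu={rid: int(b) for rid, b in zip(data.row_ids, bmu)}, hit_counts=counts
    )
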
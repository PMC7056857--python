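"""Synthetic fixtures with the structure the workflow assumes.

Real inputs to this kind of analysis are gene-level matrices with a few
distinct density centres (e.g. per-tissue eQTL significance, per-
phenotype mutation indices), binary status vectors correlated with those
centres (e.g. loss-of-function intolerance), and annotation collections
in which some sets track the centres.  The generators here produce
exactly that minimal structure — a Gaussian mixture over rows, per-group
Bernoulli status, and planted/decoy gene sets — fully determined by a
seed, so every pipeline stage can be exercised and benchmarked without
any external download.

Default sizes (hundreds of genes, ~ten measures, 2-4 groups) mirror the
shape of typical gene-by-tissue or gene-by-phenotype inputs at a scale
where tests run in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enrich import GeneSetCollection
from .overlay import OverlayMatrix
from .som import TrainingMatrix


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``group_centres`` is (k, d); ``status_probs`` gives each group's
    Bernoulli rate for the binary status column; each planted set is a
    ``(target_group, purity, background_rate)`` triple: the set keeps
    ``purity`` of its group's genes and adds ``background_rate`` of the
    rest.
    """

    n_genes: int = 600
    n_measures: int = 4
    k_groups: int = 3
    group_centres: np.ndarray | None = None
    noise_sd: float = 1.0
    status_probs: tuple[float, ...] = (0.8, 0.1, 0.1)
    planted_sets: list[tuple[int, float, float]] = field(
        default_factory=lambda: [(1, 0.8, 0.05)]
    )
    seed: int = 0

    def __post_init__(self):
        if self.k_groups < 1:
            raise ValueError("k_groups must be >= 1")
        if self.k_groups > self.n_genes:
            raise ValueError("more groups than genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.group_centres is None:
            self.group_centres = default_centres(self.k_groups, self.n_measures)
        self.group_centres = np.asarray(self.group_centres, dtype=float)
        if self.group_centres.shape != (self.k_groups, self.n_measures):
            raise ValueError("group_centres must be (k_groups, n_measures)")
        if any(not 0 <= p <= 1 for p in self.status_probs):
            raise ValueError("status probabilities must lie in [0, 1]")


def default_centres(k: int, d: int, separation: float = 8.0) -> np.ndarray:
    """Equidistant mixture centres: every pairwise distance = ``separation``.

    Groups sit at the vertices of a regular simplex (scaled coordinate
    axes, re-centred on the origin), the standard layout for
    planted-partition benchmarks.
    """
    centres = np.zeros((k, d))
    if k == 1:
        return centres
    if k > d:
        raise ValueError("need d >= k measures for equidistant centres")
    s = separation / np.sqrt(2.0)
    for g in range(k):
        centres[g, g] = s
    return centres - centres.mean(axis=0)


def gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def group_labels(n_genes: int, k: int) -> np.ndarray:
    """Deterministic group labels 0..k-1, sizes as equal as possible."""
    return np.arange(n_genes) % k


def simulate_matrix(spec: SyntheticSpec) -> tuple[TrainingMatrix, np.ndarray]:
    """Gaussian-mixture training matrix plus the true group labels."""
    rng = np.random.default_rng(spec.seed)
    labels = group_labels(spec.n_genes, spec.k_groups)
    X = spec.group_centres[labels] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, spec.n_measures)
    )
    cols = [f"m{j}" for j in range(spec.n_measures)]
    return TrainingMatrix(X, gene_ids(spec.n_genes), cols), labels


def simulate_status(
    labels: np.ndarray, status_probs, seed: int, column: str = "status"
) -> OverlayMatrix:
    """One binary overlay column: Bernoulli per gene at its group's rate."""
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(status_probs, dtype=float)
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("status probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    status = (rng.random(len(labels)) < probs[labels]).astype(float)
    return OverlayMatrix(status[:, None], gene_ids(len(labels)), [column])


def simulate_genesets(
    labels: np.ndarray,
    planted_sets: list[tuple[int, float, float]],
    n_decoys: int,
    seed: int,
    collection_name: str = "synthetic",
) -> GeneSetCollection:
    """Gene sets with planted enrichments plus uniform decoys.

    Planted set i contains a ``purity`` fraction of its target group's
    genes and a ``background_rate`` fraction of the remaining genes.
    Decoys are uniform samples of the universe (size drawn between 5%
    and 20% of it), carrying no signal.
    """
    labels = np.asarray(labels, dtype=int)
    ids = np.array(gene_ids(len(labels)))
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {}
    for i, (grp, purity, bg) in enumerate(planted_sets):
        if not (0 <= purity <= 1 and 0 <= bg <= 1):
            raise ValueError("purity and background rate must lie in [0, 1]")
        members = ids[labels == grp]
        others = ids[labels != grp]
        take_m = rng.random(len(members)) < purity
        take_o = rng.random(len(others)) < bg
        sets[f"planted_g{grp}_{i}"] = set(members[take_m]) | set(others[take_o])
    for j in range(n_decoys):
        size = int(rng.integers(max(1, len(ids) // 20), max(2, len(ids) // 5)))
        sets[f"decoy_{j}"] = set(rng.choice(ids, size=size, replace=False))
    if not sets:
        raise ValueError("empty collection: no planted sets and no decoys")
    return GeneSetCollection(sets, collection_name)


# ------------------------------------------------------- named fixtures
def two_blob_fixture(
    seed: int = 7, n_genes: int = 400, n_measures: int = 4
) -> tuple[TrainingMatrix, np.ndarray]:
    """Two groups separated by 8 noise SDs — one per map wing."""
    spec = SyntheticSpec(
        n_genes=n_genes,
        n_measures=n_measures,
        k_groups=2,
        noise_sd=1.0,
        status_probs=(0.8, 0.1),
        seed=seed,
    )
    return simulate_matrix(spec)


def three_group_fixture(
    seed: int = 11, n_genes: int = 600, n_measures: int = 4
) -> tuple[TrainingMatrix, np.ndarray]:
    """Three equidistant groups — one per trefoil leaf."""
    spec = SyntheticSpec(
        n_genes=n_genes,
        n_measures=n_measures,
        k_groups=3,
        noise_sd=1.0,
        status_probs=(0.8, 0.1, 0.1),
        seed=seed,
    )
    return simulate_matrix(spec)
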
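"""Region-growing partition of a trained map into contiguous clusters.

The codebook induces a height landscape on the lattice: the *U-height*
of a node is the mean feature-space distance between its prototype and
those of its lattice neighbours.  Valleys of this landscape are
homogeneous regions; ridges are cluster boundaries.  The partition grows
regions by steepest descent: every node points to its lowest neighbour
(lexicographic on (height, index), with a plateau tolerance), pointer
paths collect nodes into the basin of a local minimum, and basins that
touch through equal-height nodes are merged so float-level plateaus do
not fragment.  Every cluster is contiguous by construction — pointer
paths are adjacency paths — which is the contract the downstream
by-cluster summaries and enrichment tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .som import HitAssignment, TrainedMap


@dataclass
class UHeight:
    """Per-node mean codebook distance to lattice neighbours."""

    heights: np.ndarray

    def __len__(self) -> int:
        return len(self.heights)


@dataclass
class ClusterAssignment:
    """Node -> cluster labels (1..K, each cluster connected) and seeds."""

    node_labels: np.ndarray  # (M,) ints in 1..K
    seeds: dict[int, int]  # cluster id -> seed node index
    gene_labels: dict[str, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.seeds)

    def nodes_of(self, cid: int) -> np.ndarray:
        return np.nonzero(self.node_labels == cid)[0]

    def genes_of(self, cid: int) -> set[str]:
        return {g for g, c in self.gene_labels.items() if c == cid}

    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": np.arange(len(self.node_labels)), "cluster": self.node_labels}
        )

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"row_id": list(self.gene_labels), "cluster": list(self.gene_labels.values())}
        )


def compute_uheight(tm: TrainedMap) -> UHeight:
    """Mean Euclidean distance from each prototype to its neighbours'."""
    W = tm.codebook.weights
    heights = np.zeros(len(W))
    for i, nbrs in enumerate(tm.lattice.adjacency):
        if nbrs:
            idx = sorted(nbrs)
            heights[i] = np.linalg.norm(W[idx] - W[i], axis=1).mean()
    return UHeight(heights)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # deterministic: smaller root wins
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def partition_map(
    tm: TrainedMap, plateau_tol: float = 1e-12, min_depth: float = 0.15
) -> ClusterAssignment:
    """Steepest-descent basin partition of the U-height landscape.

    ``plateau_tol`` is relative to the height range: two heights within
    ``plateau_tol * (max - min)`` count as equal, both for the descent
    rule and for merging basins that touch across a plateau.

    ``min_depth`` is a persistence floor, also relative to the height
    range: after the descent, any basin separated from a neighbour by a
    saddle rising less than ``min_depth * (max - min)`` above the
    shallower basin's minimum is merged into that neighbour (smallest
    depth first).  Sampling noise in a fitted codebook always carves a
    few spurious shallow dips into an otherwise homogeneous region;
    genuine cluster boundaries ride ridges several times deeper, so this
    floor removes the noise basins without touching real boundaries.
    Set ``min_depth=0`` for the raw basin partition.

    The result labels every node with a cluster id 1..K (ordered by
    seed node index); each cluster's induced subgraph is connected.
    """
    import networkx as nx

    if not nx.is_connected(tm.lattice.graph()):
        raise ValueError("lattice must be connected")
    h = compute_uheight(tm).heights
    M = len(h)
    tol = float(plateau_tol) * float(h.max() - h.min()) if M > 1 else 0.0

    def lower(i: int, j: int) -> bool:
        """(h_i, i) strictly below (h_j, j), heights compared with tol."""
        if h[i] < h[j] - tol:
            return True
        if h[j] < h[i] - tol:
            return False
        return i < j

    pointer = np.full(M, -1, dtype=int)
    for i in range(M):
        nbrs = sorted(tm.lattice.adjacency[i])
        if not nbrs:
            continue
        best = min(nbrs, key=lambda j: (h[j], j))
        if lower(best, i):
            pointer[i] = best

    # resolve pointer paths to basin roots (paths are finite: strictly
    # decreasing in (height, index) up to tol, and tie-chains decrease index)
    root = np.full(M, -1, dtype=int)

    def find_root(i: int) -> int:
        path = []
        while root[i] < 0 and pointer[i] >= 0:
            path.append(i)
            i = pointer[i]
        r = root[i] if root[i] >= 0 else i
        for p in path:
            root[p] = r
        root[i] = r
        return r

    for i in range(M):
        find_root(i)

    seeds_list = sorted(set(root.tolist()))
    uf = _UnionFind(M)
    # merge basins whose shared plateau sits at both seeds' level: flat
    # minima must not fragment, but flat ridges must not fuse two wells
    for i in range(M):
        for j in tm.lattice.adjacency[i]:
            if (
                j > i
                and root[i] != root[j]
                and abs(h[i] - h[j]) <= tol
                and abs(h[i] - h[root[i]]) <= tol
                and abs(h[j] - h[root[j]]) <= tol
            ):
                uf.union(root[i], root[j])
    merged_root = {s: uf.find(s) for s in seeds_list}
    basin = np.array([merged_root[root[i]] for i in range(M)], dtype=int)

    # persistence merging: dissolve basins behind shallow saddles
    depth_tol = float(min_depth) * float(h.max() - h.min()) if M > 1 else 0.0
    while depth_tol > 0:
        roots = sorted(set(basin.tolist()))
        if len(roots) <= 1:
            break
        bmin = {s: h[basin == s].min() for s in roots}
        saddle: dict[tuple[int, int], float] = {}
        for i in range(M):
            for j in tm.lattice.adjacency[i]:
                a, b = int(basin[i]), int(basin[j])
                if a != b:
                    key = (min(a, b), max(a, b))
                    v = max(h[i], h[j])
                    if v < saddle.get(key, np.inf):
                        saddle[key] = v
        depths = {
            (a, b): s - max(bmin[a], bmin[b]) for (a, b), s in saddle.items()
        }
        (a, b), d = min(depths.items(), key=lambda kv: (kv[1], kv[0]))
        if d >= depth_tol:
            break
        # the deeper basin absorbs the shallower; ties keep the lower root
        keep, drop = (a, b) if (bmin[a], a) <= (bmin[b], b) else (b, a)
        basin[basin == drop] = keep

    final_seeds = sorted(set(basin.tolist()))
    label_of = {s: k + 1 for k, s in enumerate(final_seeds)}
    node_labels = np.array([label_of[b] for b in basin], dtype=int)
    return ClusterAssignment(
        node_labels=node_labels, seeds={label_of[s]: s for s in final_seeds}
    )


def assign_genes(ca: ClusterAssignment, hits: HitAssignment) -> ClusterAssignment:
    """Label every item with the cluster of its best-matching node."""
    if len(hits.hit_counts) != len(ca.node_labels):
        raise ValueError("hit assignment does not match the clustered lattice")
    gene_labels = {g: int(ca.node_labels[b]) for g, b in hits.bmu.items()}
    return ClusterAssignment(
        node_labels=ca.node_labels.copy(), seeds=dict(ca.seeds), gene_labels=gene_labels
    )


def merge_to_max_clusters(
    ca: ClusterAssignment, tm: TrainedMap, k_max: int
) -> ClusterAssignment:
    """Optional ceiling: greedily merge adjacent clusters until K <= k_max.

    At each step the pair of lattice-adjacent clusters whose seed
    prototypes are closest in feature space is merged (the smaller id is
    kept), so contiguity is preserved.  The emergent cluster count of
    :func:`partition_map` is data-driven; this post-hoc step exists only
    for users who need an upper bound.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    labels = ca.node_labels.copy()
    seeds = dict(ca.seeds)
    alias = {cid: cid for cid in seeds}  # original id -> surviving id
    W = tm.codebook.weights
    while len(seeds) > k_max:
        pairs = set()
        for i, nbrs in enumerate(tm.lattice.adjacency):
            for j in nbrs:
                a, b = int(labels[i]), int(labels[j])
                if a != b:
                    pairs.add((min(a, b), max(a, b)))
        if not pairs:
            break
        a, b = min(
            pairs, key=lambda p: (np.linalg.norm(W[seeds[p[0]]] - W[seeds[p[1]]]), p)
        )
        labels[labels == b] = a
        del seeds[b]
        for orig, cur in alias.items():
            if cur == b:
                alias[orig] = a
    relabel = {old: k + 1 for k, old in enumerate(sorted(seeds))}
    out = ClusterAssignment(
        node_labels=np.array([relabel[int(c)] for c in labels], dtype=int),
        seeds={relabel[old]: s for old, s in seeds.items()},
    )
    out.gene_labels = {g: relabel[alias[c]] for g, c in ca.gene_labels.items()}
    return out
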
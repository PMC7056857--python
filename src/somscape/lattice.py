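"""Shaped map lattices.

A lattice is the geometric scaffold of the whole workflow: a set of map
nodes with 2D positions and unit-spacing adjacency, cut to a named shape.
Unlike the ubiquitous rectangular "sheet", shaped lattices (diamond,
triangle, butterfly, trefoil, ...) let the map mirror the geometry of the
data cloud — e.g. a butterfly for two density centres, a trefoil for
three — so that self-organised groups land on visually separate parts of
the map.

Hexagonal shapes are generated on axial coordinates ``(q, r)`` with
Euclidean position ``x = q + r/2``, ``y = r*sqrt(3)/2``; candidates are
enumerated over ``q, r in [-3*scale, 3*scale]`` and kept iff they satisfy
the shape mask.  The ``square`` shape uses a rectangular grid with
4-neighbour adjacency.  Adjacent nodes are always at Euclidean distance 1.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

SQRT3 = math.sqrt(3.0)

#: axial offsets of the six hexagonal neighbours
_HEX_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))
_SQUARE_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1))

SHAPE_NAMES = (
    "sheet",
    "hexagon",
    "diamond",
    "triangle",
    "butterfly",
    "trefoil",
    "square",
    "custom",
)

# float slack for boundary membership of the Euclidean masks
_EPS = 1e-9


@dataclass(frozen=True)
class GridNode:
    """A single map unit: a stable index and a 2D Euclidean position."""

    index: int
    position: tuple[float, float]

    @property
    def x(self) -> float:
        return self.position[0]

    @property
    def y(self) -> float:
        return self.position[1]


@dataclass
class Lattice:
    """A shaped set of map nodes plus their unit-distance adjacency.

    Attributes
    ----------
    nodes : list[GridNode]
        Ordered by (y, x) of position; indices are 0..M-1 with no gaps.
    adjacency : list[set[int]]
        ``adjacency[i]`` is the set of neighbours of node ``i``; the
        relation is symmetric and irreflexive, and the graph is connected.
    grid_kind : str
        ``"hexagonal"`` or ``"rectangular"``.
    shape_name : str
        One of :data:`SHAPE_NAMES`.
    scale : int
        The linear size parameter ``R`` of the shape masks.
    meta : dict
        Generation metadata (e.g. nodes dropped to keep connectivity).
    """

    nodes: list[GridNode]
    adjacency: list[set[int]]
    grid_kind: str
    shape_name: str
    scale: int
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def positions(self) -> np.ndarray:
        """(M, 2) array of node positions, row i = node i."""
        return np.array([n.position for n in self.nodes], dtype=float)

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Sorted list of (i, j) with i < j."""
        out = set()
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                out.add((min(i, j), max(i, j)))
        return sorted(out)

    def neighbors(self, node: int) -> set[int]:
        """Adjacency set of ``node`` (never contains ``node`` itself)."""
        if not 0 <= node < len(self.nodes):
            raise IndexError(f"node index {node} out of range [0, {len(self.nodes)})")
        return set(self.adjacency[node])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        g.add_edges_from(self.edges)
        return g

    def diameter(self) -> float:
        """Largest Euclidean distance between any two node positions."""
        pos = self.positions
        # M is small (<= a few thousand); the dense pairwise form is fine
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))

    # ---------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return {
            "shape_name": self.shape_name,
            "scale": self.scale,
            "grid_kind": self.grid_kind,
            "nodes": [{"index": n.index, "x": n.x, "y": n.y} for n in self.nodes],
            "edges": [list(e) for e in self.edges],
            "meta": self.meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "Lattice":
        nodes = [
            GridNode(int(n["index"]), (float(n["x"]), float(n["y"])))
            for n in sorted(d["nodes"], key=lambda n: n["index"])
        ]
        adjacency: list[set[int]] = [set() for _ in nodes]
        for i, j in d["edges"]:
            adjacency[i].add(j)
            adjacency[j].add(i)
        return cls(
            nodes=nodes,
            adjacency=adjacency,
            grid_kind=d["grid_kind"],
            shape_name=d["shape_name"],
            scale=int(d["scale"]),
            meta=dict(d.get("meta", {})),
        )

    @classmethod
    def from_json(cls, path) -> "Lattice":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ----------------------------------------------------------------- masks
def _mask_sheet(q, r, x, y, R):
    return abs(q) <= R and abs(r) <= R


def _mask_hexagon(q, r, x, y, R):
    return abs(q) <= R and abs(r) <= R and abs(q + r) <= R


def _diamond_at(x, y, cx, R):
    return abs(x - cx) / R + abs(y) / (R * SQRT3 / 2.0) <= 1.0 + _EPS


def _mask_diamond(q, r, x, y, R):
    return _diamond_at(x, y, 0.0, R)


def _mask_triangle(q, r, x, y, R):
    return y >= -_EPS and abs(x) <= R * (1.0 - y / (R * SQRT3)) + _EPS


def _mask_butterfly(q, r, x, y, R):
    # two diamond wings meeting at a waist column
    return _diamond_at(x, y, -0.7 * R, R) or _diamond_at(x, y, 0.7 * R, R)


def _mask_trefoil(q, r, x, y, R):
    # three leaves at 90, 210, 330 degrees plus a connecting central disc
    leaf_r2 = (0.55 * R) ** 2 + _EPS
    centre_r2 = (0.35 * R) ** 2 + _EPS
    if x * x + y * y <= centre_r2:
        return True
    for ang in (90.0, 210.0, 330.0):
        a = math.radians(ang)
        cx, cy = 0.65 * R * math.cos(a), 0.65 * R * math.sin(a)
        if (x - cx) ** 2 + (y - cy) ** 2 <= leaf_r2:
            return True
    return False


_HEX_MASKS = {
    "sheet": _mask_sheet,
    "hexagon": _mask_hexagon,
    "diamond": _mask_diamond,
    "triangle": _mask_triangle,
    "butterfly": _mask_butterfly,
    "trefoil": _mask_trefoil,
}


def build_lattice(shape_name: str, scale: int, custom_mask=None) -> Lattice:
    """Construct a shaped map lattice.

    Parameters
    ----------
    shape_name : str
        One of :data:`SHAPE_NAMES`.
    scale : int
        Positive linear size ``R`` of the shape.
    custom_mask : callable, optional
        Predicate ``mask(x, y) -> bool`` over Euclidean position; only
        allowed (and required) with ``shape_name="custom"``, which cuts a
        hexagonal grid by the predicate.

    Returns
    -------
    Lattice
        Connected; if the mask produced several components only the
        largest is retained (reported in ``meta["dropped_nodes"]``).

    Raises
    ------
    ValueError
        For an unknown shape, non-positive scale, a mask that keeps no
        node ("empty lattice"), or a misused ``custom_mask``.
    """
    if shape_name not in SHAPE_NAMES:
        raise ValueError(f"unknown shape {shape_name!r}; expected one of {SHAPE_NAMES}")
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    if (custom_mask is not None) != (shape_name == "custom"):
        raise ValueError("custom_mask must be given iff shape_name='custom'")

    R = scale
    if shape_name == "square":
        keys, positions = [], []
        for row in range(-R, R + 1):
            for col in range(-R, R + 1):
                keys.append((row, col))
                positions.append((float(col), float(row)))
        offsets = _SQUARE_OFFSETS
        grid_kind = "rectangular"
    else:
        if shape_name == "custom":
            mask = lambda q, r, x, y, R: bool(custom_mask(x, y))  # noqa: E731
        else:
            mask = _HEX_MASKS[shape_name]
        keys, positions = [], []
        # deterministic (r, q) order == (y, x) order since y is monotone in r
        for r in range(-3 * R, 3 * R + 1):
            for q in range(-3 * R, 3 * R + 1):
                x = q + r / 2.0
                y = r * SQRT3 / 2.0
                if mask(q, r, x, y, R):
                    keys.append((r, q))
                    positions.append((x, y))
        offsets = _HEX_OFFSETS
        grid_kind = "hexagonal"

    if not keys:
        raise ValueError("empty lattice")

    index_of = {k: i for i, k in enumerate(keys)}
    adjacency: list[set[int]] = [set() for _ in keys]
    for i, (a, b) in enumerate(keys):
        for da, db in offsets:
            # hex keys are (r, q) with offsets (dq, dr); square keys are
            # (row, col) with offsets (dcol, drow) — symmetric, so applying
            # the offset to both coordinates in swapped order is exact
            j = index_of.get((a + db, b + da))
            if j is not None:
                adjacency[i].add(j)

    meta: dict = {}
    g = nx.Graph()
    g.add_nodes_from(range(len(keys)))
    g.add_edges_from((i, j) for i, nbrs in enumerate(adjacency) for j in nbrs)
    components = list(nx.connected_components(g))
    if len(components) > 1:
        keep = max(components, key=lambda c: (len(c), -min(c)))
        dropped = len(keys) - len(keep)
        warnings.warn(
            f"mask produced {len(components)} components; "
            f"keeping the largest ({len(keep)} nodes, {dropped} dropped)",
            stacklevel=2,
        )
        meta["dropped_nodes"] = dropped
        meta["n_components_before"] = len(components)
        old = sorted(keep)
        remap = {o: n for n, o in enumerate(old)}
        positions = [positions[o] for o in old]
        adjacency = [{remap[j] for j in adjacency[o] if j in keep} for o in old]

    nodes = [GridNode(i, (px, py)) for i, (px, py) in enumerate(positions)]
    return Lattice(
        nodes=nodes,
        adjacency=adjacency,
        grid_kind=grid_kind,
        shape_name=shape_name,
        scale=scale,
        meta=meta,
    )


def lattice_neighbors(lattice: Lattice, node: int) -> set[int]:
    """Adjacency set of ``node`` in ``lattice`` (accessor form)."""
    return lattice.neighbors(node)
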
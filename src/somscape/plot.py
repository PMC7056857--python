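"""Landscape rendering: one shaded polygon per map node.

A landscape (component plane) shades every lattice node by one column of
a trained or overlaid codebook — hexagons on hexagonal lattices, squares
on rectangular ones — with a colour bar.  Output format follows the file
extension (SVG or PNG); content is deterministic for fixed inputs.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PolyCollection

from .overlay import OverlaidMap
from .som import TrainedMap

#: circumradius of a unit-spacing pointy-top hexagon
_HEX_R = 1.0 / math.sqrt(3.0)


def _node_values(obj, column: str) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(obj, TrainedMap):
        if column not in obj.codebook.feature_ids:
            raise KeyError(f"unknown column {column!r}")
        vals = obj.codebook.weights[:, obj.codebook.feature_ids.index(column)]
        return obj.lattice.positions, vals, obj.lattice.grid_kind
    if isinstance(obj, OverlaidMap):
        vals = obj.column(column)
        return obj.lattice.positions, vals, obj.lattice.grid_kind
    raise TypeError("expected a TrainedMap or OverlaidMap")


def _polygon(x: float, y: float, grid_kind: str) -> list[tuple[float, float]]:
    if grid_kind == "hexagonal":
        return [
            (x + _HEX_R * math.cos(math.radians(30 + 60 * k)),
             y + _HEX_R * math.sin(math.radians(30 + 60 * k)))
            for k in range(6)
        ]
    h = 0.5
    return [(x - h, y - h), (x + h, y - h), (x + h, y + h), (x - h, y + h)]


def render_landscape(obj, column: str, out_path, cmap: str = "viridis") -> None:
    """Render one codebook column of a (trained or overlaid) map to file.

    NaN (undefined) nodes are drawn hatched grey.  The colour scale
    spans the finite value range of the column.
    """
    positions, values, grid_kind = _node_values(obj, column)
    finite = np.isfinite(values)
    polys = [_polygon(x, y, grid_kind) for x, y in positions]

    fig, ax = plt.subplots(figsize=(6, 6))
    vmin = float(values[finite].min()) if finite.any() else 0.0
    vmax = float(values[finite].max()) if finite.any() else 1.0
    if vmax == vmin:
        vmax = vmin + 1.0
    coll = PolyCollection(
        [p for p, f in zip(polys, finite) if f],
        array=values[finite],
        cmap=cmap,
        edgecolors="white",
        linewidths=0.3,
        clim=(vmin, vmax),
    )
    ax.add_collection(coll)
    if (~finite).any():
        ax.add_collection(
            PolyCollection(
                [p for p, f in zip(polys, finite) if not f],
                facecolors="0.85",
                hatch="///",
                edgecolors="white",
                linewidths=0.3,
            )
        )
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(column)
    fig.colorbar(coll, ax=ax, shrink=0.7)
    fig.savefig(out_path, metadata=_no_date_metadata(out_path), bbox_inches="tight")
    plt.close(fig)


def _no_date_metadata(out_path) -> dict | None:
    # strip timestamps so identical inputs give identical bytes
    s = str(out_path).lower()
    if s.endswith(".svg"):
        return {"Date": None}
    if s.endswith(".png"):
        return {"Software": None}
    return None
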
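"""Laminar geometry of the anterior piriform cortex in slice coordinates.

Layer 2 of aPCx sits under two afferent zones: layer 1a (sensory input from
the lateral olfactory tract) and layer 1b (recurrent input).  Three traced
boundary polylines — L1a/L1b, L1b/L2a, and L2/L3 — define the laminar
compartments.  This module assigns somata a normalized depth within layer 2
(which splits cells into layer 2a, the superficial third, and layer 2b, the
deep two-thirds) and classifies apical branch terminations into L1A / L1B /
L2 input zones.

Coordinates are µm in the slice plane (x lateral, y along the depth axis).
``deeper_is`` states whether depth increases with +y or -y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from shapely.ops import nearest_points

BOUNDARY_NAMES = ("L1a_L1b", "L1b_L2a", "L2_L3")

L2A_FRACTION = 1.0 / 3.0  # upper third of layer 2 is layer 2a


@dataclass(frozen=True)
class DepthAssignment:
    depth_norm: float
    cell_class: str | None          # "L2A" | "L2B" | None when unassignable
    distance_to_l1b_l2a: float      # µm
    layer2_width: float             # µm, along the perpendicular through the soma


@dataclass(frozen=True)
class TerminationAssignment:
    layer: str                      # "L1A" | "L1B" | "L2"
    extrapolated: bool              # boundary evaluated beyond its traced extent


class LayerGeometry:
    """Ordered boundary polylines delimiting L1a, L1b and layer 2.

    Parameters
    ----------
    l1a_l1b, l1b_l2a, l2_l3 : (n, 2) arrays of polyline vertices, µm.
    deeper_is : "+y" or "-y"; direction along y in which depth increases.
    """

    def __init__(self, l1a_l1b, l1b_l2a, l2_l3, deeper_is: str = "+y"):
        if deeper_is not in ("+y", "-y"):
            raise ValueError("deeper_is must be '+y' or '-y'")
        self.deeper_is = deeper_is
        self._sign = 1.0 if deeper_is == "+y" else -1.0
        self.polylines = {}
        for name, poly in zip(BOUNDARY_NAMES, (l1a_l1b, l1b_l2a, l2_l3)):
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"boundary {name} must be an (n>=2, 2) array")
            self.polylines[name] = arr
        # depth ordering sanity: mean signed y must increase with depth
        means = [self._sign * self.polylines[n][:, 1].mean() for n in BOUNDARY_NAMES]
        if not (means[0] <= means[1] <= means[2]):
            raise ValueError(
                "boundaries are not ordered along the depth axis "
                "(expected L1a/L1b most superficial, L2/L3 deepest)")
        self._linestrings = {n: LineString(p) for n, p in self.polylines.items()}

    # -- signed offsets ----------------------------------------------------
    def signed_offset(self, name: str, point) -> tuple[float, bool]:
        """Signed depth offset of ``point`` relative to boundary ``name``.

        Positive means deeper than the boundary.  The boundary is evaluated
        as y(x) by linear interpolation over its vertices, extrapolating the
        end segments beyond the traced extent; the second return value flags
        that extrapolation.
        """
        poly = self.polylines[name]
        order = np.argsort(poly[:, 0])
        xs, ys = poly[order, 0], poly[order, 1]
        x, y = float(point[0]), float(point[1])
        extrapolated = bool(x < xs[0] or x > xs[-1])
        if extrapolated:
            i = 0 if x < xs[0] else len(xs) - 2
            slope = (ys[i + 1] - ys[i]) / (xs[i + 1] - xs[i])
            yb = ys[i] + slope * (x - xs[i])
        else:
            yb = float(np.interp(x, xs, ys))
        return self._sign * (y - yb), extrapolated

    # -- soma depth --------------------------------------------------------
    def normalized_depth(self, soma_point) -> DepthAssignment:
        """Normalized soma depth within layer 2.

        depth_norm = (smallest Euclidean distance from the soma to the
        L1b/L2a boundary) / (local width of layer 2 measured along the
        perpendicular through the soma to the L2/L3 boundary).  Cells in the
        upper third are layer 2a, the deep two-thirds layer 2b (a tie at 1/3
        goes to L2B).  A soma superficial to L1b/L2a yields a negative
        depth_norm, an unassigned class, and a warning.
        """
        p = Point(float(soma_point[0]), float(soma_point[1]))
        ls_12 = self._linestrings["L1b_L2a"]
        d1 = p.distance(ls_12)
        nearest = nearest_points(ls_12, p)[0]
        width = self._perpendicular_width(np.array([nearest.x, nearest.y]),
                                          np.array([p.x, p.y]), d1)
        offset, _ = self.signed_offset("L1b_L2a", (p.x, p.y))
        if offset < 0:
            warnings.warn("soma lies superficial to the L1b/L2a boundary; "
                          "depth_norm reported negative, class unassigned")
            return DepthAssignment(-d1 / width, None, d1, width)
        depth_norm = d1 / width
        cell_class = "L2A" if depth_norm < L2A_FRACTION else "L2B"
        return DepthAssignment(depth_norm, cell_class, d1, width)

    def _perpendicular_width(self, anchor: np.ndarray, soma: np.ndarray,
                             d1: float) -> float:
        """Layer-2 width along the ray from the L1b/L2a anchor through the soma."""
        ls_23 = self._linestrings["L2_L3"]
        if d1 > 0:
            u = (soma - anchor) / d1
            if u[1] * self._sign < 0:     # superficial soma: aim the ray deep
                u = -u
        else:  # soma exactly on the boundary: fall back to the depth axis
            u = np.array([0.0, self._sign])
        span = 10.0 * (self._linestrings["L1b_L2a"].length + ls_23.length + d1 + 1.0)
        ray = LineString([anchor, anchor + span * u])
        hit = ray.intersection(ls_23)
        if not hit.is_empty:
            pts = getattr(hit, "geoms", [hit])
            dists = [Point(anchor).distance(Point(g.coords[0]) if g.geom_type != "Point" else g)
                     for g in pts]
            return float(min(dists))
        # ray misses the traced extent of L2/L3: nearest-distance fallback
        return float(d1 + Point(soma).distance(ls_23))

    # -- branch termination ------------------------------------------------
    def classify_termination(self, point) -> TerminationAssignment:
        """Input zone containing ``point`` (typically a branch's distal end).

        Ties on a boundary assign to the deeper layer.  Only x and y of the
        point are used (the slice plane); pass ``point[:2]`` of a 3-D node.
        """
        off_1a, ex1 = self.signed_offset("L1a_L1b", point[:2])
        if off_1a < 0:
            return TerminationAssignment("L1A", ex1)
        off_12, ex2 = self.signed_offset("L1b_L2a", point[:2])
        if off_12 < 0:
            return TerminationAssignment("L1B", ex1 or ex2)
        return TerminationAssignment("L2", ex1 or ex2)


def read_layer_geometry(path: str | Path, deeper_is: str = "+y") -> LayerGeometry:
    """Load boundary polylines from CSV (boundary_name, vertex_index, x, y)."""
    df = pd.read_csv(path)
    polys = []
    for name in BOUNDARY_NAMES:
        sub = df[df["boundary_name"] == name].sort_values("vertex_index")
        if sub.empty:
            raise ValueError(f"boundary {name!r} missing from {path}")
        polys.append(sub[["x", "y"]].to_numpy(dtype=float))
    return LayerGeometry(*polys, deeper_is=deeper_is)


def write_layer_geometry(geom: LayerGeometry, path: str | Path) -> None:
    rows = []
    for name in BOUNDARY_NAMES:
        for i, (x, y) in enumerate(geom.polylines[name]):
            rows.append({"boundary_name": name, "vertex_index": i, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)
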
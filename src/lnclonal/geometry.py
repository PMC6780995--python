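"""Convex tissue domains.

A :class:`DomainPolygon` is the convex boundary (in µm) within which a marked
point pattern lives: the lymph-node outline in real data, or a synthetic
stand-in.  All null randomizations are generated inside it, and Voronoi tiles
are clipped to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely

from .exceptions import InvalidDomainError, InvalidParameterError

__all__ = ["DomainPolygon", "make_elliptical_domain", "rectangle_domain"]


@dataclass(frozen=True)
class DomainPolygon:
    """A simple convex polygon with vertices in µm, stored counter-clockwise.

    Parameters
    ----------
    vertices : (m, 2) array_like
        Ordered polygon vertices. Any consistent winding is accepted and
        normalized to counter-clockwise.
    """

    vertices: np.ndarray
    _shapely: shapely.Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidDomainError("domain needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise InvalidDomainError("domain vertices must be finite")
        area2 = _signed_area2(v)
        if area2 < 0:  # clockwise -> flip
            v = v[::-1]
            area2 = -area2
        if area2 <= 0:
            raise InvalidDomainError("domain polygon has zero area")
        if not _is_convex_ccw(v):
            raise InvalidDomainError("domain polygon must be convex and simple")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "_shapely", shapely.Polygon(v))
        # inscribed-circle prefilter: centroid + min distance to an edge line
        c = v.mean(axis=0)
        w = np.roll(v, -1, axis=0)
        e = w - v
        elen = np.linalg.norm(e, axis=1)
        d = (e[:, 0] * (c[1] - v[:, 1]) - e[:, 1] * (c[0] - v[:, 0])) / np.where(
            elen > 0, elen, 1.0
        )
        object.__setattr__(self, "_incenter", c)
        object.__setattr__(self, "_inradius", float(max(d.min(), 0.0)))

    # -- basic geometry -------------------------------------------------
    @property
    def area(self) -> float:
        """Polygon area in µm²."""
        return 0.5 * _signed_area2(self.vertices)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) bounding box."""
        v = self.vertices
        return (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())

    def as_shapely(self) -> shapely.Polygon:
        return self._shapely

    def contains(self, x, y, eps: float = 1e-9) -> np.ndarray:
        """Vectorized point-in-polygon test, boundary-inclusive.

        Uses the half-plane representation of the convex boundary; `eps`
        (scaled by the domain diameter) tolerates points placed exactly on
        an edge by upstream floating-point arithmetic.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        shape = np.broadcast_shapes(x.shape, y.shape)
        x = np.broadcast_to(x, shape).ravel()
        y = np.broadcast_to(y, shape).ravel()
        # cheap accept: points within the inscribed circle are inside
        cx, cy = self._incenter
        r = self._inradius
        out = (x - cx) ** 2 + (y - cy) ** 2 <= r * r
        rest = np.flatnonzero(~out)
        if rest.size:
            v = self.vertices
            w = np.roll(v, -1, axis=0)
            ex, ey = (w - v).T  # edge vectors, CCW
            tol = eps * max(1.0, self._diameter())
            # cross((w - v), (p - v)) >= -tol for every edge
            px = x[rest, None] - v[:, 0]
            py = y[rest, None] - v[:, 1]
            cross = ex * py - ey * px
            out[rest] = np.all(cross >= -tol, axis=-1)
        return out.reshape(shape)

    def _diameter(self) -> float:
        xmin, ymin, xmax, ymax = self.bounds
        return float(np.hypot(xmax - xmin, ymax - ymin))

    # -- IO -------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write vertices as a two-column CSV with header ``x_um,y_um``."""
        arr = self.vertices
        with open(path, "w") as fh:
            fh.write("x_um,y_um\n")
            for x, y in arr:
                fh.write(f"{float(x)!r},{float(y)!r}\n")

    @classmethod
    def from_csv(cls, path) -> "DomainPolygon":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr)

    def to_geojson(self, path) -> None:
        ring = self.vertices.tolist() + [self.vertices[0].tolist()]
        obj = {"type": "Polygon", "coordinates": [ring]}
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_geojson(cls, path) -> "DomainPolygon":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("type") != "Polygon":
            raise InvalidDomainError("GeoJSON object must be a Polygon")
        ring = np.asarray(obj["coordinates"][0], dtype=float)
        if np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        return cls(ring)


def _signed_area2(v: np.ndarray) -> float:
    """Twice the signed (shoelace) area; positive for CCW winding."""
    x, y = v[:, 0], v[:, 1]
    return float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _is_convex_ccw(v: np.ndarray) -> bool:
    e = np.roll(v, -1, axis=0) - v
    cross = e[:, 0] * np.roll(e, -1, axis=0)[:, 1] - e[:, 1] * np.roll(e, -1, axis=0)[:, 0]
    scale = float(np.abs(e).max()) ** 2 or 1.0
    # collinear vertices allowed; any right turn breaks convexity
    return bool(np.all(cross >= -1e-12 * scale))


def make_elliptical_domain(
    semi_axis_a: float, semi_axis_b: float, n_vertices: int = 64
) -> DomainPolygon:
    """Convex polygon inscribed in an axis-aligned ellipse centred at the origin.

    The polygon area approaches ``pi * a * b`` as ``n_vertices`` grows
    (closed form: ``n/2 * sin(2*pi/n) * a * b``).

    Parameters
    ----------
    semi_axis_a, semi_axis_b : float
        Ellipse semi-axes in µm; must be positive.
    n_vertices : int
        Number of polygon vertices (>= 3).
    """
    if semi_axis_a <= 0 or semi_axis_b <= 0:
        raise InvalidParameterError("ellipse semi-axes must be positive")
    if n_vertices < 3:
        raise InvalidParameterError("n_vertices must be >= 3")
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    v = np.column_stack([semi_axis_a * np.cos(theta), semi_axis_b * np.sin(theta)])
    return DomainPolygon(v)


def rectangle_domain(
    xmin: float, ymin: float, xmax: float, ymax: float
) -> DomainPolygon:
    """Axis-aligned rectangular domain (a convenience for image extents)."""
    if not (xmax > xmin and ymax > ymin):
        raise InvalidParameterError("rectangle must have positive extent")
    return DomainPolygon(
        np.array([[xmin, ymin], [xmax, ymin], [xmax, ymax], [xmin, ymax]])
    )
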
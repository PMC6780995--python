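"""Voronoi tessellation, same-color tile merging, and cells-per-cluster.

Every point (cell) is allotted the territory nearer to it than to any other
point; tiles are clipped to the convex tissue boundary so they tessellate
the whole node area.  Adjacent tiles of the same color are merged into
clusters, and the statistic of interest is the average number of cells per
cluster — the number of original tiles divided by the number of merged
clusters.  Values near 1 mean colors are interleaved (no clonal patches);
large values mean same-color territories, as expected for local clonal
expansion.  For whole-node patterns with very many points, a
ratio-preserving downsampling step precedes the tessellation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import QhullError, Voronoi

from .exceptions import (
    DegenerateTessellationError,
    DuplicateConflictError,
    EmptyPatternError,
    InvalidParameterError,
)
from .geometry import DomainPolygon
from .pattern import MarkedPointPattern

__all__ = [
    "VoronoiTessellation",
    "VoronoiClusterResult",
    "downsample_pattern",
    "build_voronoi",
    "merge_same_color_clusters",
    "cluster_polygons",
]

_LEN_EPS_REL = 1e-9  # relative tolerance: positive shared-edge length


def downsample_pattern(
    pattern: MarkedPointPattern, factor: float, seed: int | np.random.Generator
) -> MarkedPointPattern:
    """Ratio-preserving random downsampling of a pattern.

    Each color c with n_c points retains ``round(n_c / factor)`` points
    (round half away from zero, floored at 1 for any represented color),
    chosen uniformly without replacement — so the color ratio of the
    subsample matches the original pattern.  The domain is unchanged.
    """
    if factor < 1:
        raise InvalidParameterError("downsampling factor must be >= 1")
    if pattern.n_points == 0:
        raise EmptyPatternError("cannot downsample an empty pattern")
    if factor == 1:
        return pattern
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for color, n_c in pattern.color_counts().items():
        if n_c == 0:
            continue
        n_keep = max(int(np.floor(n_c / factor + 0.5)), 1)
        members = np.flatnonzero(pattern.marks == color)
        keep.append(rng.choice(members, size=n_keep, replace=False))
    return pattern.subset(np.sort(np.concatenate(keep)))


@dataclass(frozen=True)
class VoronoiTessellation:
    """A Voronoi tessellation of marked points clipped to a convex boundary.

    ``adjacency_pairs`` lists (i, j) with i < j for every pair of tiles that
    share a boundary segment of positive length inside the domain; tiles
    meeting only at a single vertex are not adjacent.  ``tiles`` (lazy)
    holds the clipped shapely polygons, one per point, which together
    partition the domain.
    """

    points: np.ndarray
    marks: np.ndarray
    domain: DomainPolygon
    adjacency_pairs: np.ndarray
    _tiles: list = field(default=None, repr=False, compare=False)

    @property
    def n_tiles(self) -> int:
        return len(self.points)

    @property
    def tiles(self) -> list[shapely.Polygon]:
        if self._tiles is None:
            object.__setattr__(
                self, "_tiles", _clipped_tiles(self.points, self.domain)
            )
        return self._tiles

    def adjacency_set(self) -> set[tuple[int, int]]:
        return {tuple(p) for p in self.adjacency_pairs.tolist()}


def build_voronoi(
    pattern: MarkedPointPattern, boundary: DomainPolygon | None = None
) -> VoronoiTessellation:
    """Tessellate a pattern into Voronoi tiles clipped to the tissue boundary.

    Duplicate coordinates are merged before tessellation (with a warning;
    conflicting colors at the same coordinate raise).  Unbounded Voronoi
    cells of hull points are bounded by clipping to the convex boundary, so
    tile areas sum to the domain area.
    """
    boundary = boundary if boundary is not None else pattern.domain
    xy, marks = _dedupe(pattern.xy, pattern.marks)
    if len(xy) < 2:
        raise DegenerateTessellationError("tessellation needs >= 2 distinct points")
    pairs = _adjacency_pairs(xy, boundary)
    return VoronoiTessellation(xy, marks, boundary, pairs)


@dataclass(frozen=True)
class VoronoiClusterResult:
    """Outcome of same-color tile merging."""

    n_tiles: int
    n_clusters: int
    cells_per_cluster: float
    cluster_sizes: list[int]
    cluster_labels: np.ndarray

    def to_json(self, path=None) -> str:
        obj = {
            "n_tiles": self.n_tiles,
            "n_clusters": self.n_clusters,
            "cells_per_cluster": self.cells_per_cluster,
            "cluster_sizes": list(map(int, self.cluster_sizes)),
        }
        s = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def merge_same_color_clusters(
    tess: VoronoiTessellation, marks: np.ndarray | None = None
) -> VoronoiClusterResult:
    """Merge adjacent same-color tiles into clusters.

    Clusters are the connected components of the tile-adjacency graph
    restricted to same-color pairs; a tile with no same-color neighbor is
    its own cluster.  ``cells_per_cluster = n_tiles / n_clusters``.
    """
    marks = tess.marks if marks is None else np.asarray(marks, dtype=object)
    if marks.shape != (tess.n_tiles,):
        raise InvalidParameterError("need exactly one mark per tile")
    n = tess.n_tiles
    pairs = tess.adjacency_pairs
    if len(pairs):
        same = marks[pairs[:, 0]] == marks[pairs[:, 1]]
        pairs = pairs[same]
    if len(pairs):
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        graph = coo_matrix((n, n))
    n_clusters, labels = connected_components(graph, directed=False)
    sizes = np.bincount(labels, minlength=n_clusters)
    return VoronoiClusterResult(
        n_tiles=n,
        n_clusters=int(n_clusters),
        cells_per_cluster=n / n_clusters,
        cluster_sizes=sorted(map(int, sizes), reverse=True),
        cluster_labels=labels,
    )


def cluster_polygons(
    tess: VoronoiTessellation, result: VoronoiClusterResult
) -> dict[int, shapely.Geometry]:
    """Merged (unioned) polygon of each cluster, keyed by cluster label."""
    out: dict[int, shapely.Geometry] = {}
    for lab in np.unique(result.cluster_labels):
        members = np.flatnonzero(result.cluster_labels == lab)
        out[int(lab)] = shapely.union_all([tess.tiles[i] for i in members])
    return out


def tiles_to_geojson(
    tess: VoronoiTessellation, path=None,
    result: VoronoiClusterResult | None = None,
) -> dict:
    """Tiles as a GeoJSON FeatureCollection (color and, when a merge result
    is given, cluster label per tile) for plotting in external tools."""
    features = []
    for i, tile in enumerate(tess.tiles):
        props = {"tile": i, "color": str(tess.marks[i])}
        if result is not None:
            props["cluster"] = int(result.cluster_labels[i])
        features.append({
            "type": "Feature",
            "geometry": json.loads(shapely.to_geojson(tile)),
            "properties": props,
        })
    obj = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(obj, fh)
    return obj


# ---------------------------------------------------------------------------
# internals


def _dedupe(xy: np.ndarray, marks: np.ndarray):
    uniq, inverse = np.unique(xy, axis=0, return_inverse=True)
    if len(uniq) == len(xy):
        return xy, marks
    warnings.warn(
        f"merged {len(xy) - len(uniq)} duplicate coordinate(s) before "
        "tessellation",
        stacklevel=3,
    )
    out_marks = np.empty(len(uniq), dtype=object)
    seen = np.zeros(len(uniq), dtype=bool)
    for i, g in enumerate(inverse):
        if not seen[g]:
            out_marks[g] = marks[i]
            seen[g] = True
        elif out_marks[g] != marks[i]:
            raise DuplicateConflictError(
                f"coincident points at {tuple(uniq[g])} carry conflicting colors"
            )
    return uniq, out_marks


def _inward_normals(domain: DomainPolygon):
    v = domain.vertices
    e = np.roll(v, -1, axis=0) - v
    # CCW polygon: interior lies left of each edge
    n_in = np.column_stack([-e[:, 1], e[:, 0]])
    return v, n_in


def _clip_params(p0, p1, domain):
    """Cyrus–Beck clipping of segments p0->p1 against a convex polygon.

    Returns (t0, t1) per segment: the parameter interval of the portion
    inside the (closed) domain; empty intervals have t0 > t1.
    """
    v, n_in = _inward_normals(domain)
    d = p1 - p0  # (s, 2)
    # f_e(t) = (p0 - v_e + t d) . n_e >= 0 for every edge e
    a = np.einsum("sk,ek->se", p0, n_in) - np.einsum("ek,ek->e", v, n_in)[None, :]
    b = np.einsum("sk,ek->se", d, n_in)
    t0 = np.zeros(len(p0))
    t1 = np.ones(len(p0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_cross = -a / b
    entering = b > 0
    leaving = b < 0
    parallel_out = (b == 0) & (a < 0)
    t0 = np.maximum(t0, np.max(np.where(entering, t_cross, -np.inf), axis=1))
    t1 = np.minimum(t1, np.min(np.where(leaving, t_cross, np.inf), axis=1))
    t1 = np.where(parallel_out.any(axis=1), -np.inf, t1)
    return t0, t1


def _adjacency_pairs(xy: np.ndarray, domain: DomainPolygon) -> np.ndarray:
    """Tile-adjacency (i, j) pairs from Voronoi ridge geometry.

    A pair is adjacent iff the shared Voronoi edge, clipped to the domain,
    has positive length.  Ridges whose two finite endpoints both lie inside
    the convex domain are adjacent without clipping; only boundary-crossing
    and infinite ridges are clipped explicitly.
    """
    n = len(xy)
    if n < 4:
        return _adjacency_from_tiles(_clipped_tiles(xy, domain), domain)
    try:
        vor = Voronoi(xy)
    except QhullError:
        # collinear or otherwise degenerate site sets
        return _adjacency_from_tiles(_clipped_tiles(xy, domain), domain)

    rp = vor.ridge_points
    rv = np.asarray(vor.ridge_vertices)
    verts = vor.vertices
    diam = domain._diameter()
    len_eps = _LEN_EPS_REL * max(diam, 1.0)

    finite = np.all(rv >= 0, axis=1)
    p0 = np.empty((len(rp), 2))
    p1 = np.empty((len(rp), 2))
    p0[finite] = verts[rv[finite, 0]]
    p1[finite] = verts[rv[finite, 1]]

    if np.any(~finite):
        center = xy.mean(axis=0)
        radius = 4.0 * (diam + float(np.abs(verts).max(initial=0.0)) + 1.0)
        inf_idx = np.flatnonzero(~finite)
        fin_v = np.where(rv[inf_idx, 0] >= 0, rv[inf_idx, 0], rv[inf_idx, 1])
        a = xy[rp[inf_idx, 0]]
        b = xy[rp[inf_idx, 1]]
        t = b - a
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        nrm = np.column_stack([-t[:, 1], t[:, 0]])
        mid = 0.5 * (a + b)
        sign = np.sign(np.einsum("ij,ij->i", mid - center, nrm))
        sign[sign == 0] = 1.0
        p0[inf_idx] = verts[fin_v]
        p1[inf_idx] = verts[fin_v] + sign[:, None] * nrm * radius

    # fast path: both endpoints inside the domain's inscribed circle =>
    # the whole segment lies inside the convex domain
    cx, cy = domain._incenter
    r2 = domain._inradius**2
    in0 = (p0[:, 0] - cx) ** 2 + (p0[:, 1] - cy) ** 2 <= r2
    in1 = (p1[:, 0] - cx) ** 2 + (p1[:, 1] - cy) ** 2 <= r2
    seg_len = np.linalg.norm(p1 - p0, axis=1)
    adjacent = in0 & in1 & (seg_len > len_eps)

    needs_clip = np.flatnonzero(~(in0 & in1))
    if len(needs_clip):
        t0, t1 = _clip_params(p0[needs_clip], p1[needs_clip], domain)
        clipped = (t1 - t0) * seg_len[needs_clip]
        adjacent[needs_clip] = clipped > len_eps
    pairs = np.sort(rp[adjacent], axis=1)
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def _clipped_tiles(xy: np.ndarray, domain: DomainPolygon) -> list[shapely.Polygon]:
    """Clipped Voronoi tile polygon for every site, partitioning the domain."""
    n = len(xy)
    if n < 2:
        raise DegenerateTessellationError("tessellation needs >= 2 distinct points")
    poly = domain.as_shapely()
    if n < 4:
        return [_halfplane_tile(xy, i, poly, domain) for i in range(n)]
    try:
        vor = Voronoi(xy)
    except QhullError:
        return [_halfplane_tile(xy, i, poly, domain) for i in range(n)]
    regions, verts = _finite_regions(vor, domain)
    tiles = []
    for i, region in enumerate(regions):
        cell = shapely.Polygon(verts[region])
        if not cell.is_valid:
            cell = cell.buffer(0)
        tile = cell.intersection(poly)
        tiles.append(tile)
    return tiles


def _finite_regions(vor: Voronoi, domain: DomainPolygon):
    """Bounded polygonal regions for every Voronoi site.

    Unbounded cells are closed by pushing each infinite ridge out to a far
    point well beyond the domain, after which clipping to the domain is
    exact.  Vertices of each cell are ordered by angle around the site
    (valid because Voronoi cells are convex and contain their site).
    """
    center = vor.points.mean(axis=0)
    diam = domain._diameter()
    radius = 4.0 * (
        diam + float(np.abs(vor.vertices).max(initial=0.0))
        + float(np.abs(vor.points).max(initial=0.0)) + 1.0
    )
    new_vertices = vor.vertices.tolist()
    ridges_of: dict[int, list] = {}
    for (pa, pb), (va, vb) in zip(vor.ridge_points, vor.ridge_vertices):
        ridges_of.setdefault(pa, []).append((pb, va, vb))
        ridges_of.setdefault(pb, []).append((pa, va, vb))

    regions = []
    for p, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if -1 not in region:
            regions.append(list(region))
            continue
        new_region = [v for v in region if v >= 0]
        for q, va, vb in ridges_of[p]:
            if va >= 0 and vb >= 0:
                continue
            v_fin = va if va >= 0 else vb
            t = vor.points[q] - vor.points[p]
            t = t / np.linalg.norm(t)
            nrm = np.array([-t[1], t[0]])
            mid = 0.5 * (vor.points[p] + vor.points[q])
            sign = np.sign(np.dot(mid - center, nrm)) or 1.0
            far = vor.vertices[v_fin] + sign * nrm * radius
            new_region.append(len(new_vertices))
            new_vertices.append(far.tolist())
        vs = np.asarray([new_vertices[v] for v in new_region])
        ang = np.arctan2(vs[:, 1] - vor.points[p, 1], vs[:, 0] - vor.points[p, 0])
        regions.append([new_region[i] for i in np.argsort(ang)])
    return regions, np.asarray(new_vertices)


def _halfplane_tile(xy, i, poly, domain) -> shapely.Polygon:
    """Tile of site i as the domain cut by every bisector half-plane.

    O(n) shapely intersections per site; used only for tiny or degenerate
    site sets that qhull cannot tessellate.
    """
    big = 4.0 * (domain._diameter() + float(np.abs(xy).max()) + 1.0)
    tile = poly
    for j in range(len(xy)):
        if j == i:
            continue
        d = xy[j] - xy[i]
        du = d / np.linalg.norm(d)
        perp = np.array([-du[1], du[0]])
        mid = 0.5 * (xy[i] + xy[j])
        # rectangle on site i's side of the perpendicular bisector
        corners = [
            mid + perp * big,
            mid - perp * big,
            mid - perp * big - du * 2 * big,
            mid + perp * big - du * 2 * big,
        ]
        tile = tile.intersection(shapely.Polygon(corners))
        if tile.is_empty:
            break
    return tile


def _adjacency_from_tiles(tiles, domain) -> np.ndarray:
    """Adjacency by pairwise shared-boundary length of clipped tile polygons."""
    len_eps = _LEN_EPS_REL * max(domain._diameter(), 1.0)
    pairs = []
    for i in range(len(tiles)):
        for j in range(i + 1, len(tiles)):
            shared = tiles[i].intersection(tiles[j])
            if shared.length > len_eps:
                pairs.append((i, j))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)
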
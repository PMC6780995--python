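"""The mingling index (MI) and smoothed color probability maps.

For each point, the mingling index is the fraction of its k nearest
neighbors (k = 4 by default) carrying a different color mark; averaging over
every point in the tissue gives the node-level MI.  MI = 0 means each
neighborhood is exclusively one color; MI = 1 means neighborhoods are
entirely mixed.  Under complete spatial randomness with color frequencies
p_c, the expected MI is 1 − Σ_c p_c², e.g. 0.75 for four equally frequent
colors; values below the paired null indicate clonal clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import EmptyPatternError, InsufficientPointsError, InvalidParameterError
from .pattern import MarkedPointPattern

__all__ = [
    "AnalysisConfig",
    "MinglingResult",
    "per_point_mingling",
    "color_probability_map",
    "ColorProbabilityMap",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the clonality analysis.

    Parameters
    ----------
    k_neighbors : int
        Neighbors per point for the mingling index (default 4).
    n_null_iterations_mi, n_null_iterations_voronoi : int
        Randomized Poisson nulls per sample for each statistic (default 10).
    downsample_factor : float
        Ratio-preserving downsampling factor applied before the Voronoi
        analysis (default 1000, the factor used for whole-node patterns with
        hundreds of thousands of points; use 1 for patterns already at the
        few-thousand-point scale).
    alpha : float
        Significance level for the paired observed-vs-null tests.
    seed : int
        Master seed; all stochastic stages derive independent substreams.
    """

    k_neighbors: int = 4
    n_null_iterations_mi: int = 10
    n_null_iterations_voronoi: int = 10
    downsample_factor: float = 1000.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise InvalidParameterError("k_neighbors must be >= 1")
        if self.n_null_iterations_mi < 1 or self.n_null_iterations_voronoi < 1:
            raise InvalidParameterError("null iteration counts must be >= 1")
        if self.downsample_factor < 1:
            raise InvalidParameterError("downsample_factor must be >= 1")
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class MinglingResult:
    """Per-point mingling values and their tissue-level mean."""

    per_point: np.ndarray
    mean_mi: float
    k: int

    def to_dataframe(self, pattern: MarkedPointPattern | None = None):
        import pandas as pd

        d = {"mingling": self.per_point}
        if pattern is not None:
            d = {
                "x_um": pattern.xy[:, 0],
                "y_um": pattern.xy[:, 1],
                "color": pattern.marks,
                "mingling": self.per_point,
            }
        return pd.DataFrame(d)

    def summary_dict(self) -> dict:
        return {"n": int(len(self.per_point)), "k": self.k,
                "mean_mi": float(self.mean_mi)}


def _knn_indices(xy: np.ndarray, k: int) -> np.ndarray:
    """Indices of each point's k nearest other points.

    Distance ties at the k-th neighbor are broken by ascending point index,
    which makes results on pixel-grid patterns deterministic.  Duplicate
    coordinates are valid neighbors (distance 0).
    """
    n = len(xy)
    tree = cKDTree(xy)
    m = min(n, k + 2)
    while True:
        _, idx = tree.query(xy, k=m)
        # rank candidates by squared distance recomputed from coordinates:
        # one arithmetic path for every pair, so mathematical ties are
        # byte-identical and the index tie-break is well defined
        d2 = np.sum((xy[idx] - xy[:, None, :]) ** 2, axis=-1)
        d2 = np.where(idx == np.arange(n)[:, None], np.inf, d2)  # self last
        order = np.lexsort((idx, d2), axis=1)
        d2_sorted = np.take_along_axis(d2, order, axis=1)
        if m >= n:
            break
        # if the farthest non-self candidate ties the k-th selected neighbor
        # (within ulp noise), unseen tied candidates with smaller indices
        # may exist beyond the query horizon
        if not np.any(np.isclose(d2_sorted[:, -2], d2_sorted[:, k - 1],
                                 rtol=1e-9, atol=0)):
            break
        m = min(n, 2 * m)
    idx_sorted = np.take_along_axis(idx, order, axis=1)
    return idx_sorted[:, :k]


def per_point_mingling(pattern: MarkedPointPattern, k: int = 4) -> MinglingResult:
    """Mingling index of every point, and its unweighted mean over the node.

    ``per_point[i]`` is the fraction of the ``k`` nearest other points (by
    Euclidean distance) whose color differs from point i's; ``mean_mi`` is
    the arithmetic mean over all points.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    n = pattern.n_points
    if n < k + 1:
        raise InsufficientPointsError(
            f"mingling with k={k} needs >= {k + 1} points, got {n}"
        )
    nbrs = _knn_indices(pattern.xy, k)
    differs = pattern.marks[nbrs] != pattern.marks[:, None]
    per_point = differs.mean(axis=1)
    return MinglingResult(per_point, float(per_point.mean()), k)


@dataclass(frozen=True)
class ColorProbabilityMap:
    """Per-color probability grids over the domain.

    ``probabilities[c, i, j]`` is the probability that a cell at grid
    position (i, j) carries color ``labels[c]``; positions outside the
    domain or with zero total smoothed intensity are NaN (undefined).
    """

    probabilities: np.ndarray
    labels: tuple[str, ...]
    x_centers: np.ndarray
    y_centers: np.ndarray
    bandwidth: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.probabilities[0])

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(
            path,
            self.probabilities.astype(np.float32),
            metadata={"axes": "CYX", "channel_names": list(self.labels)},
        )


def color_probability_map(
    pattern: MarkedPointPattern,
    bandwidth: float | None = None,
    grid_spacing: float | None = None,
) -> ColorProbabilityMap:
    """Smoothed per-color probability maps (the visualization companion of MI).

    Each color's points are binned onto a regular grid over the domain and
    smoothed with an isotropic Gaussian kernel of scale ``bandwidth`` (µm);
    at every defined grid cell the per-color values are normalized to sum
    to 1.  The default bandwidth is twice the mean nearest-neighbor
    distance and the default grid spacing is half the bandwidth — the maps
    are for visualization, not inference.
    """
    from scipy.ndimage import gaussian_filter

    if pattern.n_points == 0:
        raise EmptyPatternError("probability map of an empty pattern is undefined")
    if bandwidth is None:
        tree = cKDTree(pattern.xy)
        d, _ = tree.query(pattern.xy, k=min(2, pattern.n_points))
        bandwidth = 2.0 * float(d[:, -1].mean()) if pattern.n_points > 1 else 1.0
        bandwidth = max(bandwidth, 1e-9)
    if bandwidth <= 0:
        raise InvalidParameterError("bandwidth must be positive")
    if grid_spacing is None:
        grid_spacing = bandwidth / 2.0
    if grid_spacing <= 0:
        raise InvalidParameterError("grid_spacing must be positive")

    xmin, ymin, xmax, ymax = pattern.domain.bounds
    nx = max(int(np.ceil((xmax - xmin) / grid_spacing)), 1)
    ny = max(int(np.ceil((ymax - ymin) / grid_spacing)), 1)
    x_edges = xmin + grid_spacing * np.arange(nx + 1)
    y_edges = ymin + grid_spacing * np.arange(ny + 1)
    x_centers = 0.5 * (x_edges[:-1] + x_edges[1:])
    y_centers = 0.5 * (y_edges[:-1] + y_edges[1:])

    sigma_px = bandwidth / grid_spacing
    labels = pattern.labels
    intensity = np.zeros((len(labels), ny, nx))
    for c, lab in enumerate(labels):
        sel = pattern.marks == lab
        if not sel.any():
            continue
        h, _, _ = np.histogram2d(
            pattern.xy[sel, 1], pattern.xy[sel, 0], bins=[y_edges, x_edges]
        )
        intensity[c] = gaussian_filter(h, sigma=sigma_px, mode="constant")

    total = intensity.sum(axis=0)
    gx, gy = np.meshgrid(x_centers, y_centers)
    inside = pattern.domain.contains(gx.ravel(), gy.ravel()).reshape(ny, nx)
    defined = inside & (total > 1e-300)
    probs = np.full_like(intensity, np.nan)
    probs[:, defined] = intensity[:, defined] / total[defined]
    return ColorProbabilityMap(probs, labels, x_centers, y_centers, float(bandwidth))
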
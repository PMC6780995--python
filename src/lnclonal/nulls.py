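"""Randomized Poisson nulls and paired observed-vs-null inference.

For each observed node, null patterns are generated as complete spatial
randomness inside the same boundary with the same per-color counts — a
randomized Poisson rearrangement of the same data.  The clonality statistics
(mingling index, cells-per-cluster) are recomputed on each null iteration,
null iterations are averaged with means, and observed-vs-null comparisons
across nodes use a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateTestError, InputError, InvalidDomainError
from .mingling import AnalysisConfig, per_point_mingling
from .pattern import MarkedPointPattern
from .simulate import simulate_csr_pattern
from .voronoi import build_voronoi, downsample_pattern, merge_same_color_clusters

__all__ = [
    "NullEnsemble",
    "PairedComparison",
    "randomize_pattern",
    "null_mi_ensemble",
    "null_voronoi_ensemble",
    "paired_observed_vs_null",
]


@dataclass(frozen=True)
class NullEnsemble:
    """Per-iteration statistic values from randomized Poisson nulls."""

    statistic_name: str
    iteration_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "iteration_values", np.asarray(self.iteration_values, dtype=float)
        )

    @property
    def n_iterations(self) -> int:
        return len(self.iteration_values)

    @property
    def summary(self) -> float:
        """Arithmetic mean over iterations (nulls are averaged using means)."""
        return float(self.iteration_values.mean())


@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test of an observed statistic against its per-sample null."""

    per_sample_observed: np.ndarray
    per_sample_null: np.ndarray
    t_statistic: float
    p_value: float
    direction: str  # observed_lower | observed_higher | none

    @property
    def mean_difference(self) -> float:
        return float((self.per_sample_observed - self.per_sample_null).mean())


def randomize_pattern(
    pattern: MarkedPointPattern, seed: int | np.random.Generator
) -> MarkedPointPattern:
    """One randomized Poisson rearrangement of a pattern.

    Positions are discarded and re-drawn as CSR inside the observed
    boundary; per-color counts are kept exactly, so every null iteration is
    paired to the observed pattern.
    """
    if pattern.domain is None:
        raise InvalidDomainError("randomization requires the observed boundary")
    counts = {c: k for c, k in pattern.color_counts().items() if k > 0}
    return simulate_csr_pattern(pattern.domain, counts, seed)


def _substreams(seed: int, tag: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence([int(seed), int(tag)])
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def null_mi_ensemble(
    pattern: MarkedPointPattern, config: AnalysisConfig, seed: int | None = None
) -> NullEnsemble:
    """Mean mingling index of each of the randomized null iterations.

    ``seed`` overrides ``config.seed`` so that multiple samples analysed
    under one config get independent null streams.
    """
    rngs = _substreams(config.seed if seed is None else seed, 1,
                       config.n_null_iterations_mi)
    values = [
        per_point_mingling(randomize_pattern(pattern, rng), config.k_neighbors).mean_mi
        for rng in rngs
    ]
    return NullEnsemble("mean_mi", np.asarray(values))


def null_voronoi_ensemble(
    pattern: MarkedPointPattern, config: AnalysisConfig, seed: int | None = None
) -> NullEnsemble:
    """Cells-per-cluster of each randomized, downsampled null iteration.

    Each iteration randomizes positions, applies the same ratio-preserving
    downsampling as the observed analysis, tessellates, and merges
    same-color tiles.
    """
    rngs = _substreams(config.seed if seed is None else seed, 2,
                       config.n_null_iterations_voronoi)
    values = []
    for rng in rngs:
        null = randomize_pattern(pattern, rng)
        sub = downsample_pattern(null, config.downsample_factor, rng)
        tess = build_voronoi(sub)
        values.append(merge_same_color_clusters(tess).cells_per_cluster)
    return NullEnsemble("cells_per_cluster", np.asarray(values))


def paired_observed_vs_null(observed, null_summaries) -> PairedComparison:
    """Two-sided paired t-test of observed vs null values across samples.

    ``direction`` reports the sign of the mean difference (observed − null);
    constant differences (zero variance) make the t-statistic undefined and
    raise :class:`DegenerateTestError`.
    """
    obs = np.asarray(observed, dtype=float)
    nul = np.asarray(null_summaries, dtype=float)
    if obs.shape != nul.shape or obs.ndim != 1:
        raise InputError("observed and null must be equal-length 1D sequences")
    if len(obs) < 2:
        raise InputError("paired test needs >= 2 samples")
    d = obs - nul
    if np.std(d, ddof=1) == 0:
        raise DegenerateTestError("zero-variance paired differences")
    t, p = stats.ttest_rel(obs, nul)
    mean_d = d.mean()
    if mean_d < 0:
        direction = "observed_lower"
    elif mean_d > 0:
        direction = "observed_higher"
    else:
        direction = "none"
    return PairedComparison(obs, nul, float(t), float(p), direction)
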
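"""Synthetic marked point patterns and rendered multichannel images.

Two generative regimes stand in for the Confetti fate-mapping data:

* complete spatial randomness (CSR) with fixed per-color counts — the null
  regime used for randomized comparisons, and
* a Thomas-type parent–daughter process in which each color-labeled
  progenitor seeds a local clone of daughters — the clustered alternative
  expected when stromal cells differentiate in place from single labeled
  progenitors.

Patterns can be rendered into noisy multichannel images so the imaging
front-end can be exercised without microscope data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigError,
    EmptyPatternError,
    InvalidDomainError,
    InvalidParameterError,
)
from .geometry import DomainPolygon
from .pattern import CONFETTI_COLORS, MarkedPointPattern

__all__ = [
    "ClonalSimConfig",
    "simulate_csr_pattern",
    "simulate_clustered_pattern",
    "render_pattern_to_image",
    "RenderedImage",
]


def _uniform_in_domain(
    domain: DomainPolygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. uniform points in the domain by rejection from its
    bounding box."""
    xmin, ymin, xmax, ymax = domain.bounds
    out = np.empty((n, 2))
    filled = 0
    # acceptance ratio = area / bbox area; convex domains keep this high
    while filled < n:
        m = max(int(1.5 * (n - filled)) + 16, 16)
        cand = rng.uniform((xmin, ymin), (xmax, ymax), size=(m, 2))
        keep = cand[domain.contains(cand[:, 0], cand[:, 1])]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def simulate_csr_pattern(
    domain: DomainPolygon,
    counts_per_color: dict[str, int],
    seed: int | np.random.Generator,
) -> MarkedPointPattern:
    """Simulate complete spatial randomness with fixed per-color counts.

    Exactly ``counts_per_color[c]`` points of each color are placed i.i.d.
    uniformly in the domain ("binomial" CSR): fixing the counts to the
    observed ones makes each randomization an exactly paired null for an
    observed pattern, removing count variation as a nuisance.

    Parameters
    ----------
    domain : DomainPolygon
        Convex region to fill.
    counts_per_color : dict
        Requested number of points per color label; order fixes label order.
    seed : int or numpy Generator
        Randomness source; a fixed integer reproduces coordinates exactly.
    """
    if not isinstance(domain, DomainPolygon):
        raise InvalidDomainError("a DomainPolygon is required")
    counts = {str(c): int(k) for c, k in counts_per_color.items()}
    if any(k < 0 for k in counts.values()):
        raise InvalidParameterError("per-color counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise EmptyPatternError("all per-color counts are zero")
    rng = np.random.default_rng(seed)
    xy = _uniform_in_domain(domain, total, rng)
    marks = np.concatenate(
        [np.full(k, c, dtype=object) for c, k in counts.items()]
    )
    return MarkedPointPattern(xy, marks, domain, labels=tuple(counts),
                              validate=False)


@dataclass(frozen=True)
class ClonalSimConfig:
    """Parameters of the clustered (clonal expansion) generator.

    Parameters
    ----------
    n_progenitors : int
        Number of parent (progenitor) points, placed uniformly in the domain.
    color_probs : dict
        Probability that a progenitor carries each color; must sum to 1.
    daughters_mean : float
        Expected Poisson number of daughters per progenitor.
    dispersion_sigma : float
        Isotropic Gaussian displacement scale of daughters around their
        parent, in µm.  Small values give tight clones.
    domain : DomainPolygon
        Tissue region.
    seed : int
        Seed for the generator.
    """

    n_progenitors: int
    color_probs: dict[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in CONFETTI_COLORS}
    )
    daughters_mean: float = 9.0
    dispersion_sigma: float = 10.0
    domain: DomainPolygon | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progenitors < 1:
            raise ConfigError("n_progenitors must be >= 1")
        if self.daughters_mean < 0:
            raise ConfigError("daughters_mean must be non-negative")
        if self.dispersion_sigma < 0:
            raise ConfigError("dispersion_sigma must be non-negative")
        probs = np.array(list(self.color_probs.values()), dtype=float)
        if len(probs) == 0 or np.any(probs < 0):
            raise ConfigError("color_probs must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("color_probs must sum to 1 (tolerance 1e-9)")
        if not isinstance(self.domain, DomainPolygon):
            raise ConfigError("config requires a DomainPolygon domain")


def simulate_clustered_pattern(config: ClonalSimConfig) -> MarkedPointPattern:
    """Simulate a clustered clonal pattern (Thomas-type parent–daughter process).

    Each of ``n_progenitors`` parents is placed uniformly in the domain and
    draws one color from ``color_probs``; it then emits
    ``Poisson(daughters_mean)`` daughters displaced by isotropic
    ``N(0, dispersion_sigma^2)`` offsets, resampled until inside the domain
    (so the daughter count per parent is preserved exactly).  The returned
    pattern contains parents and daughters, daughters inheriting the parent's
    color.  With ``daughters_mean = 0`` the process reduces to CSR with
    multinomial color counts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    labels = tuple(cfg.color_probs)
    probs = np.array([cfg.color_probs[c] for c in labels], dtype=float)

    parents = _uniform_in_domain(cfg.domain, cfg.n_progenitors, rng)
    parent_colors = rng.choice(len(labels), size=cfg.n_progenitors, p=probs)
    n_daughters = rng.poisson(cfg.daughters_mean, size=cfg.n_progenitors)

    total_d = int(n_daughters.sum())
    centers = np.repeat(parents, n_daughters, axis=0)
    daughters = np.empty((total_d, 2))
    pending = np.arange(total_d)
    while pending.size:
        offs = rng.normal(scale=cfg.dispersion_sigma, size=(pending.size, 2))
        cand = centers[pending] + offs
        ok = cfg.domain.contains(cand[:, 0], cand[:, 1])
        daughters[pending[ok]] = cand[ok]
        pending = pending[~ok]
        if cfg.dispersion_sigma == 0:
            # parents are inside, so zero-offset daughters always land inside
            daughters[pending] = centers[pending]
            break

    xy = np.vstack([parents, daughters])
    color_idx = np.concatenate([parent_colors, np.repeat(parent_colors, n_daughters)])
    marks = np.array([labels[i] for i in color_idx], dtype=object)
    return MarkedPointPattern(xy, marks, cfg.domain, labels=labels,
                              validate=False)


@dataclass(frozen=True)
class RenderedImage:
    """A multichannel rendering of a point pattern.

    ``channels`` has shape (C, H, W); ``channel_names[c]`` names channel c.
    Pixel (row, col) covers the µm square whose lower corner is
    ``origin_um + (col, row) * pixel_size``; a point maps to the pixel whose
    center is nearest (0-based, x = column, y = row).
    """

    channels: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size: float
    origin_um: tuple[float, float]


def render_pattern_to_image(
    pattern: MarkedPointPattern | None,
    pixel_size: float,
    spot_radius: int = 2,
    background_noise_sd: float = 0.0,
    seed: int = 0,
    channel_names: tuple[str, ...] | None = None,
    shape: tuple[int, int] | None = None,
    origin_um: tuple[float, float] | None = None,
) -> RenderedImage:
    """Render a pattern into a noisy multichannel image, one channel per color.

    Each point is drawn as a filled disc of ``spot_radius`` pixels at
    saturating intensity 1.0 in its color's channel; independent Gaussian
    background noise of standard deviation ``background_noise_sd`` is then
    added to every channel.  Channel order follows ``pattern.labels`` (or an
    explicit ``channel_names``).

    An empty ``pattern`` (None) triggers a warning and yields a noise-only
    image, for which ``shape`` and ``channel_names`` are required.
    """
    from skimage.draw import disk

    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be positive")
    rng = np.random.default_rng(seed)

    if pattern is None:
        if shape is None or channel_names is None:
            raise ConfigError("noise-only rendering needs shape and channel_names")
        warnings.warn("rendering an empty pattern: noise-only image", stacklevel=2)
        channels = rng.normal(
            scale=background_noise_sd, size=(len(channel_names), *shape)
        ) if background_noise_sd > 0 else np.zeros((len(channel_names), *shape))
        return RenderedImage(channels, tuple(channel_names), pixel_size, (0.0, 0.0))

    names = tuple(channel_names) if channel_names is not None else pattern.labels
    xmin, ymin, xmax, ymax = pattern.domain.bounds
    if origin_um is None:
        origin_um = (xmin - 2 * spot_radius * pixel_size,
                     ymin - 2 * spot_radius * pixel_size)
    if shape is None:
        h = int(np.ceil((ymax - origin_um[1]) / pixel_size)) + 2 * spot_radius + 1
        w = int(np.ceil((xmax - origin_um[0]) / pixel_size)) + 2 * spot_radius + 1
        shape = (h, w)

    channels = np.zeros((len(names), *shape))
    cols = np.floor((pattern.xy[:, 0] - origin_um[0]) / pixel_size).astype(int)
    rows = np.floor((pattern.xy[:, 1] - origin_um[1]) / pixel_size).astype(int)
    chan_index = {c: i for i, c in enumerate(names)}
    for r, c, mark in zip(rows, cols, pattern.marks):
        rr, cc = disk((r, c), spot_radius + 0.5, shape=shape)
        channels[chan_index[str(mark)], rr, cc] = 1.0

    if background_noise_sd > 0:
        channels = channels + rng.normal(scale=background_noise_sd, size=channels.shape)
        channels = np.clip(channels, 0.0, None)
    return RenderedImage(channels, names, pixel_size, tuple(origin_um))
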
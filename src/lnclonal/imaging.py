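"""Imaging front-end: thresholding, point extraction, boundary, area fraction.

Mirrors the microscopy quantification pipeline: fluorescence channels are
thresholded to binary signal, every above-threshold location (or connected
component) inside the tissue mask becomes a marked point, the tissue boundary
is the convex hull of the overlay of all colors, and reporter coverage is
summarized as an area fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    ConfigError,
    DegenerateHullError,
    DegenerateThresholdError,
    EmptyPatternError,
    InvalidMaskError,
    InvalidParameterError,
)
from .geometry import DomainPolygon, rectangle_domain
from .pattern import MarkedPointPattern
from .simulate import RenderedImage

__all__ = [
    "BinaryMask",
    "AreaFractionResult",
    "threshold_channel",
    "extract_point_pattern",
    "compute_ln_boundary",
    "area_fraction",
    "write_image_tiff",
    "read_image_tiff",
]


@dataclass(frozen=True)
class BinaryMask:
    """A thresholded channel: boolean pixels plus provenance.

    ``threshold`` and ``method`` record how the mask was produced, since the
    choice of threshold is the main free parameter of the imaging front-end.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    threshold: float | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise InvalidMaskError("mask must be a 2D pixel grid")
        if self.pixel_size <= 0:
            raise InvalidMaskError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def n_true(self) -> int:
        return int(self.pixels.sum())

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, (self.pixels.astype(np.uint8) * 255))

    @classmethod
    def from_tiff(cls, path, pixel_size: float = 1.0) -> "BinaryMask":
        import tifffile

        return cls(tifffile.imread(path) > 0, pixel_size=pixel_size)


@dataclass(frozen=True)
class AreaFractionResult:
    """Area-fraction quantification of a signal inside a tissue mask."""

    ln_area_px: int
    positive_area_px: int
    fraction: float


def threshold_channel(
    channel: np.ndarray,
    method: str = "otsu",
    manual_value: float | None = None,
    pixel_size: float = 1.0,
) -> BinaryMask:
    """Threshold an intensity channel to binary signal.

    ``method="otsu"`` picks the threshold automatically from the intensity
    histogram; ``method="manual"`` uses ``manual_value``.  The mask is true
    where intensity is strictly greater than the threshold, and the threshold
    used is recorded on the result.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0 or channel.ndim != 2:
        raise InvalidParameterError("channel must be a non-empty 2D array")
    if method == "manual":
        if manual_value is None:
            raise ConfigError("method='manual' requires manual_value")
        thr = float(manual_value)
    elif method == "otsu":
        if manual_value is not None:
            raise ConfigError("manual_value only applies to method='manual'")
        if np.ptp(channel) == 0:
            raise DegenerateThresholdError(
                "constant-intensity channel: Otsu threshold undefined"
            )
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(channel))
    else:
        raise ConfigError(f"unknown threshold method {method!r}")
    return BinaryMask(channel > thr, pixel_size=pixel_size, threshold=thr, method=method)


def _pixel_centers_um(rows, cols, pixel_size, origin):
    """0-based pixel convention: point at center (col+0.5, row+0.5)·pixel_size."""
    x = origin[0] + (np.asarray(cols) + 0.5) * pixel_size
    y = origin[1] + (np.asarray(rows) + 0.5) * pixel_size
    return x, y


def extract_point_pattern(
    image: RenderedImage | np.ndarray,
    channel_map: dict[int | str, str],
    ln_mask: BinaryMask,
    mode: str = "pixel",
    multi_positive: str = "argmax",
    threshold_method: str = "otsu",
    manual_thresholds: dict[str, float] | None = None,
    pixel_size: float | None = None,
    origin_um: tuple[float, float] = (0.0, 0.0),
    domain: DomainPolygon | None = None,
) -> MarkedPointPattern:
    """Convert a multichannel image into a marked point pattern.

    Each reporter channel is thresholded, restricted to ``ln_mask``, and
    turned into points: with ``mode="pixel"`` every positive pixel becomes
    one point at its pixel center (the regime behind very large whole-node
    patterns); with ``mode="centroid"`` each connected component becomes one
    point at its centroid.  Pixels positive in more than one channel are
    resolved by ``multi_positive``: ``"argmax"`` assigns the brightest
    channel (ties to the lowest channel index), ``"exclude"`` drops the
    pixel.

    ``channel_map`` maps channel index (or name, for a
    :class:`~lnclonal.simulate.RenderedImage`) to a color label.  The
    returned pattern's domain defaults to the image extent; pass ``domain``
    or apply :func:`compute_ln_boundary` afterwards for a hull boundary.
    """
    if isinstance(image, RenderedImage):
        stack = image.channels
        name_to_idx = {n: i for i, n in enumerate(image.channel_names)}
        pixel_size = image.pixel_size if pixel_size is None else pixel_size
        origin_um = image.origin_um
    else:
        stack = np.asarray(image, dtype=float)
        name_to_idx = {}
        pixel_size = 1.0 if pixel_size is None else pixel_size
    if stack.ndim != 3:
        raise ConfigError("image must be a (C, H, W) stack")
    if stack.shape[1:] != ln_mask.pixels.shape:
        raise ConfigError("channels and ln_mask must share a shape")
    if mode not in ("pixel", "centroid"):
        raise ConfigError(f"unknown mode {mode!r}")
    if multi_positive not in ("argmax", "exclude"):
        raise ConfigError(f"unknown multi_positive policy {multi_positive!r}")

    # resolve channel_map keys to channel indices, keep user-given order
    chan_idx: list[int] = []
    labels: list[str] = []
    for key, color in channel_map.items():
        if isinstance(key, str):
            if key not in name_to_idx:
                raise ConfigError(f"channel {key!r} not present in image")
            chan_idx.append(name_to_idx[key])
        else:
            if not (0 <= key < stack.shape[0]):
                raise ConfigError(f"channel index {key} out of range")
            chan_idx.append(int(key))
        labels.append(str(color))

    positives = np.zeros((len(chan_idx), *ln_mask.pixels.shape), dtype=bool)
    manual_thresholds = manual_thresholds or {}
    for k, (ci, color) in enumerate(zip(chan_idx, labels)):
        if color in manual_thresholds:
            m = threshold_channel(
                stack[ci], "manual", manual_thresholds[color], pixel_size
            )
        else:
            m = threshold_channel(stack[ci], threshold_method, pixel_size=pixel_size)
        positives[k] = m.pixels & ln_mask.pixels

    # multi-positive resolution on the pixel grid
    n_pos = positives.sum(axis=0)
    conflict = n_pos > 1
    if conflict.any():
        if multi_positive == "exclude":
            positives[:, conflict] = False
        else:  # argmax on raw intensities; np.argmax ties -> lowest index
            sub = np.stack([stack[ci][conflict] for ci in chan_idx])
            winner = np.argmax(sub, axis=0)
            keep = np.zeros_like(sub, dtype=bool)
            keep[winner, np.arange(sub.shape[1])] = True
            positives[:, conflict] = keep

    xs, ys, marks = [], [], []
    if mode == "pixel":
        for k, color in enumerate(labels):
            rows, cols = np.nonzero(positives[k])
            x, y = _pixel_centers_um(rows, cols, pixel_size, origin_um)
            xs.append(x)
            ys.append(y)
            marks.extend([color] * len(rows))
    else:
        from skimage.measure import label as cc_label
        from skimage.measure import regionprops

        for k, color in enumerate(labels):
            lab = cc_label(positives[k])
            for rp in regionprops(lab):
                r, c = rp.centroid
                x, y = _pixel_centers_um(r, c, pixel_size, origin_um)
                xs.append(np.atleast_1d(x))
                ys.append(np.atleast_1d(y))
                marks.append(color)

    if not marks:
        raise EmptyPatternError("no positive pixels inside the tissue mask")
    xy = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
    if domain is None:
        h, w = ln_mask.pixels.shape
        domain = rectangle_domain(
            origin_um[0], origin_um[1],
            origin_um[0] + w * pixel_size, origin_um[1] + h * pixel_size,
        )
    return MarkedPointPattern(xy, np.array(marks, dtype=object), domain,
                              labels=tuple(dict.fromkeys(labels)))


def compute_ln_boundary(pattern_or_points) -> DomainPolygon:
    """Convex hull of all points regardless of color — the tissue boundary.

    Raises :class:`DegenerateHullError` for fewer than 3 points or collinear
    configurations.
    """
    from scipy.spatial import ConvexHull, QhullError

    if isinstance(pattern_or_points, MarkedPointPattern):
        pts = pattern_or_points.xy
    else:
        pts = np.atleast_2d(np.asarray(pattern_or_points, dtype=float))
    if pts.shape[0] < 3:
        raise DegenerateHullError("convex hull needs >= 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate hull: {exc}") from exc
    return DomainPolygon(pts[hull.vertices])


def area_fraction(signal_mask: BinaryMask, ln_mask: BinaryMask) -> AreaFractionResult:
    """Fraction of the tissue mask covered by signal: |signal ∧ ln| / |ln|."""
    if signal_mask.pixels.shape != ln_mask.pixels.shape:
        raise InvalidMaskError("signal and tissue masks must share a shape")
    ln_px = ln_mask.n_true
    if ln_px == 0:
        raise InvalidMaskError("tissue mask is empty")
    pos = int(np.sum(signal_mask.pixels & ln_mask.pixels))
    return AreaFractionResult(ln_px, pos, pos / ln_px)


def append_area_fraction_csv(path, sample_id: str,
                             result: AreaFractionResult) -> None:
    """Append one sample's area-fraction row to a results CSV, creating the
    file (with header ``sample_id,ln_area_px,positive_area_px,fraction``)
    if needed."""
    import os

    new = not os.path.exists(path)
    with open(path, "a") as fh:
        if new:
            fh.write("sample_id,ln_area_px,positive_area_px,fraction\n")
        fh.write(f"{sample_id},{result.ln_area_px},{result.positive_area_px},"
                 f"{result.fraction!r}\n")


def write_image_tiff(image: RenderedImage, path) -> None:
    """Write a multichannel image as a TIFF stack with channel names in
    metadata (ImageJ-style axes CYX)."""
    import tifffile

    tifffile.imwrite(
        path,
        image.channels.astype(np.float32),
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "channel_names": list(image.channel_names),
            "pixel_size_um": image.pixel_size,
            "origin_um": list(image.origin_um),
        },
    )


def read_image_tiff(path, channel_names=None, pixel_size=None) -> RenderedImage:
    """Read a multichannel TIFF written by :func:`write_image_tiff` (or any
    (C, H, W) stack, given explicit ``channel_names``)."""
    import json

    import tifffile

    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = {}
        desc = tf.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except (ValueError, TypeError):
                meta = {}
    if stack.ndim == 2:
        stack = stack[None]
    names = tuple(channel_names or meta.get("channel_names")
                  or [f"ch{i}" for i in range(stack.shape[0])])
    ps = pixel_size or float(meta.get("pixel_size_um", 1.0))
    origin = tuple(meta.get("origin_um", (0.0, 0.0)))
    if len(names) != stack.shape[0]:
        raise ConfigError("channel_names length does not match channel count")
    return RenderedImage(np.asarray(stack, dtype=float), names, ps, origin)
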
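"""Marked point patterns.

The central object of the analysis: 2D point locations (µm) carrying one
categorical color mark each — one of the four Confetti reporters nGFP, cRFP,
cYFP, mCFP in the motivating data, but any finite label set works — together
with the convex tissue domain the points live in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyPatternError, InputError
from .geometry import DomainPolygon

__all__ = ["CONFETTI_COLORS", "MarkedPointPattern"]

#: The four Brainbow2.1/Confetti reporter proteins, in the conventional order.
CONFETTI_COLORS: tuple[str, ...] = ("nGFP", "cRFP", "cYFP", "mCFP")


@dataclass(frozen=True)
class MarkedPointPattern:
    """Point locations with one categorical color mark per point.

    Parameters
    ----------
    xy : (n, 2) array_like
        Point coordinates in µm.
    marks : (n,) array_like of str
        Color label per point.
    domain : DomainPolygon
        Convex boundary containing every point (boundary-inclusive, with a
        small floating-point tolerance).
    labels : tuple of str, optional
        Fixed label universe and ordering.  Defaults to the distinct marks in
        order of first appearance; pass explicitly to keep colors with zero
        observed points in the accounting.
    """

    xy: np.ndarray
    marks: np.ndarray
    domain: DomainPolygon
    labels: tuple[str, ...] = field(default=())
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        marks = np.asarray(self.marks, dtype=object)
        if xy.shape[0] == 0:
            raise EmptyPatternError("pattern has no points")
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise InputError("xy must be an (n, 2) array")
        if marks.shape != (xy.shape[0],):
            raise InputError("marks must have one entry per point")
        if not isinstance(self.domain, DomainPolygon):
            raise InputError("pattern requires a DomainPolygon")
        if self.validate:
            # trusted internal constructors (simulators, subset) skip the
            # containment re-check; user-facing paths keep it
            if not np.all(np.isfinite(xy)):
                raise InputError("coordinates must be finite")
            inside = self.domain.contains(xy[:, 0], xy[:, 1])
            if not np.all(inside):
                k = int(np.sum(~inside))
                raise InputError(f"{k} point(s) fall outside the domain")
        labels = tuple(self.labels) or tuple(pd.unique(marks))
        unknown = set(marks) - set(labels)
        if unknown:
            raise InputError(f"marks {sorted(unknown)} not in label set {labels}")
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "marks", marks)
        object.__setattr__(self, "labels", labels)

    # -- accessors ------------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.xy.shape[0]

    def __len__(self) -> int:
        return self.n_points

    def color_counts(self) -> dict[str, int]:
        """Number of points per color, in label order (zeros included)."""
        return {c: int(np.sum(self.marks == c)) for c in self.labels}

    def subset(self, index) -> "MarkedPointPattern":
        """Pattern restricted to the given integer index, same domain/labels."""
        index = np.asarray(index)
        return MarkedPointPattern(
            self.xy[index], self.marks[index], self.domain, labels=self.labels,
            validate=False,
        )

    def with_domain(self, domain: DomainPolygon) -> "MarkedPointPattern":
        return MarkedPointPattern(self.xy, self.marks, domain, labels=self.labels)

    # -- IO -------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_um": self.xy[:, 0], "y_um": self.xy[:, 1], "color": self.marks}
        )

    def to_csv(self, path) -> None:
        """Write the pattern as CSV with header ``x_um,y_um,color``."""
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        domain: DomainPolygon | None = None,
        labels: tuple[str, ...] = (),
    ) -> "MarkedPointPattern":
        """Build a pattern from a table with columns ``x_um, y_um, color``.

        When ``domain`` is omitted the convex hull of the points is used,
        mirroring how the lymph-node boundary is derived from the overlay of
        all colors.
        """
        required = {"x_um", "y_um", "color"}
        if not required.issubset(df.columns):
            raise InputError(f"dataframe needs columns {sorted(required)}")
        xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
        marks = df["color"].to_numpy(dtype=object)
        if domain is None:
            from .imaging import compute_ln_boundary  # cycle-free at call time

            domain = compute_ln_boundary(xy)
        return cls(xy, marks, domain, labels=labels)

    @classmethod
    def from_csv(
        cls, path, domain: DomainPolygon | None = None, labels: tuple[str, ...] = ()
    ) -> "MarkedPointPattern":
        return cls.from_dataframe(pd.read_csv(path), domain=domain, labels=labels)
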
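"""The clonality model: per-node statistics plus paired null inference.

:class:`SpatialClonalityModel` is the top-level entry point.  It is built
from one marked point pattern per lymph node; :meth:`fit` computes, for each
node, the observed mingling index and cells-per-cluster together with their
randomized-Poisson-null counterparts, and then tests observed against null
across nodes with paired t-tests.  The fitted
:class:`SpatialClonalityResults` carries the per-node table, both paired
comparisons, and a clustering verdict: a pattern set is called *clustered*
when the mingling index is significantly below its null AND
cells-per-cluster is significantly above its null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError
from .mingling import AnalysisConfig, MinglingResult, per_point_mingling
from .nulls import (
    NullEnsemble,
    PairedComparison,
    null_mi_ensemble,
    null_voronoi_ensemble,
    paired_observed_vs_null,
)
from .pattern import MarkedPointPattern
from .voronoi import (
    VoronoiClusterResult,
    build_voronoi,
    downsample_pattern,
    merge_same_color_clusters,
)

__all__ = ["SpatialClonalityModel", "SpatialClonalityResults", "clustering_report"]


class SpatialClonalityModel:
    """Observed-vs-null clonality analysis over a set of lymph nodes.

    Parameters
    ----------
    patterns : sequence of MarkedPointPattern
        One marked point pattern per node (each with its own boundary).
    config : AnalysisConfig, optional
        k for the mingling index, null iteration counts, downsampling
        factor, significance level, and master seed.
    sample_ids : sequence of str, optional
        Node identifiers for the report (default LN01, LN02, ...).
    """

    def __init__(self, patterns, config: AnalysisConfig | None = None,
                 sample_ids=None):
        patterns = list(patterns)
        if not patterns:
            raise InputError("the model needs at least one pattern")
        if not all(isinstance(p, MarkedPointPattern) for p in patterns):
            raise InputError("every sample must be a MarkedPointPattern")
        if sample_ids is None:
            sample_ids = [f"LN{i + 1:02d}" for i in range(len(patterns))]
        if len(sample_ids) != len(patterns):
            raise InputError("one sample_id per pattern required")
        self.patterns = patterns
        self.config = config or AnalysisConfig()
        self.sample_ids = list(map(str, sample_ids))

    @classmethod
    def from_csv(cls, paths, config: AnalysisConfig | None = None,
                 sample_ids=None, use_hull_boundary: bool = True):
        """Build the model from pattern CSVs (columns ``x_um,y_um,color``).

        With ``use_hull_boundary`` (default) each node's boundary is the
        convex hull of all its points, as in the imaging pipeline.
        """
        pats = [MarkedPointPattern.from_csv(p) for p in paths]
        if sample_ids is None:
            import os

            sample_ids = [os.path.splitext(os.path.basename(str(p)))[0]
                          for p in paths]
        return cls(pats, config=config, sample_ids=sample_ids)

    def fit(self, statistics=("mi", "voronoi")) -> "SpatialClonalityResults":
        """Run the statistics and their nulls on every node, then the paired
        observed-vs-null tests across nodes.

        ``statistics`` selects which of the two clonality statistics to
        compute (both by default); restricting to one halves the work when
        only one comparison is of interest.
        """
        cfg = self.config
        unknown = set(statistics) - {"mi", "voronoi"}
        if unknown:
            raise InputError(f"unknown statistics {sorted(unknown)}")
        ss = np.random.SeedSequence([int(cfg.seed), 777])
        sample_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in
                        ss.spawn(len(self.patterns))]

        rows = []
        detail = []
        for pat, sid, seed in zip(self.patterns, self.sample_ids, sample_seeds):
            row = {"sample_id": sid, "n_points": pat.n_points}
            mi = mi_null = vr = vr_null = None
            if "mi" in statistics:
                mi = per_point_mingling(pat, cfg.k_neighbors)
                mi_null = null_mi_ensemble(pat, cfg, seed=seed)
                row.update(mean_mi=mi.mean_mi, null_mean_mi=mi_null.summary)
            if "voronoi" in statistics:
                sub = downsample_pattern(
                    pat, cfg.downsample_factor, np.random.default_rng([seed, 3])
                )
                vr = merge_same_color_clusters(build_voronoi(sub))
                vr_null = null_voronoi_ensemble(pat, cfg, seed=seed)
                row.update(
                    n_tiles=vr.n_tiles,
                    n_clusters=vr.n_clusters,
                    cells_per_cluster=vr.cells_per_cluster,
                    null_cells_per_cluster=vr_null.summary,
                )
            rows.append(row)
            detail.append((sid, mi, mi_null, vr, vr_null))

        table = pd.DataFrame(rows)
        mi_test = vor_test = None
        if len(table) >= 2:
            if "mi" in statistics:
                mi_test = paired_observed_vs_null(
                    table["mean_mi"], table["null_mean_mi"]
                )
            if "voronoi" in statistics:
                vor_test = paired_observed_vs_null(
                    table["cells_per_cluster"], table["null_cells_per_cluster"]
                )
        return SpatialClonalityResults(self, table, mi_test, vor_test, detail)


@dataclass
class SpatialClonalityResults:
    """Fitted per-node statistics, paired tests, and the clustering verdict."""

    model: SpatialClonalityModel
    per_sample: pd.DataFrame
    mi_comparison: PairedComparison | None
    voronoi_comparison: PairedComparison | None
    sample_detail: list[tuple[str, MinglingResult, NullEnsemble,
                              VoronoiClusterResult, NullEnsemble]]

    @property
    def alpha(self) -> float:
        return self.model.config.alpha

    @property
    def verdict(self) -> str:
        """"clustered" requires MI significantly below its null AND
        cells-per-cluster significantly above its null, at level alpha."""
        if self.mi_comparison is None or self.voronoi_comparison is None:
            return "undetermined"
        mi_ok = (
            self.mi_comparison.p_value < self.alpha
            and self.mi_comparison.direction == "observed_lower"
        )
        vor_ok = (
            self.voronoi_comparison.p_value < self.alpha
            and self.voronoi_comparison.direction == "observed_higher"
        )
        return "clustered" if (mi_ok and vor_ok) else "not clustered"

    def summary(self) -> str:
        """Human-readable report table plus the paired tests."""
        cfg = self.model.config
        lines = [
            "Spatial clonality analysis",
            "==========================",
            f"samples: {len(self.per_sample)}   k_neighbors: {cfg.k_neighbors}   "
            f"null iterations (MI/Voronoi): {cfg.n_null_iterations_mi}/"
            f"{cfg.n_null_iterations_voronoi}",
            f"downsample factor: {cfg.downsample_factor:g}   alpha: {cfg.alpha}   "
            f"seed: {cfg.seed}",
            "",
            self.per_sample.to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            ),
            "",
        ]
        for name, comp in (
            ("mingling index", self.mi_comparison),
            ("cells per cluster", self.voronoi_comparison),
        ):
            if comp is None:
                lines.append(f"{name}: paired test not computed "
                             "(single sample or statistic not requested)")
            else:
                lines.append(
                    f"{name}: paired t = {comp.t_statistic:.3f}, "
                    f"p = {comp.p_value:.3g}, direction = {comp.direction}"
                )
        lines.append(f"verdict: {self.verdict}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.per_sample.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        def comp_dict(c: PairedComparison | None):
            if c is None:
                return None
            return {
                "t_statistic": c.t_statistic,
                "p_value": c.p_value,
                "direction": c.direction,
                "mean_difference": c.mean_difference,
            }

        cfg = self.model.config
        obj = {
            "config": {
                "k_neighbors": cfg.k_neighbors,
                "n_null_iterations_mi": cfg.n_null_iterations_mi,
                "n_null_iterations_voronoi": cfg.n_null_iterations_voronoi,
                "downsample_factor": cfg.downsample_factor,
                "alpha": cfg.alpha,
                "seed": cfg.seed,
            },
            "per_sample": self.per_sample.to_dict(orient="records"),
            "mingling_test": comp_dict(self.mi_comparison),
            "voronoi_test": comp_dict(self.voronoi_comparison),
            "verdict": self.verdict,
        }
        s = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def plot_pairs(self, ax=None):
        """Observed-vs-null dumbbell plot for both statistics."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(7, 3.2))
        for a, (obs, nul, title) in zip(
            np.atleast_1d(ax),
            [
                (self.per_sample["mean_mi"], self.per_sample["null_mean_mi"],
                 "mingling index"),
                (self.per_sample["cells_per_cluster"],
                 self.per_sample["null_cells_per_cluster"], "cells / cluster"),
            ],
        ):
            for o, r in zip(obs, nul):
                a.plot([0, 1], [o, r], "-", color="0.7", lw=0.8)
            a.plot(np.zeros(len(obs)), obs, "o", label="observed")
            a.plot(np.ones(len(nul)), nul, "s", label="null")
            a.set_xticks([0, 1], ["observed", "null"])
            a.set_title(title)
        return ax


def clustering_report(samples, config: AnalysisConfig | None = None):
    """Functional wrapper over the model for pre-computed inputs.

    ``samples`` is a list of ``(sample_id, MinglingResult, NullEnsemble,
    VoronoiClusterResult, NullEnsemble)`` tuples.  Returns
    ``(per_sample_table, {"mean_mi": PairedComparison, "cells_per_cluster":
    PairedComparison}, verdict)``.
    """
    config = config or AnalysisConfig()
    if len(samples) < 2:
        raise InputError("clustering report needs >= 2 samples (paired tests)")
    rows = []
    for sid, mi, mi_null, vr, vr_null in samples:
        rows.append(
            {
                "sample_id": sid,
                "mean_mi": mi.mean_mi,
                "null_mean_mi": mi_null.summary,
                "cells_per_cluster": vr.cells_per_cluster,
                "null_cells_per_cluster": vr_null.summary,
            }
        )
    table = pd.DataFrame(rows)
    comps = {
        "mean_mi": paired_observed_vs_null(table["mean_mi"], table["null_mean_mi"]),
        "cells_per_cluster": paired_observed_vs_null(
            table["cells_per_cluster"], table["null_cells_per_cluster"]
        ),
    }
    mi_ok = (comps["mean_mi"].p_value < config.alpha
             and comps["mean_mi"].direction == "observed_lower")
    vor_ok = (comps["cells_per_cluster"].p_value < config.alpha
              and comps["cells_per_cluster"].direction == "observed_higher")
    verdict = "clustered" if (mi_ok and vor_ok) else "not clustered"
    return table, comps, verdict
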
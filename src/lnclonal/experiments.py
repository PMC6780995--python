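"""Repeatable synthetic experiments: power and type-I calibration.

Each synthetic *experiment* emulates one imaging study: a set of lymph
nodes is generated (clustered clonal patterns or CSR), analysed with
:class:`~lnclonal.model.SpatialClonalityModel`, and the paired
observed-vs-null tests are read out.  Repeating experiments over
independent seeds estimates the detection power on clustered data and the
type-I error rate on CSR data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DomainPolygon, make_elliptical_domain
from .mingling import AnalysisConfig
from .model import SpatialClonalityModel
from .pattern import CONFETTI_COLORS, MarkedPointPattern
from .simulate import ClonalSimConfig, simulate_clustered_pattern, simulate_csr_pattern

__all__ = [
    "default_ln_domain",
    "simulate_lymph_nodes",
    "ExperimentOutcome",
    "run_experiment",
    "repeat_experiments",
]

#: Generator defaults for one synthetic lymph node: 200 labeled progenitors,
#: 9 expected daughters each (≈2000 cells — the tile scale of the analysis),
#: 10 µm clone dispersion, equal reporter frequencies, in a 1000 × 600 µm
#: elliptical node.
DEFAULT_N_PROGENITORS = 200
DEFAULT_DAUGHTERS_MEAN = 9.0
DEFAULT_DISPERSION_SIGMA = 10.0


def default_ln_domain(n_vertices: int = 64) -> DomainPolygon:
    """A 1000 × 600 µm elliptical node outline (semi-axes 500 and 300 µm)."""
    return make_elliptical_domain(500.0, 300.0, n_vertices)


def simulate_lymph_nodes(
    kind: str,
    n_lns: int,
    seed: int,
    domain: DomainPolygon | None = None,
    n_progenitors: int = DEFAULT_N_PROGENITORS,
    daughters_mean: float = DEFAULT_DAUGHTERS_MEAN,
    dispersion_sigma: float = DEFAULT_DISPERSION_SIGMA,
    labels: tuple[str, ...] = CONFETTI_COLORS,
) -> list[MarkedPointPattern]:
    """Generate one experiment's worth of synthetic lymph nodes.

    ``kind="clustered"`` uses the clonal parent–daughter generator;
    ``kind="csr"`` places the same expected number of points
    (``n_progenitors * (1 + daughters_mean)``, split equally across colors)
    completely at random.
    """
    domain = domain if domain is not None else default_ln_domain()
    children = np.random.SeedSequence([int(seed), 11]).spawn(n_lns)
    pats = []
    for child in children:
        s = int(child.generate_state(1)[0] % (2**31))
        if kind == "clustered":
            cfg = ClonalSimConfig(
                n_progenitors=n_progenitors,
                color_probs={c: 1.0 / len(labels) for c in labels},
                daughters_mean=daughters_mean,
                dispersion_sigma=dispersion_sigma,
                domain=domain,
                seed=s,
            )
            pats.append(simulate_clustered_pattern(cfg))
        elif kind == "csr":
            n_total = int(round(n_progenitors * (1 + daughters_mean)))
            per = n_total // len(labels)
            counts = {c: per for c in labels}
            pats.append(simulate_csr_pattern(domain, counts, s))
        else:
            raise ValueError(f"unknown kind {kind!r}")
    return pats


@dataclass(frozen=True)
class ExperimentOutcome:
    """Read-out of one synthetic experiment's paired tests.

    Fields for a statistic that was not computed are NaN / "".
    """

    mi_p: float
    mi_direction: str
    voronoi_p: float
    voronoi_direction: str

    def mi_detects_clustering(self, alpha: float = 0.05) -> bool:
        return self.mi_p < alpha and self.mi_direction == "observed_lower"

    def mi_rejects(self, alpha: float = 0.05) -> bool:
        return self.mi_p < alpha

    def voronoi_detects_clustering(self, alpha: float = 0.05) -> bool:
        return self.voronoi_p < alpha and self.voronoi_direction == "observed_higher"


def run_experiment(
    kind: str,
    n_lns: int = 15,
    seed: int = 0,
    config: AnalysisConfig | None = None,
    statistics: tuple[str, ...] = ("mi", "voronoi"),
    **sim_kwargs,
) -> ExperimentOutcome:
    """Simulate ``n_lns`` nodes of the given kind and run the full analysis.

    The default analysis config uses 10 null iterations per statistic and no
    further downsampling (the synthetic nodes are generated at the ≈2000
    point scale on which the tessellation statistic operates).
    """
    config = config or AnalysisConfig(downsample_factor=1.0, seed=seed)
    pats = simulate_lymph_nodes(kind, n_lns, seed, **sim_kwargs)
    res = SpatialClonalityModel(pats, config=config).fit(statistics=statistics)
    mi, vor = res.mi_comparison, res.voronoi_comparison
    return ExperimentOutcome(
        mi_p=mi.p_value if mi else float("nan"),
        mi_direction=mi.direction if mi else "",
        voronoi_p=vor.p_value if vor else float("nan"),
        voronoi_direction=vor.direction if vor else "",
    )


def repeat_experiments(
    kind: str,
    n_experiments: int,
    n_lns: int = 15,
    seed: int = 0,
    config: AnalysisConfig | None = None,
    statistics: tuple[str, ...] = ("mi", "voronoi"),
    **sim_kwargs,
) -> list[ExperimentOutcome]:
    """Run many independent experiments, one derived seed each."""
    children = np.random.SeedSequence([int(seed), 23]).spawn(n_experiments)
    out = []
    for child in children:
        s = int(child.generate_state(1)[0] % (2**31))
        cfg = config
        if cfg is not None:
            cfg = AnalysisConfig(
                k_neighbors=cfg.k_neighbors,
                n_null_iterations_mi=cfg.n_null_iterations_mi,
                n_null_iterations_voronoi=cfg.n_null_iterations_voronoi,
                downsample_factor=cfg.downsample_factor,
                alpha=cfg.alpha,
                seed=s,
            )
        out.append(
            run_experiment(kind, n_lns=n_lns, seed=s, config=cfg,
                           statistics=statistics, **sim_kwargs)
        )
    return out
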
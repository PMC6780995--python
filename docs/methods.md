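# Methods

`lnclonal` quantifies whether color-labeled cells in a tissue section are
spatially clustered by clonal origin, or mixed as if placed at random.  The
motivating data are multicolor (Brainbow2.1/Confetti) fate-mapping images of
lymph-node stromal cells, in which every recombined cell permanently
expresses one of four reporters (nGFP, cRFP, cYFP, mCFP), so color marks
clonal origin.  The package works on *marked point patterns*: 2D point
locations in µm, one categorical color mark per point, inside a convex
tissue boundary.

## The model and its statistics

**Marked point pattern.**  Either extracted from a multichannel image
(thresholded channels; every positive pixel, or every connected-component
centroid, becomes a point) or simulated.  The tissue boundary is the convex
hull of the overlay of all colors.

**Mingling index (MI).**  For point *i* with color *m_i*,

    MI_i = (1/k) * #{ j in kNN(i) : m_j != m_i },      k = 4 by default,

where kNN(i) are the k nearest other points by Euclidean distance.  The
node-level MI is the unweighted mean over all points: 0 when every
neighborhood is exclusively one color, 1 when neighborhoods are entirely
mixed.  Under complete spatial randomness (CSR) with color frequencies
p_c, E[MI] = 1 − Σ_c p_c² (0.75 for four equal colors); for fixed positions
with permuted marks the finite-sample expectation is
1 − Σ_c n_c(n_c−1)/(n(n−1)).  Spatial clonal clustering pushes MI *below*
its null.

**Voronoi cells-per-cluster.**  The domain is tessellated into Voronoi
tiles (one per cell, clipped to the boundary so the tiles partition the
node area).  Adjacent tiles of the same color — sharing a boundary segment
of positive length; single-vertex contact does not count — are merged into
clusters, and

    cells_per_cluster = n_tiles / n_clusters.

Values near 1 mean interleaved colors; clonal patches give large values.
Under CSR with four equal colors the same-color adjacency subgraph is far
below the Delaunay site-percolation threshold (same-color edge probability
1/4 vs threshold 1/2), and cells-per-cluster is ≈ 2.5–2.6 at n = 2000 — a
value we cross-checked against an independent R implementation (deldir
Voronoi adjacency + igraph components).  For whole-node pixel patterns
(10⁵–10⁶ points) a ratio-preserving 1000-fold downsampling precedes the
tessellation: each color retains round(n_c/factor) points (round half away
from zero, floored at 1), so the reporter ratio of the subsample matches
the node.

**Randomized Poisson nulls and paired inference.**  For each node, null
patterns are CSR re-draws inside the *same* boundary with the *same*
per-color counts ("binomial" CSR: fixing the counts makes every null
exactly paired to its node and removes count variation as a nuisance).
Each statistic is recomputed on 10 null iterations per node and the
iterations averaged with means.  Across nodes, observed and null values are
compared with a two-sided paired t-test; the direction of the mean
difference is reported alongside.  A set of nodes is called *clustered*
when MI is significantly below its null AND cells-per-cluster is
significantly above its null, both at α = 0.05.  The two statistics are
confirmatory of one hypothesis, so no multiple-testing correction is
applied across them.

## Synthetic data

The generator produces the two regimes the analysis must separate:

* **CSR** — fixed per-color counts, positions i.i.d. uniform in the domain
  (rejection sampling from the bounding box).
* **Clustered clonal expansion** — a Thomas-type parent–daughter process:
  progenitors uniform in the domain, one color each (default equal
  frequencies; real Confetti outcomes are unequal, so the frequencies are a
  config parameter, not a claim), Poisson(daughters_mean) daughters per
  progenitor displaced by isotropic N(0, σ²) offsets, resampled until
  inside the domain so expected totals stay analytic.  With
  daughters_mean = 0 the process reduces exactly to CSR with multinomial
  colors.

Default study conditions for one synthetic lymph node: 200 progenitors,
9 expected daughters each (≈ 2000 cells), dispersion σ = 10 µm, equal
colors, in a 1000 × 600 µm elliptical boundary (a convex stand-in for a
node outline); experiments use 15 nodes, mirroring the node-level design of
the motivating study.  These sizes put the synthetic nodes directly at the
~2000-tile scale on which the tessellation statistic operates in real
whole-node analyses (where ~10⁵–10⁶-point patterns are first downsampled
1000-fold to ~2000 tiles).  Because the synthetic nodes are generated at
that post-downsampling scale, the analysis of synthetic experiments runs
with downsample_factor = 1; applying a further 1000-fold reduction to a
2000-point pattern would leave ~1 point per color, a degenerate
tessellation.  The downsampling operation itself is validated separately
by its exact arithmetic (4000:2000:1000:1000 → 4:2:1:1 at factor 1000).

Patterns can be rendered into multichannel images (one channel per
reporter, points as saturating discs, Gaussian background noise) to
exercise the imaging front-end.  The renderer deliberately omits
photophysics — no point-spread function, bleed-through, or depth effects —
so imaging round-trip tests certify the extraction geometry, not
robustness to real microscope artifacts.

## What passing tests show — and what they do not

The synthetic generator emulates spatial clonality, not lymph-node biology:
no tissue compartments (follicles, medulla), no density gradients, no
unequal reporter frequencies by default, no segmentation errors.  Power and
type-I figures measured on it characterize the *statistics* under the
stated conditions; they are not claims about detection rates in real
images.  Monte-Carlo campaign sizes (100 experiments for power, 200 for
type-I calibration, 10 null iterations per node) were chosen to keep
Monte-Carlo standard errors a few percent while remaining desk-scale.

## Numerical choices

* **Pixel convention** — 0-based, x = column, y = row, point at pixel
  center (col+0.5, row+0.5)·pixel_size; prevents half-pixel drift in
  round trips.
* **Thresholding** — Otsu per channel by default (deterministic and
  parameter-free); manual override available; the threshold used is
  recorded on the mask for provenance.  Pixels positive in more than one
  channel default to the brightest channel (reporters are nominally
  mutually exclusive, so ties are treated as bleed-through); an exclude
  policy is available.
* **kNN ties** — squared distances are recomputed from coordinates with a
  single arithmetic path so mathematical ties are byte-identical, then
  broken by ascending point index; this makes MI deterministic on
  pixel-grid patterns.  Duplicate coordinates are valid neighbors
  (distance 0).
* **No edge correction for MI** — boundary points use their ordinary k
  nearest neighbors; the paired null (same boundary, same counts) absorbs
  edge effects.
* **Voronoi clipping** — unbounded cells of hull sites are closed by
  extending infinite ridges far beyond the domain and clipping to the
  convex boundary (Cyrus–Beck parametric clipping); tile areas sum to the
  domain area to 1e-6 relative.  Tile adjacency is computed from ridge
  segments; the test suite validates it against an independent
  polygon-boundary-sharing oracle.
* **Duplicate sites** — merged before tessellation with a warning
  (Voronoi is undefined for coincident sites); conflicting colors at one
  coordinate raise an error.
* **Degenerate site sets** — 2–3 points or collinear configurations fall
  back to direct half-plane tile construction.
* **Seeding** — one master seed; every stochastic stage (simulation, null
  iterations, downsampling, per-sample substreams) derives independent
  substreams via `numpy.random.SeedSequence`, so identical configs produce
  byte-identical reports.
* **Probability maps** — per-color Gaussian-kernel smoothing on a grid,
  normalized across colors per cell; default bandwidth is twice the mean
  nearest-neighbor distance.  The maps are visualization aids, not
  inference.

## Open design choices made here

* MI is averaged over points of all colors jointly (the node-wide mean),
  not per color and then averaged.
* The per-node null MI is the mean of 10 randomizations (the Voronoi null
  uses 10 by published protocol; MI adopts the same count for symmetry;
  both configurable).
* Tests are two-sided with direction reported, α = 0.05.
* Null positions are freshly simulated CSR rather than mark permutations;
  a permutation mode can be emulated by shuffling marks upstream.

## Known limitations

2D only; homogeneous CSR nulls (no intensity-matched inhomogeneous
alternative); no hierarchical modeling across mice; no weighted or periodic
tessellations; manual tissue masking is taken as given rather than
re-implemented as a segmenter.
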
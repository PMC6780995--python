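# lnclonal

Spatial clonality analysis for multicolor (Confetti/Brainbow2.1)
fate-mapping of lymph-node stromal cells.

In Confetti fate-mapping, each recombined cell permanently expresses one of
four fluorescent reporters (nGFP, cRFP, cYFP, mCFP), so color marks clonal
origin.  If stromal cells differentiate locally from single labeled
progenitors, same-color cells should form spatial patches; if fates are
assigned independently of position, colors should be mixed.  `lnclonal`
turns multichannel fluorescence images — or pre-extracted tables of
(x, y, color) points — into that comparison, for imaging scientists and
spatial statisticians working with clonal labeling data.

## The statistics

For a marked point pattern (points in µm, one categorical color each,
inside a convex tissue boundary):

* **Mingling index (MI)** — per point, the fraction of its k = 4 nearest
  neighbors carrying a *different* color, averaged over the node:
  MI = 0 for locally monochrome tissue, MI = 1 for entirely mixed;
  E[MI] = 1 − Σ_c p_c² under complete spatial randomness (0.75 for four
  equal colors).  Clonal clustering pushes MI **below** its null.
* **Voronoi cells-per-cluster** — the node is tessellated into Voronoi
  tiles (clipped to the boundary); adjacent same-color tiles merge into
  clusters; the statistic is n_tiles / n_clusters.  Clonal patches push it
  **above** its null.  Whole-node pixel patterns are first downsampled
  1000-fold, preserving the reporter ratio per color.
* **Randomized Poisson nulls** — per node, CSR re-draws with the same
  boundary and the same per-color counts; 10 iterations per statistic,
  averaged with means.  Across nodes, observed vs null is tested with a
  paired t-test; "clustered" requires MI significantly low *and*
  cells-per-cluster significantly high.

A synthetic generator (CSR and a Thomas-type clustered clonal process,
plus an image renderer) stands in for the mouse imaging data, and a
tdTomato-style area-fraction quantifier covers binary coverage
measurements.

## Worked example

```python
from lnclonal import AnalysisConfig, SpatialClonalityModel
from lnclonal.experiments import simulate_lymph_nodes

patterns = simulate_lymph_nodes("clustered", 5, seed=42)   # 5 synthetic nodes
config = AnalysisConfig(downsample_factor=1.0, seed=0)
results = SpatialClonalityModel(patterns, config=config).fit()
print(results.summary())
```

prints

```
Spatial clonality analysis
==========================
samples: 5   k_neighbors: 4   null iterations (MI/Voronoi): 10/10
downsample factor: 1   alpha: 0.05   seed: 0

sample_id  n_points  mean_mi  null_mean_mi  n_tiles  n_clusters  cells_per_cluster  null_cells_per_cluster
     LN01      1985   0.2426        0.7463     1985         154            12.8896                  2.5672
     LN02      2027   0.2111        0.7408     2027         129            15.7132                  2.6140
     LN03      2043   0.2030        0.7433     2043         138            14.8043                  2.5810
     LN04      2024   0.1934        0.7428     2024         124            16.3226                  2.5937
     LN05      2014   0.2378        0.7473     2014         160            12.5875                  2.6237

mingling index: paired t = -60.195, p = 4.56e-07, direction = observed_lower
cells per cluster: paired t = 15.916, p = 9.11e-05, direction = observed_higher
verdict: clustered
```

Each row is one synthetic lymph node of ≈ 2000 cells grown from 200
color-labeled progenitors (clone dispersion 10 µm).  Observed MI ≈ 0.22
sits far below the ≈ 0.75 of its paired random null, and
cells-per-cluster ≈ 13–16 far above its null of ≈ 2.6 — both paired tests
agree, so the verdict is "clustered".  CSR input instead yields MI ≈ 0.75,
cells-per-cluster ≈ 2.6, and non-significant tests.

The same analysis runs from the shell:

```
lnclonal simulate --mode clustered --replicates 15 --outdir sim/
lnclonal analyze sim/ln*.csv --outdir out/ --factor 1
```

and on images: `lnclonal analyze section.tiff --channel-map
'0=nGFP,1=cRFP,2=cYFP,3=mCFP' --outdir out/`.

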
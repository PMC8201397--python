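# uavfield

Analysis of UAV-supported field experiments: predict a ground-sampled crop
trait from multi-date drone imagery indices, map the prediction over a
fine grid of the whole field, and test experimental treatments on the
dense predicted values with spatially structured mixed models.

## The problem

Field experiments — crop-rotation trials, cultivar comparisons, fertilizer
studies — suffer from two chronic issues: large spatial heterogeneity
(fertility trends, topography) and small sample sizes, because manual
harvesting and weighing is slow. A drone survey, by contrast, yields
millions of georeferenced pixels of canopy cover, plant height and NDVI in
minutes. `uavfield` integrates the two data sources:

1. **Model** — regress the manually harvested trait (e.g. wheat ear dry
   weight per 1 m² quadrat, `y_p`) on the quadrat-mean imagery indices
   `x̄_{i,p}`, searching *all* subsets of the m candidates with a Gaussian
   linear model and ranking by AIC (full Gaussian log-likelihood; the
   parameter count k includes intercept, slopes and residual variance;
   Akaike weights `exp(−ΔAIC/2)/Σexp(−ΔAIC/2)`).
2. **Map** — apply the best model pixel-wise over the field, divide the
   field into 25 cm × 25 cm cells, discard cells touching two plots or
   mixing plot and corridor, and average predictions per retained cell:
   `ŷ_c = Σ_{p∈c} ŷ_p / n_c`.
3. **Test** — fit linear mixed models to the thousands of cell predictions
   with random intercepts for the sowing row and the plot nested in the
   row (avoiding pseudo-replication from ~125 correlated cells per plot),
   likelihood-ratio tests for treatment terms, Wald z contrasts against
   the lowest-yield treatment level, and marginal-effect surfaces for
   trait × trait interactions.

Because datasets of this kind are rarely public, the package ships a
synthetic experiment generator with known ground truth (latent yield
surface, true index subset, true effects and variance components), so the
whole pipeline is testable by parameter recovery. See `docs/methods.md`
for the models, defaults and limitations.

## Worked example

Run the full pipeline on a synthetic full-scale experiment (40 m × 50 m,
70 plots of 2.4 m × 4.2 m, 14 soybean cultivars preceding a wheat crop,
one quadrat per plot plus 84 adjacent points) in which cultivar v5 has
been given a +60 g rotational benefit:

```python
import dataclasses
from uavfield.config import PipelineConfig
from uavfield.pipeline import run_all
from uavfield.synthetic import detection_config

syn = dataclasses.asdict(detection_config(effect=60.0, random_seed=7))
syn["trait_effect_spec"] = {}
cfg = PipelineConfig(output_dir="demo", seed=7, synthetic=syn)
run_all(cfg)
```

or, from the shell, `uavfield run --config demo.yaml`. The run directory
then contains the ranked model search (`selection_table.csv`):

```
 rank                                                 spec  r_squared  df         aic  delta_aic   weight
    1            C_Mar.14 + C_Apr.12 + H_Mar.14 + N_Apr.12   0.516236   6 1390.793610   0.000000 0.332572
    2 C_Mar.14 + C_Apr.12 + H_Mar.14 + H_Apr.12 + N_Apr.12   0.518248   7 1392.151669   1.358059 0.168650
```

— the rank-1 model is exactly the generating subset (two cover dates, one
height, one NDVI; df = 6 because k counts the 4 slopes, the intercept and
the residual variance). The gridding summary (`grid_summary.json`) shows
the scale change from 148 usable quadrats to ~9.7k cell predictions:

```
 "n_cells_retained": 9657,  "mean_cells_per_plot": 137.96,
 "retained_area_m2": 603.56, "pct_outside_iqr": 59.4
```

and the treatment test (`cultivar_lrt.json`, `cultivar_contrasts.csv`)
recovers the planted effect: the cultivar likelihood-ratio test gives
χ²(15) = 63.5, p = 6.2e-08, and the contrast table against the
lowest-yield cultivar (v9 in this realization) flags v5 and only v5 at the
1 % level:

```
cultivar  estimate        se        z            p mark
      v5 69.517488  9.831266 7.071062 1.537530e-12   **
      v3 21.873272 10.131823 2.158868 3.086038e-02    *
```

The estimate 69.5 ± 9.8 g brackets the true +60 g (the reference cultivar
sits below the mean, shifting all contrasts up). On an all-null
configuration the same test stays quiet at close to the nominal 5 % rate —
that calibration is part of the test suite.

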
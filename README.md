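# reefscape

Structural-complexity metrics, tidal accessibility and herbivorous-fish
distribution models for coral-reef habitat zonation studies.

Reef habitats differ enormously in physical structure — from rugose,
crevice-rich slopes and crests to flat, sandy inner reef zones — and that
structure shapes where roving herbivorous fishes (parrotfishes,
surgeonfishes, rabbitfishes) feed. `reefscape` implements the full
quantitative pipeline for studying this zonation from cross-section
elevation profiles (e.g. extracted from photogrammetric reconstructions):

- **`reefscape.profiles`** — structural metrics along a transect profile:
  rugosity index (contour/planar length ratio), verticality (mean absolute
  elevation change per 10 cm interval), contour-weighted benthic cover
  fractions, grazing surface area (turf/EAM cover), and rule-based refuge
  detection (crevices 10–20 cm wide and ≥ 10 cm deep that admit a 10 cm
  disc, plus near-vertical surfaces > 10 cm high). Profiles can be sampled
  from a DEM raster along arbitrary transect endpoints.
- **`reefscape.viewshed`** — the feeding field-of-view: the fraction of the
  upward 90° quadrant unobstructed by terrain for virtual observers placed
  along the transect at feeding-fish eye height.
- **`reefscape.tides`** — Rule-of-Twelfths tidal interpolation from
  high/low-water tables, tide-corrected depths, and the percentage of time
  each habitat holds enough water for fishes to graze.
- **`reefscape.fish`** — standardisation of timed-swim belt-transect
  surveys to densities per 250 m², allometric biomass (W = a·L^b at
  size-class midpoints), and unit × species assemblage matrices.
- **`reefscape.models`** — hierarchical Bayesian GLMMs with a site random
  intercept: habitat-contrast models (Gaussian / beta / negative-binomial /
  Gamma families) summarised as per-habitat means with 95% HPDIs and
  pairwise contrasts, and fish-distribution models with covariate selection
  by collinearity screening, PC1 composites and exact leave-one-out
  cross-validation.
- **`reefscape.multivariate`** — zero-adjusted Bray–Curtis dissimilarities
  and marginal distance-based linear models (DistLM) with permutation
  pseudo-F tests.
- **`reefscape.synthetic`** — seeded synthetic field campaigns (3 sites ×
  5 habitat zones × 2 reconstructions × 5 transects by default) with known
  ground truth, used to validate the whole pipeline end to end.

## Worked example

Simulate a campaign, compute the per-transect metrics, select and fit the
fish-distribution model:

```python
import numpy as np
from reefscape.synthetic import generate_study, metrics_table, unit_covariates
from reefscape.fish import build_assemblage
from reefscape.models import ModelSpec, loo_select, fit_habitat_model, hpdi

bundle = generate_study(seed=7)
metrics = metrics_table(bundle)
print(metrics.groupby("habitat")[["rugosity", "refuge_count", "grazing_area"]].mean().round(3))

units = build_assemblage(
    bundle.fish_records, lw_params=bundle.lw_params,
    covariates=unit_covariates(metrics, bundle),
)["units"]
candidates = [
    ModelSpec(response="total_abund_250m2", family="gamma-log", fixed=("grazing_area",)),
    ModelSpec(response="total_abund_250m2", family="gamma-log", fixed=("depth",)),
]
selection = loo_select(candidates, units, seed=1)
print(selection.table)

fit = fit_habitat_model(selection.best, units, seed=2)
lo, hi = hpdi(fit.slope_draws["grazing_area"])
print(f"grazing slope: mean={np.mean(fit.slope_draws['grazing_area']):.2f} "
      f"95% HPDI=({lo:.2f}, {hi:.2f}) P(slope>0)={fit.p_positive('grazing_area'):.3f}")
```

Output:

```text
            rugosity  refuge_count  grazing_area
habitat
crest          1.332         5.367         0.408
inner_flat     1.010         0.200         0.195
mid_flat       1.042         0.733         0.241
outer_flat     1.102         1.833         0.587
slope          1.449         5.000         0.392
                            model  n_covariates   elpd_loo  rank
0  total_abund_250m2~grazing_area             1 -51.542589     1
1         total_abund_250m2~depth             1 -68.423210     2
grazing slope: mean=3.38 95% HPDI=(2.53, 4.23) P(slope>0)=1.000
```

The study was generated with a log-linear grazing→abundance slope of 3.0;
the pipeline selects the grazing model by leave-one-out cross-validation
and recovers the slope within its 95% HPDI.

## Command line

The same stages are available as subcommands of the `reefscape` CLI:

```bash
reefscape simulate --seed 11 --out bundle/
reefscape metrics --profiles bundle/profiles --segments bundle/segments --out metrics.csv
reefscape accessibility --tides bundle/tides.csv --depths bundle/depths.csv --out access.csv
reefscape fish --surveys bundle/fish_surveys.csv --lw bundle/lw_params.csv --out density.csv
reefscape distlm --assemblage assemblage.csv --covariates grazing_area,depth --out distlm.csv
reefscape fit --config models.yaml --data metrics.csv --out fits/
```

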
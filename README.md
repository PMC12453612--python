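# volehabitat

Drone-image analysis of habitat selection by fossorial water voles
(*Arvicola amphibius*) on dandelion (*Taraxacum officinale*) density in
mountain meadows — rebuilt as a tested, reusable pipeline with a synthetic
scene generator standing in for the field imagery.

Meadow quadrats (80 m × 60 m, 1 cm/pixel RGB orthomosaics, three dates a
year over two years) are classified pixel by pixel: yellow pixels
(`R > 0.9, G > 0.9, B < 0.1`) are dandelion flower heads (7 cm² each),
brown pixels (per-image calibrated window) are the earth mounds voles eject
while burrowing.  Each quadrat is summarised into 1200 tiles of 2 m × 2 m;
a tile is *colonized* when mounds cover more than 2.5 % of it.  Three
questions are then asked of the tile table and of colony-centred point
maps:

* **Colonization** — on tiles free in March, is the probability of being
  colonized by October driven by flower density?  Binomial GLM
  `Col ~ Anom * D_q + Q`, where `D_t`, `D_q` are tile and quadrat-mean
  flower densities (heads/m²), `Anom = (D_t/D_q)^{1/4} − 1` is the local
  density anomaly, and `Q` is the quadrat factor.
* **Reuse** — on tiles colonized in October and the following March, does
  continued use depend on the remaining flowers?
  `Reuse ~ D_t + D_t:D_q + Q`.
* **Depletion** — do flowers decline after colonization?  Broad scale:
  `DPGR ~ log(Cover + 1) + Q` with `DPGR = ln(F₂/F₁)` and `Cover` the
  percent March mound cover.  Fine scale: the depletion ratio `DD` (flower
  density in 20 log-spaced distance-to-mound buffers, 5 cm–5 m, relative
  to the subplot mean) modelled as `DD ~ s(log DM) + (1|subplot)` — a
  Gaussian additive model with a P-spline on log distance and a
  ridge-penalized subplot intercept, REML smoothing.

Model families are compared with explicit AIC ladders and greedy forward
selection.  The synthetic generator produces the exact statistical
structure these analyses assume — Thomas-clustered flowers, logit-driven
colonization, mound colonies, kernel thinning near mounds, rendered
rasters — so every stage is validated against known ground truth without
downloading anything.

## Worked example

Fit the depletion profile on simulated colony subplots:

```python
import numpy as np, pandas as pd
from volehabitat import depletion as dep
from volehabitat import experiments as ex

subplots = ex.simulate_subplots(30, seed=20212, depletion_delta=0.8, depletion_range=4.0)
records = pd.concat([dep.depletion_profile(sp) for sp in subplots], ignore_index=True)
fit = dep.fit_depletion_gam(records)
print(dep.depletion_ladder(records).rows.round(2).to_string(index=False))
print(f"depletion measurable up to {dep.detectable_depletion_range(fit):.2f} m")
```

prints

```
                           model   df     AIC   dAIC  explained_variance
                    DD ~ Subplot 30.0  388.50 912.91                0.02
                      DD ~ s(DM)  5.1 -520.41   3.99                0.76
                 DD ~ s(log(DM))  6.5 -516.09   8.32                0.76
     DD ~ s(DM) + s(Subplot, re) 13.9 -524.41   0.00                0.77
DD ~ s(log(DM)) + s(Subplot, re) 15.3 -520.06   4.35                0.77
depletion measurable up to 3.07 m
```

— the distance smooths dominate the subplot-only model by ~900 AIC; the
fitted ratio at 10 cm from a mound is ≈ 0.26 (a quarter of the subplot
mean density) and the curve's pointwise interval stays below 1 out to
about 3 m, inside the 4 m thinning range the subplots were generated with.
On these kernel-thinned records the raw- and log-distance smooths are
nearly equivalent (ΔAIC ≈ 4); the log form wins systematically when the
underlying curve is log-linear, which is what the selection-consistency
experiment checks.

The habitat-model side, at study scale (`analysis/03_habitat_models.py`):

```
colonization coefficients (true 1.8, 0.01, -0.02):
          estimate      se    p
Anom        1.7331  0.0648  0.0
D_q         0.0094  0.0014  0.0
Anom:D_q   -0.0186  0.0028  0.0
stepwise selected: Col ~ 1 + Anom + D_q + Anom:D_q + Q
```

— the fitted logit recovers the generating coefficients within their
standard errors, and forward-stepwise AIC lands on the generating
interaction structure.  The negative interaction means local anomalies
matter most in flower-poor quadrats.

## Analysis scripts

Numbered drivers under `analysis/` run the study start to finish and write
tables to `results/` (rasters go to `scratch/`):

1. `01_simulate_scenes.py` — render a two-quadrat, six-date synthetic survey
2. `02_classify_and_tile.py` — classify the scenes, build the tile table
3. `03_habitat_models.py` — AIC ladders, coefficients, prediction curves
4. `04_depletion_profile.py` — buffers, GAM curve, depletion ladder
5. `05_validation_summary.py` — recovery bias/coverage and selection rates

A `volehabitat` CLI exposes the same stages (`simulate`, `classify`,
`tiles`, `fit`, `depletion`, `run-all`) with `--seed`, `--config` and
`--out-dir`; each run writes a manifest with per-artifact checksums so
outputs are reproducible from config + seed alone.

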
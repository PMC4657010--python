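# occuscale

**Scale sensitivity of camera-trap occupancy models.**

Wildlife surveys increasingly pair camera-trap detection data with habitat
covariates extracted from classified satellite imagery. Both the *grain*
(pixel size) of the land-cover raster and the *extent* (radius of the focal
patch around each camera) of those covariates are analysis choices — and
they change the answers. `occuscale` is a tested pipeline for studying that
sensitivity: it generates synthetic rainforest landscapes and camera-trap
detection histories with known truth, derives habitat covariates at
multiple grains and extents, fits single-season occupancy models by maximum
likelihood, runs AIC-based model selection including a cross-species
consensus-radius procedure, and checks model adequacy with a
parametric-bootstrap goodness-of-fit test. The same covariate and modelling
code paths accept real inputs (an ASCII land-cover grid, station and record
CSVs, canopy transect CSVs).

It is written for quantitative ecologists and biostatisticians who want to
probe how robust occupancy inference is to spatial-scale decisions before
committing to a field protocol or a remote-sensing product.

## The model

Occupancy state and detections are two Bernoulli stages with logit links:

    z_i  ~ Bernoulli(ψ_i),              logit(ψ_i)  = β₀ + β₁ x_i
    y_ik | z_i ~ Bernoulli(p_ik z_i),   logit(p_ik) = γ₀ + γ' w_ik

Marginalising z gives the likelihood per site; models are ranked by
AIC = −2ℓ̂ + 2K with Akaike weights w_m = exp(−Δ_m/2)/Σ_j exp(−Δ_j/2).
Habitat covariates follow the standard multi-scale battery: distance to
plantation / water at grains 5–250 m (majority-resampled raster), forest
score FS ∈ [0, 3] (weighted mean of class proportions, weights 0–3 by
forest quality), land-cover heterogeneity HET (Pielou's evenness) at radii
10–500 m, and in-situ canopy closure CC at 50–150 m. Details, including all
tie-break and edge-case conventions, are in [docs/methods.md](docs/methods.md).

## Worked example

Run the whole synthetic experiment (landscape → covariates → detection
simulation for six species → detection-model selection → grain and extent
comparisons → consensus radius → goodness of fit; a few minutes):

```bash
occuscale all --seed 1 --n-boot 99 --outdir demo_run
```

or equivalently from Python:

```python
from occuscale.pipeline import Experiment, ExperimentConfig
exp = Experiment(ExperimentConfig(master_seed=1, n_boot=99))
exp.run_all("demo_run")
```

`demo_run/goal1_water_fine_DWATER.csv` — AIC table for the distance-to-water
covariate at four grains, for the synthetic species whose occupancy is tied
to fine-grain water (slope −2 per SD at the 5-m grain):

```
model    AIC  dAIC  wAIC beta1   SE   CV p_value
    5 850.38  0.00 0.511 -2.06 0.37 0.18     0.0
   30 850.47  0.09 0.489 -2.06 0.37 0.18     0.0
   90 893.34 42.96 0.000 -0.85  0.2 0.24     0.0
  250 900.75 50.37 0.000 -0.67 0.19 0.28  0.0004
    — 912.32 61.94 0.000     —    —    —       —
```

The fine-grain models dominate (ΔAIC ≈ 43–50 against the 90/250-m grains,
which lose the small water features to majority resampling) and the fitted
slope recovers the generating value −2.06 ± 0.37. The matching
`...DPLANT.csv` tables are flat across grains (ΔAIC < 0.1): distance to a
large contiguous block does not depend on resolution. "—" is the
constant-occupancy model.

`demo_run/goal2_cumulative_dAIC.csv` — cumulative ΔAIC per radius summed
over the six species, per covariate family:

```
 radius    FS   HET    CC
   10.0 12.01 30.43     —
   50.0  6.25 19.25  6.65
  100.0 12.18 36.05 14.32
  150.0 20.87 35.16 23.66
  250.0 30.24 29.61     —
  500.0 42.29 35.35     —
```

The 50-m radius minimises the total over the radii available to every
family (50/100/150, since canopy transects reach only 150 m), so the
consensus radius is **50 m**. `demo_run/gof_summary.csv` shows the
MacKenzie–Bailey bootstrap per species' global model — all p-values ≥ 0.09
and variance-inflation factors ĉ between 0.90 and 1.23, i.e. no evidence of
lack of fit on these well-specified data:

```
        species   chisq  p_value  c_hat  n_boot  converged
     water_fine  841.09     0.66  0.952      99       True
   water_coarse 1197.13     0.24  1.080      99       True
      forest_50  800.41     0.63  0.895      99       True
      hetero_50 1200.55     0.09  1.231      99       True
      canopy_50 1086.85     0.40  1.031      99       True
plantation_edge 1171.46     0.11  1.155      99       True
```

Every output directory also contains the landscape (`landscape.asc`, ESRI
ASCII grid), the station table, the full covariate table, and a
`manifest.json` recording seeds, timings and the file inventory.

## Layout

```
src/occuscale/
  raster.py      land-cover raster container, ESRI ASCII grid I/O
  covariates.py  majority resampling, distances, focal patches, FS/HET/CC
  synthetic.py   landscape / station / detection-history generators
  occupancy.py   likelihood, ML fitting, Wald inference, simulation
  selection.py   Akaike weights, two-stage selection, consensus radius
  gof.py         MacKenzie–Bailey χ², parametric bootstrap, c-hat
  pipeline.py    experiment orchestration, manifests, seed splitting
  cli.py         `occuscale` command (simulate/covariates/goal1/goal2/gof/all)
```
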
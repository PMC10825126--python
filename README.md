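# camcat

Camera-trap analysis of two sympatric species — Bayesian occupancy
modelling, diel-activity overlap, and detection mapping — built for studies
of small cats (e.g. jungle cat *Felis chaus* and leopard cat *Prionailurus
bengalensis*) sharing a landscape, and for anyone asking how two species
partition space and time from camera-trap detections.

## What it computes

**Occupancy.** For each species, a single-season occupancy model

&nbsp;&nbsp;&nbsp;&nbsp;z_i ~ Bernoulli(ψ_i), &nbsp; logit(ψ_i) = x_i′β
&nbsp;&nbsp;&nbsp;&nbsp;y_i ~ Binomial(n_i, p_i·z_i), &nbsp; logit(p_i) = w_i′α

separates where a species *is* (ψ, occupancy, driven by site covariates:
canopy cover, large-predator presence, livestock, humans, the other cat)
from how often it is *seen* (p, detection, driven by distances to water,
road, settlement). Detection histories are binary site × weekly-occasion
matrices built from 30-minute-independent photo events. Fitting is by
MCMC (adaptive random-walk Metropolis on the z-marginalized likelihood,
plus exact Gibbs draws of the latent states); summaries report posterior
mean, SD, 95% credible interval, split-chain Rhat, ESS, whether the
interval overlaps 0, and the posterior sign probability f. Species are
compared with a Welch t-test on per-site posterior means.

**Temporal overlap.** Event times become angles on the 24-h circle,
smoothed with von Mises kernel density estimates (plug-in concentration,
adjust 0.8). The overlap coefficient Dhat1 is the area under the pointwise
minimum of the two densities (0 = disjoint activity, 1 = identical), with
norm0 bootstrap confidence intervals (999 smoothed-bootstrap replicates)
and optional stratification (inside/outside protected areas, with/without
large predators).

**Detection mapping.** Per-site detection frequency (proportion of
occasions with a detection) is interpolated onto a raster by inverse
distance weighting (power 2) and written as an ESRI ASCII grid.

**Synthetic studies.** A generator reproduces the whole design — 154 sites
≥ 1 km apart, 21-day deployments in three weekly occasions (3234
trap-days), covariates with realistic field moments, logit-linear
occupancy/detection with known coefficients, bimodal nocturnal activity
mixtures — so every stage can be validated against ground truth.
See `docs/methods.md` for models, numerical choices, and limitations.

## Worked example

```python
from camcat import (simulate_study, standardize, screen_collinearity,
                    OccupancyModelSpec, MCMCSettings, run_mcmc, summarize,
                    derive_site_probabilities, to_radians, DielSample,
                    bootstrap_ci)

study = simulate_study(seed=7)          # 154-site two-species survey
cov = study["covariates"]
cov["othercat"] = cov["leopardcat"]     # the other cat as a covariate

spec = OccupancyModelSpec()
design = standardize(cov, sorted(set(spec.psi_covariates) | set(spec.p_covariates)))
assert screen_collinearity(design).passed   # no |r| > 0.7 pairs

draws = run_mcmc(study["history_junglecat"], design, spec,
                 MCMCSettings(chains=3, adapt=1000, burn=1000,
                              iterations=5000, seed=7))
print(summarize(draws).round(3))
```

```
                    mean     sd    lci    uci   rhat       ess  overlap0      f
parameter
psi_intercept     -1.476  0.374 -2.279 -0.793  1.000  1258.672         0  1.000
psi_canopycover   -0.107  0.251 -0.606  0.386  1.000  3073.013         1  0.665
psi_predators      0.385  0.230 -0.066  0.836  1.000  3474.638         1  0.952
...
p_dist_settlement -0.824  0.310 -1.431 -0.215  1.000  3375.150         0  0.997
```

Every Rhat is below the 1.1 convergence threshold. `overlap0 = 0` flags
coefficients whose 95% credible interval excludes zero — here the occupancy
intercept (baseline occupancy well below 0.5 at average covariates), and
`f` gives the posterior probability of the reported sign. Pushing the draws
through the inverse logit gives per-site probabilities:

```python
probs = derive_site_probabilities(draws)
print(probs["psi_mean"].mean(), probs["p_mean"].mean())
# 0.266 0.450   (true simulated values: psi ~ 0.25, p ~ 0.5)
```

Diel overlap between the two species from the same simulated records:

```python
rec = study["records"]
a = DielSample(to_radians(rec.loc[rec.species == "junglecat", "timestamp"]))
b = DielSample(to_radians(rec.loc[rec.species == "leopardcat", "timestamp"]))
print(bootstrap_ci(a, b, reps=999, seed=7))
# Dhat1 = 0.680 (norm0 CI 0.561-0.799, n=52/62)
```

The two preset activity patterns (early-morning-peaked vs evening-peaked
nocturnal mixtures) share about two-thirds of their activity time; the CI
is wide because only ~50 independent events per species exist, as in a
one-season field study.

The same workflow is scriptable from the shell:

```bash
camcat simulate --seed 1 --out data/
camcat occupancy --records data/records.csv --covariates data/covariates.csv \
                 --seed 1 --out fits/
camcat overlap   --records data/records.csv --covariates data/covariates.csv \
                 --seed 1 --out overlap/
camcat idw-map   --records data/records.csv --covariates data/covariates.csv \
                 --out maps/ --cell-size 2000
```

Each command writes a JSON sidecar with the config hash and seed; identical
config + seed reproduces every CSV byte for byte.

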
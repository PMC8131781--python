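# invaniche

Niche modeling for invasive species that are **not in equilibrium** with
their new range: reciprocal native/invaded maximum-entropy climate models
with background weighting, landscape and dispersal covariates, paired
distribution and severe-impact models, and AUC / continuous-Boyce-index
evaluation — all exercisable end to end on synthetic virtual-species
landscapes with known generative truth.

## The problem

A species distribution model (SDM) fitted only to an invader's current
occurrences underestimates its potential range: climatically suitable
sites the species has simply not reached yet sit in the background sample
as *false absences*, and the occupied climate envelope is a truncated
subset of the fundamental niche.  A model fitted only to the native range
transfers poorly in the other direction.  The workflow implemented here
combines both sources:

1. **MaxEnt core.**  A Gibbs density over environmental space,
   q_λ(x) = w(x)·exp(λ·f(x))/Z with Z = Σ_background w(x)·exp(λ·f(x)),
   where f(x) are standardized linear + quadratic features (one-hot for
   categoricals).  Fitting maximizes the mean presence log-likelihood
   minus an L1 penalty Σ_j ρ_j|λ_j|, ρ_j = β·s_j/√m (β = 3 by default).
   Predictions use the cloglog transform.
2. **Background weighting.**  Each invaded-range background point is
   weighted by w(p) = 1/(1 + (p/(1−p))²), where p is the *native* model's
   projected suitability at that point — likely false absences count for
   little, agreed-upon true absences keep full weight.
3. **Regional models.**  Occurrence distribution and severe-impact models
   at landscape resolution, driven by the weighted climate projection,
   topography, habitat composition (focal forest cover, basal area, patch
   fragmentation/heterogeneity, host cover within the yearly flight
   distance) and minimum distance to the previous year's records —
   plus "Reduced" variants with a 10 km presence-buffered, host-masked
   background that remove the dominant distance and host signals.
4. **Evaluation.**  Presence/background AUC (Mann–Whitney) and the
   continuous Boyce index (Spearman correlation of the predicted-to-
   expected ratio across sliding suitability windows), with replicated
   70/30 presence splits.

Because the real datasets behind such studies (occurrence archives,
bioclimate rasters, forestry maps) are external, the package ships a
first-class **virtual-species generator**: spatially autocorrelated,
collinear climate layers; clustered host/habitat/DEM rasters; equilibrium
(native-range analog) sampling and dispersal-limited invasion-front
simulation with 4-level impact severity linked to suitability.  The
generative parameters are retained as the oracle for recovery tests.

## Worked example

```python
from invaniche import experiments as ex

# recover a known quadratic niche from 500 equilibrium occurrences
rec = ex.equilibrium_recovery(seed=0)
print("spearman(true, predicted) =", round(rec["spearman_true_vs_predicted"], 3))
print("fitted niche optimum at z =", round(rec["response_peak_clim1"], 3))

# two-region transfer experiment under niche truncation
run = ex.transfer_ordering(seed=1)
for name in ("clim_native", "clim_invaded", "clim_weighted"):
    print(f"{name:14s} home AUC {run['calibration_auc'][name]:.3f}"
          f"  transfer AUC {run['transfer_auc'][name]:.3f}")
```

prints

```
spearman(true, predicted) = 1.0
fitted niche optimum at z = -0.017
clim_native    home AUC 0.779  transfer AUC 0.650
clim_invaded   home AUC 0.901  transfer AUC 0.561
clim_weighted  home AUC 0.896  transfer AUC 0.593
```

The fitted model ranks every landscape cell essentially identically to
the generative truth and places the niche optimum at the true value
(z = 0, within 0.02 sd).  In the two-region run the invaded-range-only
model looks best at home but collapses when projected onto the native
range (0.90 → 0.56), while background weighting recovers part of that
transfer loss (0.59) at a negligible cost at home — the signature pattern
of niche truncation.  Single seeds vary; the multi-seed means are what
the test suite asserts.

There is also a CLI for the file-based workflow:

```sh
invaniche simulate --config study.yaml --out out/ --seed 3
invaniche pipeline --config study.yaml --out out/ --seed 3
invaniche select-vars --background bg.csv --presences occ.csv --out report.json
```

Rasters are read and written as ESRI ASCII grids; occurrences as CSV
(`x,y,year,severity,source`); models and reports as JSON.

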
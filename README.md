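# copulageo

Joint copula geo-additive regression for paired binary child-health
outcomes — childhood **anaemia** (haemoglobin < 9.9 g/dL) and
**malnutrition** (weight-for-age z-score < −3.0) — for epidemiologists and
biostatisticians analysing DHS-style survey data, where the two conditions
co-occur and their association varies across regions.

## The model

For child *k*, each binary outcome has a marginal event probability built
from a geo-additive predictor,

p<sub>km</sub> = g<sub>m</sub><sup>−1</sup>( x<sub>km</sub>ᵀβ<sub>m</sub> + f<sub>m</sub>(age<sub>k</sub>) + u<sup>str</sup><sub>r(k),m</sub> + u<sup>unstr</sup><sub>r(k),m</sub> ),

with categorical fixed effects, a penalized cubic-spline age smooth, and
structured (intrinsic autoregressive over the region adjacency graph) plus
unstructured (i.i.d.) region effects. The two margins are coupled by an
Archimedean copula C(·,·; θ) — Clayton, Gumbel, or Frank — giving the four
joint cell probabilities by inclusion–exclusion:

P(Y₁=1, Y₂=1) = C(p₁, p₂; θ),  P(Y₁=1, Y₂=0) = p₁ − C(p₁, p₂; θ),  …

Fitting is penalized maximum likelihood with AIC-driven smoothing-parameter,
copula-family, and link-pair selection (AIC = −2 log L + 2 V with V the
effective degrees of freedom); inference is Wald-based (per-coefficient z
tests, block chi-square tests for the smooth and spatial terms); the
model-implied dependence is reported as Kendall's τ. The endpoint of the
pipeline is the four joint outcome probabilities averaged per region,
exported as CSV/GeoJSON for mapping. See `docs/methods.md` for the full
account.

Because the underlying survey microdata is access-restricted, the package
ships a first-class synthetic generator that emulates the study's structure
(covariate frequencies, age profile, spatial correlation, copula
dependence) with known ground truth, plus the study's printed 2×2
contingency table as a fixture.

## Worked example

```python
import copulageo as cg

ds = cg.simulate_dataset(cg.SyntheticConfig(n=4000, grid=(4, 4),
                                            family="gumbel", theta=2.0, seed=1))
fit = cg.fit_model(cg.ModelSpec.geoadditive(), ds.records, graph=ds.graph)
print(fit.theta_hat.theta, fit.aic)
tau, ci = cg.model_kendall_tau(fit)
print(tau, ci)
table = cg.region_average(cg.predict_joint(fit, ds.records))
print(table.head(3))
```

prints:

```
2.045 8932.1
0.511 (0.482, 0.54)
region_id    p11    p10    p01    p00   n
      R00 0.5235 0.1520 0.0681 0.2564 239
      R01 0.5324 0.1483 0.0692 0.2501 253
      R02 0.4732 0.1710 0.0668 0.2889 254
```

The first line is the fitted Gumbel dependence parameter (truth 2.0) and
the model AIC; the second is the model-implied Kendall τ with its 95%
delta-method interval (truth 0.5 — strong positive dependence between the
two conditions); `p11` is the region-average probability that a child has
*both* conditions — the quantity behind joint-probability maps.
`examples/` contains narrated scripts for each capability: the copula
primitives, the descriptive contingency analysis, simulation + fitting,
AIC model selection, and region-table export.

A thin CLI wires the same stages for shell use:

```sh
copulageo simulate --config sim.yaml --seed 9 --out data
copulageo select   --observations data/observations.csv --out sel
copulageo fit      --observations data/observations.csv \
                   --adjacency data/adjacency.gal --spec sel/chosen_spec.json --out fit
copulageo predict  --observations data/observations.csv --model fit/model.json --out pred
copulageo table1
```

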
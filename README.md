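# streamtn

Spatial regression and kriging prediction of stream total-nitrogen (TN)
concentration on river networks.

Water-quality monitoring networks are sparse: a basin of several thousand
km² may carry only a few dozen sampling sites, concentrated on the main
channels. `streamtn` is for watershed scientists who want to (1) quantify how
sub-watershed characteristics — land use, hydrologic soil groups, point-source
loads, rural population — drive stream TN, (2) exploit the spatial correlation
between nearby sites to sharpen those estimates, and (3) predict TN and
water-quality classes for the unmonitored stream segments in between.

## The model

TN is modelled on the natural-log scale. With `Y = ln TN` at `n` sites,

```
Y = Xβ + ε,     ε ~ N(0, σ²Ω),
Ω_ij = C(d_ij),  C(d) = 1 if d = 0,  (1 − θ₁)·exp(−d/θ₂) if d > 0
```

where `X` is the design matrix (intercept plus covariates), `θ₁ ∈ [0, 1]` is
the nugget proportion, `θ₂ > 0` the correlation range in km, and `d` is either
the straight-line distance or the *river distance* (shortest path along the
stream network). For fixed `(θ₁, θ₂)` the likelihood is maximized by the GLS
estimators

```
β̂ = (X′Ω⁻¹X)⁻¹X′Ω⁻¹Y,     σ̂² = (Y − Xβ̂)′Ω⁻¹(Y − Xβ̂)/n
```

and substituting them back gives the profile log-likelihood

```
ℓ_p(θ₁, θ₂) = −(n/2)·ln 2π − (n/2)·ln σ̂² − ½·ln|Ω| − n/2,
```

which `SpatialGLS` maximizes by a coarse grid plus local refinement. At an
unmonitored site `Ŷ₀ = X₀β̂ + ε̂₀`, where `ε̂₀ = Σ λᵢ ε̂ᵢ` is the ordinary-kriging
estimate of the residual from the `m = 8` nearest monitoring sites (weights
constrained to sum to one). A fitted TN prediction is classified against the
GB3838-2002 class bounds (worse than Class V above 2 mg/L, strict).

One covariate is itself spatial: the distance-weighted TN load from point
sources, `Σᵢ TNᵢ/Dᵢ` over the upstream composite sources, with `Dᵢ` the river
distance from source to site.

Because monitoring campaigns of this kind rarely publish their raw site data,
the package ships a first-class synthetic watershed generator
(`streamtn.synthetic`) producing dendritic networks, sites, covariates and TN
fields with exactly the statistical structure the model assumes.

## Worked example

```python
import numpy as np
from streamtn import (SimulationConfig, simulate_watershed, SpatialGLS,
                      river_distance_matrix, cross_validate)
from streamtn.covariates import assemble_design_matrix

cfg = SimulationConfig(seed=1)              # 41 sites, θ₁=0.08, θ₂=250 km
network, sites, sources = simulate_watershed(cfg)
D = river_distance_matrix(sites, network)

X, names = assemble_design_matrix(sites)    # intercept + 4 covariates
fit = SpatialGLS(n_neighbors=8).fit(X, np.log(sites.tn), D=D.values,
                                    feature_names=names)
print(f"theta1={fit.theta1_:.3f} theta2={fit.theta2_:.0f} km")

_, ols = cross_validate(sites, D, "ols", m=8)
_, sp  = cross_validate(sites, D, "spatial", m=8)
print(f"CV R2: ols={ols['r2']:.3f} spatial={sp['r2']:.3f}")
```

prints

```
theta1=0.054 theta2=54 km
CV R2: ols=0.896 spatial=0.938
```

`theta1` is the fitted nugget proportion (small: TN varies little over short
stream distances), `theta2` the fitted range; the cross-validated R² shows the
spatial model predicting held-out sites better than ordinary regression
because it borrows the residuals of the 8 nearest monitoring sites.

The same pipeline is scriptable from a shell:

```
streamtn simulate --seed 1 --out-dir work/
streamtn distances --metric river --network work/network.csv --sites work/sites.csv --out work/D.csv
streamtn fit --model spatial --metric river --sites work/sites.csv --network work/network.csv --out work/fit.json
streamtn run --out-dir work/bundle       # full pipeline with manifest
```

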
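# Methods

## Model and estimation

`streamtn` fits a Gaussian spatial regression for log total-nitrogen
concentration, `Y = ln TN`:

* mean: `Xβ`, with an intercept plus explanatory variables (by default the
  percentage of cropland, the percentage of hydrologic soil group C, the
  natural log of the distance-weighted point-source TN load, and the natural
  log of rural population density);
* residual: multivariate normal with covariance `σ²Ω`, where
  `Ω_ij = (1 − θ₁)·exp(−d_ij/θ₂)` off the diagonal and 1 on it. `θ₁` is the
  nugget proportion (micro-scale plus measurement variance as a fraction of
  the sill), `θ₂` the exponential range in km. `d` is either straight-line or
  river distance; river distance is the *symmetric* shortest path along the
  network (no flow-connected/unconnected weighting — the tail-up/tail-down
  refinements of the stream-network kriging literature are out of scope).

Estimation is profile maximum likelihood. For fixed `(θ₁, θ₂)`, `β̂` and `σ̂²`
have the closed GLS/ML forms (`σ̂²` uses divisor `n`, not `n − p`; REML is
deliberately not offered). The profile log-likelihood is maximized over a
25×25 grid — `θ₁` linear on [0, 1], `θ₂` log-spaced on
[1 km, 4·max pairwise distance] — followed by L-BFGS-B refinement from the
grid best, with the result never allowed below the grid best. The grid is
cheap at n ≈ 41–150 and guards against the multi-modality the profile
surface can exhibit; `profile_surface` exposes the full grid for contour
inspection. `θ₁ = 0` and boundary estimates are allowed.

All applications of `Ω⁻¹` are Cholesky solves and `ln|Ω|` comes from the
triangular factor; no explicit inverse is formed. If `Ω` fails the Cholesky
(exponential correlation on network distance is not guaranteed positive
definite in general), 1e-8 jitter is added to the diagonal, the matrix
renormalized to unit diagonal, and a warning emitted; an irreparable matrix
raises with its minimum eigenvalue.

Variable selection uses ordinary stepwise regression (forward entry and
backward elimination, both at α = 0.05 on the t-test p-value), with VIF and
Breusch–Pagan heteroscedasticity diagnostics reported as advisory flags
(VIF < 10, p > 0.05). The spatial models re-use the selected variables; no
spatial p-values are reported.

## Prediction and cross-validation

At a target site, `Ŷ₀ = X₀β̂ + ε̂₀` with `ε̂₀` the ordinary-kriging combination
of the regression residuals at the `m = 8` nearest monitoring sites (same
distance metric as the fitted correlation — a package decision surfaced as an
option, since neighbor choice is otherwise underdetermined). The bordered
kriging system is solved in correlation form; because ordinary-kriging
weights are invariant to a common scale on the covariance, correlations and
covariances give identical weights (asserted in a test). Back-transformation
is a plain `exp(Ŷ₀)` — a median-type predictor; a lognormal half-variance
correction is available but off by default.

Leave-one-out cross-validation offers two variants: per-fold re-estimation of
`(β, σ², θ)` on the retained sites (the package default — conservative, no
information leakage) and a fixed full-data fit with per-site kriging only
(`fixed_fit=True`), which matches the classical one-fit-then-sequential-
prediction protocol of snapshot monitoring studies. Reported metrics are the
squared Pearson correlation of observed vs predicted LnTN and the RMSE on
the LnTN scale (the natural scale for a log-linear model), plus the binary
classification tally at the 2 mg/L bound.

Water-quality classes use TN upper bounds (0.2, 0.5, 1.0, 1.5, 2.0) mg/L for
classes I–V per the GB3838-2002 surface-water standard, overridable in the
pipeline config; a value exactly at a bound takes the better class
("exceeds" is strict), so anything above 2.0 mg/L is worse than Class V.

## Covariate construction

* Distance-weighted point-source load: `Σ TNᵢ/Dᵢ` over sources strictly
  upstream of the site (a source is upstream iff its path to the outlet
  passes through the site; non-upstream sources are excluded with a logged
  warning). `Dᵢ` below 0.1 km is clamped to 0.1 km because the expression is
  singular at zero distance.
* The load covariate enters the design matrix as `ln(1 + x)`, not `ln x`:
  sites without upstream point sources have load 0, where the plain log is
  undefined. `ln(1+x)` is monotone, zero at zero and asymptotically equal to
  `ln x`; the transform registry records this per-variable choice.
  Density covariates enter as plain `ln`.
* County-level rural population and manure densities are area-weighted over
  the county fractions intersecting each sub-watershed; compositional
  covariates (10 LULC classes, 4 soil groups) are percentages closed to 100.
* Units are declared, never inferred: loads kg/yr, distances km, densities
  persons/km² and kg/(km²·yr).

## Synthetic watershed generator

No public dataset carries this study design (site table plus stream network
plus sub-watershed covariates), so the generator is a first-class module and
defines the conditions under which the pipeline is tested:

* **Network**: recursive bifurcation from the outlet. A mildly sinuous main
  stem runs along the long axis of an elongated 146 × 50.2 km region
  (≈7,330 km²; basins of this size are stem-elongated rather than square);
  each of 60 branch events attaches a tributary chain at a random interior
  node, adding exactly one headwater leaf, with segment lengths attenuating
  by level. Edge channel lengths are the planar chord times a per-edge
  sinuosity factor ≥ 1, as in a digitized network, so river distance always
  dominates straight-line distance. Typical realizations carry ~1,500 km of
  channel (drainage density ≈ 0.2 km/km²) and maximum between-site river
  distances of ~250 km, and support ~150 prediction sites at 10-km spacing.
* **Sites**: 41 by default, uniform along total channel length, with network
  position (edge, offset) and interpolated planar coordinates.
* **Covariates**: LULC and soil compositions are Dirichlet draws scaled
  to 100 — closure is exact by construction — with means/concentrations set
  to a cropland-dominated agricultural basin (cropland mean 63.1%, SD ≈ 22%;
  soil-C SD ≈ 28%). Rural population density is area-weighted over a
  10-county overlay with log-normal county densities (median ≈ 150
  persons/km²); manure density and topography are log-normal. 80 composite
  point sources with log-normal loads (median ≈ 245 kg/yr) are placed with
  upstream-weighted probability so that roughly half the sites have at least
  one upstream source — sites with zero upstream load are a deliberate
  feature (they exercise the `ln(1+x)` transform).
* **Response**: `LnTN = Xβ + ε` with `ε` drawn from `N(0, σ²Ω)` under the
  configured metric; `TN = exp(LnTN)`. Defaults: the river-distance
  coefficient set (intercept −3.118, cropland +0.019, soil-C −0.023, ln load
  +0.262, ln rural density +0.454), `σ² = 0.35`, `θ₁ = 0.08`, `θ₂ = 250` km,
  river metric. Under these defaults TN is right-skewed and positive with
  mean ≈ 3–4 mg/L and typical per-realization ranges ≈ 0.1–30 mg/L, and
  roughly half the sites exceed the 2 mg/L Class-V bound — a heavily
  polluted agricultural basin.
* **Reproducibility**: one integer seed fans out to fixed per-stage
  sub-seeds (network, sites, covariates, sources, TN) via
  `numpy.random.SeedSequence` spawn keys; every stage is bit-reproducible.

What the generator does **not** emulate: real site placement is purposive
(bridges, confluences), not uniform; covariates derive from shared geography
and are spatially autocorrelated with each other, while the generator draws
them independently per site; point-source loads in reality correlate with
population and land use. Passing tests therefore demonstrate correctness of
the estimators under the model's own assumptions, not robustness to the
violations real data bring.

## Numerical and design notes

* Profile-likelihood evaluations share the `exp(−D/θ₂)` kernel across all
  `θ₁` values of a grid column.
* `σ̂² = 0` (noiseless data) would make the profile log-likelihood diverge;
  the log is floored so the fit still returns the exact `β̂`.
* Nearest-neighbor ties break by ascending site id (site-level API) or array
  index (matrix-level API) for cross-platform determinism.
* Kriging at a monitoring site with `θ₁ = 0` reproduces the observation
  exactly; with `θ₁ > 0` it does not (the nugget is not interpolated).
* CSVs are written with `%.17g` and read with round-trip float parsing, so
  write-then-read reproduces every value bit-exactly.
* Cross-validation R² is the squared Pearson correlation; with ranges much
  longer than the basin the residual field behaves like a regional offset
  that correlation does not penalize, so absolute R² values run higher than
  mean-square-based definitions would suggest.

## Known limitations

* Maximum-likelihood range estimation is weakly identified when `θ₂` is
  comparable to or larger than the basin diameter: the fixed effects absorb
  the large-scale field and essentially only `σ²/θ₂` is well determined, so
  `θ̂₂` scatters widely and is biased low in that regime even though `β̂`
  remains accurate. Parameter-recovery simulations in the test suite
  document this behavior.
* No REML, no Matérn or anisotropic correlation families, no
  flow-direction-aware stream-network covariances, no prediction variances,
  no spatio-temporal extension.
* Inputs must be projected planar coordinates in km; no geodesic support.
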
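# Methods

This note records the model conventions, default parameters, numerical
choices and known limitations of `ballastgwr`.

## Flux derivation from ²³⁴Th disequilibria

²³⁴Th (half-life 24.1 d) is produced from dissolved ²³⁸U and removed on
sinking particles, so the near-surface deficit of total ²³⁴Th relative to
²³⁸U integrates export over the preceding weeks.  `th_flux_steady_state`
implements the one-dimensional steady-state balance

F_Th = λ ∫₀^z (A_U − A_Th) dz,

with trapezoidal integration on the union of the tabulated depths, the
surface (constant extension of the shallowest sample) and the integration
depth z (linear interpolation).  Defaults and conventions:

- λ = ln 2 / 24.1 d⁻¹ (the standard half-life; code constant, overridable
  through `DecayConstants`).
- z = 100 m by default, exposed as `z_int`.
- ²³⁸U, where not measured, follows a linear salinity law
  A_U = 0.0786·S − 0.315 dpm L⁻¹ with configurable slope/offset, covering
  the common literature calibrations; direct measurements take precedence.
- Element fluxes are F_Th × (element:Th ratio of >53 µm particles) ×
  molar mass.  PIC is reported as mg C (12.011 g mol⁻¹); BSi as mg Si
  (28.086 g mol⁻¹ — no opal-hydration mass is applied, a deliberate,
  conservative convention since reporting practice varies).
- Lithogenic flux = 100/8 × Al flux (Al assumed 8 % of crustal material);
  the Al flux comes from the integrated Th flux times a particulate-Al:Th
  ratio (the "ratio route").  Where particulate Al was not measured,
  literature concentrations ship as constants: 1.27 nmol L⁻¹ for
  island-plume stations, 0.23 nmol L⁻¹ for non-plume Southern Ocean
  stations.
- Non-steady-state terms, upwelling corrections and uncertainty
  propagation are out of scope.

## Global regression (MLRA)

Ordinary least squares of F_POC on [F_PIC, F_BSi, F_lith, 1]
(statsmodels under the hood).  Coefficients are unconstrained — negative
carrying coefficients are information, not errors, and local estimates
plainly go negative — so no non-negativity constraint is imposed anywhere.
At least 5 complete stations and a full-rank design are required;
collinear columns are named in the error.

## Corrected AIC

One criterion scores both estimators:

AICc = 2n ln σ̂ + n ln 2π + n (n + k) / (n − 2 − k),  σ̂² = RSS/n,

the Gaussian small-sample form standard in the local-regression
literature, where k is the effective number of parameters.  For the global
fit k = p + 1 = 5 (four regression parameters plus the error variance);
for the GWR fit k = tr(S), the hat-matrix trace.  The criterion is
undefined for n ≤ k + 2 (reported as NaN with a warning for very small
tables).

## Geographically weighted regression

- **Distances** are great-circle (haversine, sphere radius 6371 km), not
  degree-space Euclidean: the stations span hemispheres and degree metrics
  distort high-latitude neighbourhoods.
- **Kernel**: adaptive Gaussian, w_ij = exp(−½ (d_ij/h_i)²) with h_i the
  distance from station i to its N-th nearest neighbour, the station
  itself counted as neighbour 1.  The Gaussian constant only rescales the
  bandwidth search, so the standard form is used.  Distance ties at the
  N-th neighbour simply enlarge the effective neighbour set.  Co-located
  stations that fill the whole neighbour set (h_i = 0) raise an error with
  a remediation hint (jitter or raise N).
- The target station participates in its own local fit with weight 1;
  overfit is penalised through tr(S) in the AICc rather than by
  leave-one-out.
- **Local fits** solve (XᵀWX)β = XᵀWy per station; the hat-matrix row
  xᵢᵀ(XᵀWX)⁻¹XᵀW gives fitted values and tr(S).  Local designs with
  condition number above 10¹² are treated as singular and named.
- **Local R²** is the weighted 1 − RSS_w/TSS_w within each station's
  kernel window (weighted mean of y in TSS_w).
- **Bandwidth selection** minimises AICc over integer neighbour counts in
  [p + 2, n] by golden-section search with a final exhaustive sweep of the
  bracketing interval; AICc ties (within 10⁻⁹) break toward the larger,
  smoother bandwidth.  The AICc profile can be locally flat near its
  minimum; the golden/exhaustive combination finds the global minimiser on
  unimodal profiles and a near-optimal bandwidth otherwise.

## Test of geographical variability (TGV)

For each term k, a semiparametric model holds coefficient k global while
the others stay local.  The global coefficient is estimated by two-stage
back-fitting: the local-part hat matrix S_l (which does not depend on y)
is assembled once from the reduced design; then γ ← OLS of (y − S_l(y −
x_k γ)) on x_k, iterated to relative tolerance 10⁻⁶ (max 100 iterations,
non-convergence flagged per term).  The converged estimator is linear in
y, so the mixed model's hat matrix — and hence its tr(S) and AICc — is
explicit.  The reported *diff of criterion* is AICc(fully local) −
AICc(term-k-global): below −2 supports spatial variability of that term,
above +2 a constant term, in between the comparison is inconclusive.

Calibration under the generator's conditions (n = 100, noise 10 mg m⁻²
d⁻¹, AICc-selected bandwidth): classifying each term by "diff < −2 ⇔
varying" is correct in ≥ 92 % of 50 seeded replicates per term, for both a
config with a strong logistic front in the PIC coefficient and an
all-constant config.  The classification is evaluated per coefficient;
requiring all four terms of a table to classify correctly simultaneously
compounds the per-term error rates and is not the calibrated guarantee.

## ANOVA against the global fit

F = [(RSS_global − RSS_gwr)/ν₁] / [RSS_gwr/ν₂], ν₁ = tr(S) − p,
ν₂ = n − tr(S); the p-value uses the real-valued (ν₁, ν₂) and the reported
degrees of freedom are the conventional integers (n − p, round(n − tr S)).
If the GWR does not genuinely improve on the global fit (uniform-weight
degeneracy), F is reported as 0 and flagged.

## Residual correlograms

Moran's I with binary weights per great-circle distance bin
(w_ij = 1 ⇔ d_ij in the bin), I = (n/W) Σ w_ij z_i z_j / Σ z_i².  Default
bins are 10 equal-pair-count quantile bins, since station density is very
uneven across basins.  Significance is two-sided permutation (default 999
seeded relabelings, +1-corrected) rather than the analytic normal
approximation: per-bin pair counts are small and the weights binary.  The
seed is recorded in the output.

## POC partitioning

Per station: poc_X = coefficient × mineral flux, the unassociated portion
is the intercept, and the residual closes the identity poc_PIC + poc_BSi +
poc_lith + poc_nonassoc + residual = observed F_POC to machine precision.
Percentages are taken against the *observed* POC flux (a map of "percent
of export ballasted" reads most naturally against measured export), which
is why the residual is carried explicitly.  Negative components are
reported as-is and flagged; a clipped variant (percentages floored at 0)
is available behind a flag.  Regional aggregates are unweighted station
means by default, with a flux-weighted option; default provinces are the
Arctic (≥ 66.5°N), the high-latitude North Atlantic (45–66.5°N, 80°W–30°E),
the subtropical gyres (|lat| < 25°) and the Southern Ocean (≤ 45°S), with
first-match priority and an "other" pool.

## Synthetic generator

`generate_table` scatters stations uniformly within basin boxes
(largest-remainder apportionment of the box weights), draws mineral fluxes
lognormal — export fluxes are positive and right-skewed — and assembles
POC flux from smooth coefficient fields plus Gaussian noise.  Negative POC
draws are rejection-sampled (noise redrawn, up to 1000 attempts, count
logged) rather than truncated, so the linear model holds exactly for every
retained station.  One seed drives everything; identical seeds give
byte-identical CSVs.

`default_study_config` encodes the study-like conditions used
throughout the tests and the acceptance script: 95 stations over Arctic
(13), high-latitude North Atlantic (36), low-latitude Atlantic (22) and
Southern Ocean (24) boxes — 49 stations north of 45°N, 24 south of 45°S.
Coefficient fields are logistic fronts at 45°N: PIC 0.05 → 1.15, BSi 0.13
→ 0.40, lithogenic 0.06 → 0.14; the intercept is constant at 89 mg m⁻²
d⁻¹, consistent with a variability test that supports no spatial structure
in it.  The levels bracket the reported mean local coefficients (≈ 0.57,
0.26, 0.10, 89) and stay within the reported local spreads.  Mineral
fluxes use log-means ln 15 (PIC), ln 25 (BSi), ln 2 (lithogenic) mg m⁻²
d⁻¹ with log-sds 1.0/1.1/1.2; POC noise is 35 mg m⁻² d⁻¹, a realistic
scatter for Th-derived export estimates.  These values were fixed once as
the generator's study conditions.

What the generator does *not* emulate: ²³⁴Th measurement error structure,
seasonal aliasing of the Th method, longitude structure in the coefficient
fields, correlated mineral fluxes, or region-dependent flux magnitudes.
Passing tests therefore demonstrate that the estimators recover known
spatial coefficient structure under realistic noise and clustered
sampling — not that any particular ocean value is correct.

## Test-design choices

- Coefficient-recovery error is measured scale-aware: absolute error for
  the dimensionless carrying coefficients, relative error for the
  intercept (which is two orders of magnitude larger in its own units).
  At zero noise the pooled median error is ~0.01–0.03 per seed (median
  0.014 over ten seeds); the residual error is smoothing bias of the
  kernel against the coefficient fronts, concentrated in the weakly
  identified lithogenic coefficient (lithogenic fluxes are a minor flux
  component, so c is estimated from little leverage).
- Sign/ordering claims (GWR beats the global fit on R² and AICc; the
  ANOVA rejects; the PIC coefficient is the most spatially variable term;
  GWR residuals lose their spatial autocorrelation) are asserted over
  seeded replicates of the default conditions rather than a single draw.
  Under these conditions the BSi front (amplitude 0.27 against noise 35)
  is only marginally detectable — single replicates often return an
  inconclusive diff of criterion — so the BSi claim is asserted as an
  aggregate (mean diff over replicates negative), mirroring how marginal
  the evidence is.
- Problem sizes in the test suite (95–200 stations, 99–999 permutations,
  10–50 replicates) are the package's chosen study scales; the full suite
  runs in well under a minute.

## Known limitations

- The steady-state Th model omits upwelling and non-steady-state terms;
  in strongly advective regimes the derived fluxes are biased.
- The semiparametric TGV estimator is the simplest back-fitting form;
  commercial GWR software may use different mixed-model estimators, so
  criterion differences can disagree in the decimals (signs and the ±2
  evidence bands are the robust content).
- The AICc bandwidth search assumes a near-unimodal criterion profile.
- Regional summaries depend on box definitions; province polygons are
  rectangles, not water-mass boundaries.
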
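# ballastgwr

Where does mineral ballast matter for the export of particulate organic
carbon (POC) from the surface ocean?  `ballastgwr` answers that question the
way biogeochemists pose it: take station-level export fluxes of POC and the
three candidate ballast minerals — calcium carbonate (PIC), biogenic silica
(BSi) and lithogenic material — derived from ²³⁴Th disequilibria, regress
POC flux on the mineral fluxes, let the regression coefficients vary in
space, and map the fraction of export that is mineral-associated.

It is written for sea-going biogeochemists and carbon-cycle modellers who
have a table of ²³⁴Th-derived export fluxes (or raw activity profiles plus
large-particle element:Th ratios) and want a reproducible, tested version of
the ballast-partitioning analysis.

## The model

Each station's POC export flux (mg C m⁻² d⁻¹) is decomposed as

```
F_POC = a·F_PIC + b·F_BSi + c·F_lith + d + ε
```

where *a*, *b*, *c* are **carrying coefficients** (mg POC carried per mg of
mineral exported) and the intercept *d* is the flux not statistically
associated with any mineral.  Two estimators are provided:

- **MLRA** — one global ordinary-least-squares fit (`fit_mlra`);
- **GWR** — geographically weighted regression (`fit_gwr`): a weighted fit
  at every station, with weights `w_ij = exp(−½ (d_ij/h_i)²)` from an
  adaptive Gaussian kernel whose local scale `h_i` is the great-circle
  distance to the *N*-th nearest neighbour.  The neighbour count *N* (the
  bandwidth) is chosen by minimising the small-sample corrected AIC
  (`select_bandwidth`), with the hat-matrix trace tr(S) as the effective
  number of parameters.

Model comparison and diagnostics: a per-term **test of geographical
variability** (hold one coefficient global, keep the rest local; negative
AICc difference supports spatial variability), an **ANOVA** of GWR against
the global fit, and **Moran's I residual correlograms** with permutation
significance.  `partition_poc` converts coefficients into per-station
mineral-associated fluxes and percent-ballasted shares; `regional_summary`
aggregates them over ocean provinces (high-latitude North Atlantic, Arctic,
subtropical gyres, Southern Ocean by default).

Upstream of the regression, the `thflux` module turns ²³⁴Th activity
profiles into export fluxes with the one-dimensional steady-state model
(`F_Th = λ ∫ (A_U − A_Th) dz`, integrated to 100 m) and the element:Th
ratios of large (>53 µm) particles; lithogenic flux is estimated from
particulate aluminium as 100/8 × the Al flux.

## Worked example

A synthetic study-like table (95 stations over Atlantic, Arctic and
Southern Ocean boxes, with known spatially varying carrying-coefficient
fields) ships as a generator, so the whole pipeline can be exercised
without any external data:

```
$ ballastgwr simulate --seed 42 --out stations.csv --truth truth.csv
wrote 95 stations to stations.csv
$ ballastgwr report stations.csv --seed 7 --n-perm 999 --out-dir report
ballastgwr 0.1.0 summary for stations.csv (n=95)

          a(PIC)  b(BSi)  c(lith)  d(intercept)    AICc      R2
MLRA       0.405   0.145    0.762         93.22   997.3   0.147
GWR mean   0.600   0.169    1.380         89.46   972.7   0.414

bandwidth (neighbours): 32   trace(S): 9.55
TGV diff of criterion: pic=-12.3  bsi=+1.9  lith=+3.1  intercept=-0.0
ANOVA GWR vs MLRA: F(91,85) = 7.03, p = 7.42e-06
significant correlogram bins (p<0.05): MLRA 7, GWR 0
```

Reading the numbers: the global fit explains 15 % of the variance in POC
export; letting the coefficients vary spatially almost triples that (R²
0.41) at a lower AICc, and the ANOVA confirms the improvement is not just
extra flexibility.  The variability test flags the PIC coefficient as
strongly spatially variable (diff −12.3, well below the −2 evidence
threshold) while the other terms show no strong spatial structure — which
is exactly how the table was generated (a logistic front in the PIC
coefficient at 45°N).  The global model's residuals are spatially
autocorrelated in 7 of 10 distance bins; the GWR residuals in none.
Per-station outputs (local coefficients, local R², partitioned fluxes,
regional means, correlograms, the AICc bandwidth profile) land in
`report/`.

The same stages are available as library functions (`fit_mlra`, `fit_gwr`,
`select_bandwidth`, `test_geographical_variability`, `anova_gwr_vs_mlra`,
`residual_correlogram`, `partition_poc`) and as individual subcommands
(`thflux`, `fit-mlra`, `fit-gwr`, `tgv`, `diagnose`, `partition`).

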
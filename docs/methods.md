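# Methods

This note documents the statistical model, the covariate definitions, the
marginal-inference machinery, the synthetic study conditions and the
numerical choices behind `phenosense`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The model and its estimand

Phenological temperature sensitivity is defined as the marginal effect of
standardized seasonal temperature `t_std` on the day of year (DOY) of a
reproductive phenophase, in days/°C; negative values mean earlier phenology
in warmer years. The working hypothesis is that this sensitivity is not a
species constant but varies geographically with two long-term climate
normals: mean annual temperature (MAT) and interannual temperature
variability (IVT).

The global model is a Gaussian OLS regression:

```
DOY ~ (t_std × MAT × IVT × species)
    + (p_std × MAT × IVT × species)
    + (phenophase × MAT × IVT × species)
```

where `×` denotes a full factorial product expanded hierarchically (every
interaction implies its marginal terms). With six species and three
reproductive phenophases, treatment coding yields 120 coefficients; the
package verifies that count against an independent symbolic expansion. The
three-way `t_std:MAT:IVT` block is the scientific core: it lets the
temperature slope be an (approximately bilinear) function of the local
climate normals. Precipitation (`p_std`) and phenophase enter with the same
moderators so that their effects are statistically controlled, and species
interacts with everything so that intraspecific structure is not forced to
be shared.

Assumptions: independent homoskedastic Gaussian errors and a response
linear in the included products. Residuals of real phenology data are
typically leptokurtic; the package reports excess residual kurtosis with
every fit rather than transforming the response, on the usual grounds that
large-n Gaussian OLS is robust for point estimates and conservative for
type-I error, and that non-Gaussian alternatives handicap multi-way
interaction inference. Mixed-effects, robust and GLM variants are out of
scope by design.

## Covariates

* **Seasonal climate** (`t_seasonal`, `p_seasonal`): the mean of monthly
  mean temperature / precipitation over the three-month window immediately
  preceding the species' reproductive season — January–March for the
  spring-blooming species (*Tussilago farfara*, *Ficaria verna*, *Alliaria
  petiolata*), March–May for the summer-blooming species (*Cirsium
  arvense*, *Daucus carota*, *Lythrum salicaria*) — in the observation year.
* **Standardization** (`t_std`, `p_std`): the seasonal values mean-centred
  within a grouping. The default grouping is *species* (one cohort per
  species across both continents), which matches the per-species seasonal
  windows; `species_continent` and `global` groupings are config options and
  the chosen grouping is logged with every run. Centering is exact, so
  "precipitation controlled at its mean" and "controlled at zero" coincide;
  a test asserts group means are 0 to 1e−9. Note that centering within
  species does **not** remove spatial structure: `t_std` retains a
  geographic component (winter/spring climate declines with latitude), as is
  inherent to this standardization.
* **MAT**: per 0.5° cell, the mean over 1901–2021 of the annual mean of the
  12 monthly minimum temperatures. The stated record bounds (121 years
  inclusive) are used rather than a nominal "120-year" count.
* **IVT**: the sample standard deviation (denominator n−1) of those annual
  means. Minimum temperature is used for the normals and mean temperature
  for the seasonal values; at 0.5° resolution the two are nearly collinear
  and the choice is conventional.
* **Cell lookup**: cells cover half-open intervals `[c−0.25°, c+0.25°)`;
  points on a shared edge belong to the higher cell. Out-of-grid points and
  all-missing (e.g. ocean) cells raise errors naming the offending record.

## Curation

Records are excluded sequentially, each counted once under the first rule it
violates: (1) missing coordinates or date; (2) unannotatable phenophase;
(3) vegetative phenophase (an unconstrained stage unsuitable for timing
analysis); (4) location inside an excluded region. Excluded regions are
configurable bounding boxes (defaults: Iceland, the Azores, eastern Asia,
Australia — areas outside the species' primary ranges). The report satisfies
`retained + Σ excluded = input` and filtering is idempotent. DOY uses a
fixed 1–365 scale; day 366 of leap years clamps to 365. Phenophase
classification from organ flags follows "latest stage wins":
fruit → fruiting, else flower → flowering, else bud → budding, else
vegetative.

## Marginal inference

The package builds design matrices from an explicit term structure (each
column = product of factor-level indicators and covariates). This makes two
things exact rather than numeric:

* a **reference grid** fixes moderators ("at"), averages factors with equal
  weights per level ("over"; proportional weighting is deliberately not the
  default, matching the estimated-marginal-means convention), and holds all
  other covariates at their sample means;
* the **simple slope** for a focal covariate is the linear functional
  `c'β` whose contrast `c` is the grid-weighted average of column
  *derivatives*: a column's derivative w.r.t. the focal covariate is the
  same indicator/covariate product with the focal factor replaced by 1 (zero
  if the column does not contain it). Second cross-derivatives give slope
  *trends*, e.g. Δ(temperature sensitivity)/°MAT.

Standard errors are delta-method, `se = sqrt(c'Σc)` with `Σ = s²(X'X)⁻¹`;
tests are two-sided t at the residual degrees of freedom (single-stratum
OLS; no Satterthwaite machinery). All marginal quantities are invariant to
the factor reference-level choice, which is asserted by a test rather than
assumed. Pairwise contrasts support Tukey HSD adjustment through the
studentized range distribution (`q = |t|·√2` with k groups at the model
df); for k = 2 this reduces exactly to the unadjusted t-test. The engine is
cross-validated against R's `emmeans` (estimates, standard errors and
Tukey-adjusted p-values) on a shared dataset, and against brute-force
predictions/finite differences on randomized models.

OLS fitting itself, and its AIC/adjusted-R² bookkeeping, are delegated to
statsmodels on the explicitly built matrix; AIC uses the full Gaussian
log-likelihood convention `n·ln(RSS/n) + n·ln(2π) + n + 2k` with k the
number of coefficients, so ΔAIC matches common statistical packages. Rank
deficiency is a hard error that names the suspect columns — the global model
is full-rank on valid data, and silent column dropping would mask design
bugs. The AIC-selection routine requires all candidates to be fit on
identical rows; the shipped candidate list contains the global model
(default) plus simpler baselines, since the exact historical candidate set
is not reproducible from public sources.

## Sensitivity outputs

* **Surface**: marginal `t_std` slope at every node of a MAT × IVT grid —
  fine grid 0.2 °C × 0.05 s.d. over −5…15 °C × 0.4…1.2 s.d. (1717 nodes) for
  mapping, coarse 1 °C × 0.1 s.d. (189 nodes) for summaries — averaged
  equally over species and phenophase with `p_std` at its mean, or per
  species. Because the pooled surface is an exact bilinear function of
  (MAT, IVT), its extrema lie at grid corners; a test checks the coarse-grid
  range against corner evaluation. The grid may extend beyond the observed
  covariate range; this is allowed with a warning, and standard errors
  widen accordingly.
* **Geographic projection**: the slope is evaluated at each record's exact
  MAT/IVT (not a nearest node), so discretization cannot leak into maps and
  records sharing a climate cell share a sensitivity value exactly.
* **Intraspecific range**: max − min of the pooled slope over the coarse
  grid, with the extreme locations reported at full precision (printed
  summaries of such extremes can differ in the last digit depending on
  rounding conventions).
* **Interspecific range**: max − min of per-species mean slopes (averaged
  over phenophase, MAT/IVT/`p_std` at sample means), with Tukey-adjusted
  pairwise species contrasts.
* **MAT-trend profile**: ∂²E[DOY]/∂t_std∂MAT at chosen IVT levels
  (default 0.4, 0.8, 1.2 s.d.) plus an "overall" row at the sample-mean IVT.
* **Precipitation sensitivity**: the same machinery with `p_std` focal
  (days/mm), optionally as a full surface.

## Synthetic study conditions

The generator is first-class, tested code; its defaults *are* the study
conditions and every parameter is inspectable in
`phenosense.synthetic.SensitivityTruth` / `ClimateGradientParams` and
serialized with each run.

**Climate.** Monthly minimum temperature is a sinusoidal seasonal cycle
(amplitude 10 °C, warmest in July) around a per-cell MAT target, plus an
annual anomaly shared by all months of a year within a cell, plus
independent monthly noise (σ = 0.8 °C). The anomaly s.d. is set per cell to
`sqrt(IVT_target² − σ_monthly²/12)`, so the realized IVT matches its target
up to the sampling error of a 121-year series; targets at or below the
monthly-noise floor are rejected (IVT is undefined without interannual
variance). MAT targets follow a lapse of −0.45 °C per °latitude with a
+4.91 °C Eurasian offset (North America: 2.5 °C at 50° N); IVT targets gain
+0.02 s.d. per °latitude with a −0.22 s.d. Eurasian offset (North America:
0.92 s.d. at 50° N). Over the default domain (35–65° N, one 15°-wide
longitude band per continent) MAT spans about −4…16 °C and IVT about
0.4…1.2 s.d., matching the analysis grids. Mean temperature is minimum
temperature plus a constant 4.5 °C offset (the two are near-collinear in
real 0.5° data, and the constant guarantees `tmn ≤ tmp`); precipitation is
an independent seasonal cycle with annual and monthly noise, clipped at
zero.

**Observations.** Each record draws a uniform cell on its continent (a
sampling-bias weight per continent exists but defaults to balanced,
matching the balanced study design), uniform coordinates within the cell, a
uniform year 2017–2019 and phenophase, and

```
DOY = baseline(species) + offset(phenophase) + κ·(MAT − 5)
      + [b(MAT,IVT) + δ_species]·t_std + β_P·p_std + N(0, σ)
```

rounded and clamped to [1, 365] (clamping, not wrapping, because DOY is
defined on a 1–365 scale; with the default baselines it never binds).
`t_std`/`p_std` are computed from the same grid through the same seasonal
windows and species-level centering the analysis uses.

Default truth: γ₀ = −1.59, γM = +0.012, γV = −0.275, γMV = −0.14 — the
bilinear surface through corner slopes (−1.48, −1.14, −2.36, −4.26) days/°C
at (MAT, IVT) ∈ {−5, 15} × {0.4, 1.2}, which evaluates to ≈ −2.3 days/°C at
the sample-mean climate with an average MAT trend of ≈ −0.10 days/°C per °C.
Species slope offsets δ (zero-sum, spanning 2.30 days/°C from *A. petiolata*
+1.21 to *T. farfara* −1.09) set the interspecific spread without moving the
pooled surface. β_P = 0.03 days/mm. Baseline DOYs are 80/95/115 (spring
species) and 175/185/195 (summer species) with phenophase offsets 0/10/25
days. The climatology term κ = −1.09 days/°C advances baseline phenology in
warmer climates and, through the MAT lapse, produces a poleward delay; it is
routed through MAT (not raw latitude/continent dummies) so the generating
process stays inside the fitted model's span — the property that makes
confidence intervals from the fit nominally valid against the truth surface
and parameter-recovery tests meaningful. A consequence worth knowing: the
synthetic latitudinal DOY trend combines this channel with the geographic
component of `t_std` (≈ +1.5 days/°lat in total), so descriptive spatial phenology
regressions are checked qualitatively (poleward delay), not against a fixed
number.

**Residual noise** σ = 22 days is a package choice (opportunistic records
are noisy at roughly this scale); with the configured baseline spread it
puts the global model's adjusted R² near 0.82 on default-sized datasets.

**What the generator does not emulate:** observer effort and spatial
sampling bias (beyond the continent weight), spatial autocorrelation in
residuals, photoperiod or chilling cues, species range limits within the
domain, and image-level annotation error. Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the stated
model, not robustness of the scientific conclusions to these real-data
complications.

## Verification strategy and problem sizes

The suite checks every layer against an independent oracle: OLS against
normal equations; marginal means against averaged predictions; slopes and
trends against centered finite differences (exact for linear models, tested
to 1e−8); Tukey p-values against a 10⁶-draw studentized-range simulation
and, together with estimates and standard errors, against R `emmeans`;
column counts against a sympy expansion; MAT/IVT against hand-computed
series; curation counts against toy tables. End-to-end recovery runs 20
replicate datasets of ~24,000 records (2000 per species × continent) and
requires the estimated surface to cover the truth within nominal 95% CIs at
≥ 90% of coarse-grid nodes pooled across replicates (node coverage is
strongly correlated within a replicate, so per-replicate coverage is
bimodal while the pooled rate sits near 0.95). `scripts/acceptance.py` uses
24 replicates at the same size and averages estimates across replicates
before summarizing; ranges are taken on the replicate-averaged surface and
per-species slopes, because averaging per-replicate max−min ranges would be
biased upward by estimation noise. These sizes keep the full suite and the
acceptance script each around a minute on one CPU while leaving
Monte-Carlo error well below the effects of interest.

## Known limitations

* Gaussian OLS only; no mixed effects, GLMs or robust errors.
* Equal-weight factor averaging is the only built-in EMM weighting
  (proportional weighting would change marginal estimates when designs are
  unbalanced).
* The exclusion-region boxes are coarse rectangles; real coastline-accurate
  masks would require geometry dependencies out of scope here.
* The NetCDF writer targets classic NETCDF3 (via scipy), which caps
  per-variable sizes far beyond the grids used here but is not suited to
  global-scale archives.
* `slope_trend` reports exact zeros (se = 0) when the focal×moderator
  interaction is absent from the model; this is a statement about the model
  space, not a calibrated test.
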
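# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical choices, and what the test suite does and does not
establish.

## Model and estimators

**Outcome equation.** Log BLL is linear in: log distance to the mine waste
dump (km), the unsigned direction angle to the WNW contamination axis and
its square (radians; the quadratic lets exposure peak at WNW, dip between
the lobes and rise again toward ESE), altitude (raw metres — the reference
coefficient sets are only consistent with uncentred altitude, given their
intercepts), a piecewise age response, and cohort-specific covariates.
Children (0–10 y) and adults (19+ y) get separate equations; adolescents
(11–18 y) are never offered blood sampling and are later scored with the
child equation, extrapolating its linear age decline through 18 years. The
age response is a quadratic in *months* below two years and linear in
*years* from two years on; the two blocks are not forced to join at the
boundary, because the functional form is specified that way. All logs are
natural: the linear age coefficient then converts to a percent decline per
year as 100·(1 − exp(φ3)).

**Direction geometry.** Coordinates are planar km with the dump at the
origin; at district scale (< 20 km) planar geometry is adequate and no map
projection is claimed. The WNW axis is the compass bearing 292.5°. The
direction angle is computed as atan2(|cross|, dot) of the household vector
against the WNW unit vector — exact at 0 and π, where an arccos formulation
loses half its digits. The angle is unsigned, so the model (and the
predicted surface) is symmetric across the WNW–ESE axis by construction.

**Selection.** Participation is a probit on the same regressors plus the
blood-sampling window length in days (range 3–31). The window shifts the
cost of attending a clinic but has no physiological link to BLL, making it
the exclusion restriction. The two-step correction fits the probit on all
records, evaluates the inverse Mills ratio λ(z) = ψ(z)/Ψ(z) at the fitted
index of the selected records, and adds it to the outcome regression. The
two-step (rather than full-information ML) is the estimator whose fit
report carries an explicit inverse-Mills-ratio row, which is the form in
which results are conventionally tabulated for this design. λ is computed
via the scaled complementary error function, λ(z) = √(2/π)/erfcx(−z/√2),
stable to z ≪ 0.

**Inference.** Standard errors are CR1 cluster sandwiches at the SEA level
(small-sample factor G/(G−1)·(n−1)/(n−k)); OLS P values use t(G−1), probit
P values the normal. The first-stage probit covariance is clustered too,
for symmetry with the second stage. Second-stage inference treats λ as an
ordinary regressor; this matches the reported convention for this design
and is exact under the null of no selection (the generated-regressor
correction vanishes when λ's coefficient is zero), which is also why the
selection-test calibration check is valid. Away from the null the reported
second-stage SEs understate the two-step sampling variance. Estimation is
unweighted throughout; the survey's sampling weights enter only at
aggregation. Collinear design columns are never dropped silently — fitting
raises an error naming them.

**Probit numerics.** Fisher scoring with the expected-information weight
φ²/(Φ(1−Φ)), analytic gradient, step-halving (the log-likelihood path is
non-decreasing), convergence at gradient max-norm < 1e-8, at most 100
iterations (both configurable). Perfect separation is reported as an error,
detected by diverging coefficients or a log-likelihood at numerical zero.

**Retransformation.** Predictions exponentiate the fitted log BLL. The
default is naive exp(·) with no correction — matching how a log-linear
exposure model of this kind is conventionally read back into levels — with
Duan smearing (mean of exp(residuals)) and the lognormal exp(σ̂²/2) factor
selectable. Under lognormal errors the naive mean is biased low by roughly
σ²/2 ≈ 8%; this is the likeliest source of level differences when comparing
retransformation settings.

**Aggregation.** Weighted means; weighted quantiles by linear interpolation
of the midpoint weighted empirical CDF ((cumw − w/2)/W); clinical band
shares with the middle band closed on both ends (< 5, [5, 45], > 45 µg/dL);
95% CIs by resampling SEAs (the primary sampling units) with replacement,
percentile method, 2000 replicates by default, seeded. How the original
survey computed its CIs is not stated anywhere reproducible, so the cluster
bootstrap is this package's own choice. Aggregation is invariant to
rescaling all weights. Counts of residents above the reference level are
proportion × projected population, rounded to the nearest hundred.

## Synthetic data-generating process

The field data are confidential, so the generator is the test bed. It
emulates:

* **Design:** 40 of 384 SEAs sampled, 25 households per SEA; SEA frame
  sizes ~ N(128, 40) households (truncated below at the take), giving
  weights (384/40)·(frame size/25). The frame-size distribution is a
  convention — only its mean is pinned by a realistic district of roughly
  49,000 households.
* **Geography:** SEA centroids at a uniform bearing and log-normal radial
  distance calibrated to the published distance moments (mean 6.07, SD 5.31
  km); households scatter N(0, 0.3 km) around the centroid; altitude ~
  N(1185, 9) m split into SEA and household components. Uniform bearing
  makes the direction variable span [0, π] with mean π/2, close to the
  published 1.3 ± 0.85.
* **Covariates:** independent draws per record matched to the published
  non-participant means/SDs (the larger, less-selected group): truncated
  normals for bounded quantities, Bernoulli for binaries, log-normals for
  expenditure. The real covariate joint distribution is unpublished;
  independence is the simplest testable default.
* **Roster:** household members are drawn per cohort as Poisson counts
  (rates 1.69 children, 1.13 adolescents, 1 + 1.65 adults per household,
  matching the published cohort totals per interviewed household). The
  roster is deliberately independent of the reported household-size
  covariate, so cohort-level covariate means hit their targets without
  size-biased sampling effects.
* **Outcome and selection:** latent log BLL from the child/adult reference
  coefficient sets; participation from the probit reference sets;
  (ε, v) bivariate normal with SD(ε) = σ_ε, SD(v) = 1, correlation ρ
  (default 0) — the canonical selection-on-unobservables process that the
  inverse-Mills correction assumes. σ_ε = 0.40 was calibrated once so the
  child outcome R² lands near the published 0.74 (observed ≈ 0.71–0.78
  across seeds; documented, not asserted). Adolescents are never offered
  participation. Observed BLL is exp(latent), masked for non-participants.

One master seed drives a single deterministic stream; identical seeds give
byte-identical surveys.

**What the generator does not emulate:** covariate correlations (e.g.
informal settlements lying downwind near the dump), interview-stage
nonresponse, household panel structure, real ward geography, measurement
error in BLL assays. Consequently, passing tests demonstrate that the
estimators recover the assumed data-generating process — not that the
synthetic district's *levels* match the real one. In particular the
observed association between participation and location class can have the
opposite sign from the real survey, where it is driven by geography–
covariate correlations the generator omits; and the published continuity of
predicted BLLs across the 18/19-year cohort boundary depends on the real
covariate joint distribution and is not reproduced under independent
covariates.

## Default problem sizes

The Monte-Carlo suites run at the scale the estimators are meant for:
parameter recovery uses 200 replicates of single-cohort surveys with ~5,000
individuals in 40 SEA clusters; selection-test calibration uses 500
replicates at the default survey scale (~1,700 children, ~380
participants); the bias-reduction comparison at ρ = 0.6 uses 40 replicates.
The demo pipeline and grid use the default design (1,000 households,
~5,300 individuals; 1 km cells over a 20 × 20 km synthetic district with
quadrant wards).

## Known limitations

* The second-stage covariance omits the generated-regressor correction
  away from the null (flagged above); a full Murphy–Topel/Heckman variance
  is not implemented.
* The grid surface ships with a synthetic district polygon and uniform ward
  covariates; real cartography and ward means would be dropped in as
  fixtures.
* Weighted quantile interpolation is one of several conventions; results
  at small n differ across conventions.
* No spatial autocorrelation beyond SEA clustering; no random effects; no
  multiple imputation for missing covariates (missing covariates are a
  named error, not silently dropped).
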
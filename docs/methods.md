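# Methods

This note documents the statistical model, the synthetic-data generator
that stands in for cohort data, the numerical choices inside the sampler,
and what the package's tests do and do not establish.

## 1. The distributed lag interaction model

For child *i*, outcome *yᵢ* (a spirometry z-score or raw GSTP1 %5mC),
covariates *zᵢ*, weekly exposures *xᵢₜ* (t = 1…T gestational weeks,
µg/m³) and sex *g(i)*:

yᵢ = zᵢᵀγ + β_{g(i)} Σₜ w_{g(i),t} xᵢₜ + εᵢ, εᵢ ~ N(0, σ²), ‖w_g‖₂ = 1.

The lag function δ_{g,t} = β_g w_{g,t} separates *timing* (w, a unit-L2
vector) from *magnitude* (β, outcome units per µg/m³). Patterns `n`, `b`,
`w`, `bw` share or free each component across the two sexes. The weight
vector is parameterized as w = Bξ/‖Bξ‖ where B (T × K) is a natural cubic
spline basis over the week index with K evenly spaced knots spanning
[1, T]; K (the `weight_df`) is chosen by DIC via `select_weight_df`.

The (β, w) pair is only identified up to a joint sign flip. The stored
draws follow the convention Σₜ w_t ≥ 0, applied to the smallest invariant
block: per (β_g, w_g) pair for patterns `n`/`bw`; for pattern `b` the
shared w is flipped together with both βs; for pattern `w` the shared β is
flipped together with both weight vectors, keyed on the first group's
weight sum (the second group's sign is then data-identified).

**Group main effect.** Exposures are strictly positive, so each group's
weighted-exposure column contains a near-constant component (mean exposure
times Σw). Without the modifier's main effect in the design this component
is confounded with a group mean shift through the shared intercept, which
couples the two sexes' effect estimates. `fit_bdlim` therefore always
augments Z with the group indicator when a two-level modifier is supplied
(skipped if already spanned). This is the usual main-effects-with-
interactions convention.

### Priors and sampler

- γ, β ~ N(0, c²) with c² = 100 (weakly informative on standardized
  outcomes); σ² ~ Inverse-Gamma(0.01, 0.01); ξ ~ N(0, I_K) — the radial
  direction of ξ is not identified (w is scale-free), and the standard
  normal prior keeps the chain proper without affecting w.
- Metropolis-within-Gibbs: joint conjugate normal draw of (γ, β…) given
  the weights; conjugate inverse-gamma draw of σ²; spherical random-walk
  Metropolis on each ξ_g with per-group proposal scales adapted during
  burn-in toward 20–40% acceptance (×0.8 below 20%, ×1.25 above 40%,
  batches of 100).
- Defaults: 10,000 iterations, 5,000 burn-in, thinning 5, seed recorded in
  the fit. The acceptance and test simulations use 4,000–6,000 iterations
  with half burn-in — the package's chosen simulation sizes, which the
  oracle checks show are sufficient for the summaries reported.
- A fit whose β chain has effective sample size (arviz `ess`) below 100 is
  flagged `converged=False` with a warning, never an error.

### DIC and pattern probabilities

DIC = D̄ + p_D with D̄ the posterior mean deviance and
p_D = D̄ − D(plug-in), where the plug-in uses posterior means of γ, β, σ²
and the renormalized mean weight vector. Pattern comparison reports
normalized pseudo-probabilities exp(−ΔDIC/2)/Σexp(−ΔDIC/2); this is a
DIC-based approximation to a posterior model probability and is labelled
as such in the table metadata. Ties in `select_weight_df` break toward the
smaller basis dimension.

### Windows and cumulative effects

Pointwise equal-tailed credible intervals are computed per week from the
draw percentiles (no density estimation, reproducible); HPD intervals are
deliberately not used. A sensitive window is a maximal run of consecutive
weeks whose interval excludes zero, reported as closed integer ranges.
The cumulative effect CE = Σₜ δ_t is computed draw-by-draw (identically
β·Σₜw_t), summarized by its mean and equal-tailed interval. Widening the
credible level can only shrink the window set (interval nesting).

## 2. The synthetic cohort generator

The generator emulates an urban pregnancy cohort followed to age ~7, with
marginals calibrated once to the motivating cohort's descriptives:

- **Exposure.** Weekly PM₂.₅ = 10.9 + 3.0·sin(2π(t+φᵢ)/52) + AR(1) noise
  (ρ = 0.6, innovation SD 2.2 µg/m³), truncated at 0, with a uniformly
  random conception phase φᵢ per subject. This yields per-subject
  pregnancy means with median ≈ 10.9 and IQR width ≈ 1.4 µg/m³ (target
  10.2–11.7). The sinusoid-plus-AR(1) form is a stand-in for a
  satellite-based exposure model; it preserves the within-pregnancy
  autocorrelation that makes window estimation nontrivial, which is the
  property the lag model actually stresses. One consequence worth knowing:
  a late-pregnancy window is seasonally *anti-correlated* with the
  pregnancy average, so flat-weight summaries and window-specific effects
  genuinely disagree — a useful stress test.
- **Covariates.** Sex (52.1% boys), race/ethnicity (22.8/65.5/11.7%
  Black/Hispanic/White-Other), maternal education (66.7% ≤12 y), smoking
  category (71.4/8.2/14.0/6.4%), asthma (15.8%), maternal age N(27.2,
  5.7²), child age N(6.9, 0.8²), height = 80 + 6·age + N(0, 5²) cm (the
  linear growth line only needs to create realistic collinearity for the
  z-score stage). Gestational age is uniform on 37…41 completed weeks;
  the exposure matrix always has T = 40 columns since ambient
  concentrations exist regardless of delivery date, and the analysis
  filter keeps the full-term (≥37 weeks) sample.
- **Spirometry.** FEV₁ = covariate linear predictor (target mean 1.44 L)
  + lag term + N(0, 0.20²). FVC = FEV₁ + gap, where the gap has its own
  linear predictor (mean 0.14 L), lag channel and N(0, 0.08²) noise, and
  is floored at 0.01 L — this enforces FEV₁ ≤ FVC exactly and makes the
  ratio column FEV₁/FVC consistent by construction (mean ≈ 0.91, SD
  ≈ 0.05). The configured FVC lag effect is injected into the gap as
  δ_fvc − δ_fev1, so the total FVC lag equals δ_fvc; the ratio outcome has
  no direct injection slot because it is derived. FEF₂₅₋₇₅ is a separate
  linear model (mean 1.87, residual SD 0.40 L/s).
- **Methylation.** Child-mean %5mC is lognormal with location ln(2.26) and
  scale solved so the IQR width matches 3.02 − 1.56 (a two-parameter
  lognormal cannot match three printed quantiles exactly; the quartiles
  land at 1.65/3.10 vs 1.56/3.02, inside the ±0.1 calibration band), plus
  an optional per-sex lag term, clipped to [0, 100]. The 17 CpG sites are
  the child mean times mean-one multiplicative lognormal noise (log-SD
  0.3), so the site average recovers the child mean.
- **True lag effects** are specified in raw outcome units per µg/m³.
  `lag_effects_for_zscore_ce` converts a z-scale cumulative-effect target
  into raw units by multiplying by the outcome's residual SD (for FVC, the
  combined fev1⊕gap SD). Because the injected lag term itself adds a few
  percent to the standardization residual SD, the realized z-scale CE is
  attenuated by ~3–4% relative to the nominal target.

Every generator is a pure function of (spec, seed); per-stage substreams
are derived with `SeedSequence` so stages can be re-run independently.

**What the generator does not emulate:** spatial structure and residential
mobility, exposure measurement error, calendar-time trends shared across
subjects, missing spirometry/assay data, and any causal pathway from
methylation to lung function (the methylation-model tests construct that
link explicitly). Passing recovery tests therefore demonstrate that the
estimator works under the assumed data-generating process, not that the
epidemiologic findings themselves are reproduced from real data.

## 3. Preprocessing conventions

- Daily exposures are averaged over days 7(t−1)+1 … 7t; a trailing partial
  week with ≥1 day is averaged over the available days rather than dropped
  (the delivery week is part of the reported windows); empty weeks are NaN.
- Z-scores are OLS residuals on age, sex, height and race/ethnicity
  (indicator contrasts), divided by the sample residual SD; mean 0 / SD 1
  holds within 1e−8 on the fitted sample, the fitted coefficients are
  exported so new children can be scored consistently, and the ratio
  outcome uses the same covariate set as the other three.
- The high-methylation split is the 75th percentile of the child-mean %5mC
  under the linear-interpolation ("type 7") quantile rule, declared in the
  output metadata; high ⇔ value ≥ threshold. The child-level summary is
  the arithmetic mean over non-missing CpG sites (a site-selection option
  exists since a single-position convention would also be defensible).
- Methylation-outcome models: complete cases, classical SEs. The model
  ladder is univariate; M1 += maternal age + education; M2 += child
  asthma; M3 += the four-level pre/postnatal smoking category via
  indicator contrasts. The interaction p-value is the Wald test of the
  sex × high-methylation product term added to a pooled M1 fit with a sex
  main effect.
- Lag-model adjustment sets: spirometry fits adjust for maternal age and
  education (the z-scores already absorb age, sex, height,
  race/ethnicity); methylation-outcome fits adjust for child age, sex,
  race/ethnicity, maternal age and education.

## 4. Numerical and design notes

- Degenerate inputs raise typed errors: zero-residual-variance outcomes,
  rank-deficient designs (offending columns named), exposure matrices with
  no between-subject variance, all-identical methylation samples, empty
  grids/draws. Credible levels are restricted to (0.5, 1).
- The natural-spline weight basis is built from the truncated-cubic
  construction (linear beyond the boundary knots); its unit test compares
  column spaces against an independently constructed scipy
  `CubicSpline(bc_type="natural")` basis via projection matrices.
- The conjugate-limit oracle integrates σ² by 1-D quadrature with θ
  marginalized in closed form, giving numerically exact posterior
  summaries and DIC for fixed-weight fits, independent of the sampler.
- Simulation sizes in the test suite (cohorts of 500–1,000 children,
  4,000–6,000 MCMC iterations, 10–20 seeds per experiment) are the
  package's chosen problem sizes; medians across seeds are compared
  against truth rather than single-seed estimates.

## 5. Known limitations

- A K-dimensional spline weight cannot represent a sharp window exactly;
  lag curves smear into adjacent weeks and, at high signal-to-noise,
  spline wiggle can produce short spurious significant runs away from the
  true window. DIC-based K selection mitigates but does not remove this.
- DIC pseudo-probabilities are not marginal-likelihood model
  probabilities; they are reported as the model-comparison convention and
  labelled accordingly.
- Pointwise (not simultaneous) credible bands are used for window
  identification, by design; multiplicity-adjusted bands are out of scope.
- With a binary modifier only; more than two groups are not supported.
- The random-walk update on ξ mixes slowly when the lag signal is weak
  (the weight function is then barely identified); the effective-sample-
  size flag surfaces this, and longer chains are the remedy.
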
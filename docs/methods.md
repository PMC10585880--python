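# Methods

## Synthetic mortality generator

Weekly death counts are simulated on the exact ISO-8601 calendar: one row per
ISO week, `t` = days since 1970-01-01 of the week's Monday, `w` =
`(iso_week - 1) / weeks_in_year` in [0, 1). Using the Monday anchor makes
consecutive rows exactly 7 days apart; the half-open `w` convention keeps a
cyclic seasonal function from evaluating week 1 and the year's last week at
the same point. Long years (2004, 2009, 2015, 2020 within 2000–2023) carry 53
weeks, so their totals run ~2% higher for purely calendrical reasons — the
evaluation keeps this, summing predicted weekly means over the true target
grid rather than multiplying a constant by 52.

The mean structure is

```
log mu_t = b0 + b1 t + b2 t^2 + A cos(2 pi w + phi) + sum_p h_p g_p^2 / ((t - c_p)^2 + g_p^2)
D_t ~ NegBin(mu_t, s)     Var = mu + mu^2/s
```

Base-case constants: `b0 = 10.11`, `b1 = -7.36e-5`, `b2 = 3.04e-9` (per day),
`A = 0.07`, `phi = -0.61` (seasonal peak near week 6), `s = 1000`. Scenarios
`constant` / `linear` / `nonmonotone` alter only the trend coefficients.

Each year draws at most one winter peak (probability 0.45, mode height
0.11–0.33 on the log scale, Cauchy scale 8.41–35.36 **days**, located
uniformly over ISO weeks 1–11) and one summer peak (0.40, 0.10–0.24,
0.86–9.24 days, weeks 26–37). Conventions chosen here:

- **Width units.** The peak widths are interpreted as Cauchy scales in days,
  and the kernel is evaluated on the day timeline. Week-scale widths would
  produce flu seasons spanning multiple years and year-total standard
  deviations of ~130k deaths, an order of magnitude beyond both German
  reality and the error magnitudes the study design targets; the day scale
  gives winter epidemics of 1–5 weeks' half-width adding ~30–40k deaths,
  matching both. (Pilot check: constant scenario, year-to-year SD of totals
  ≈ 31k deaths → irreducible MSE floor ≈ 935 on the thousands² scale.)
- **Mode normalization.** The Cauchy kernel is rescaled so a peak adds
  exactly its sampled height to `log mu` at its mode; heights are printed as
  log-scale magnitudes, which forces this normalization.
- **Continuous locations.** Peak centers are continuous uniform over the day
  span from Monday of the window's first week through the end of its last
  week; tails extend over the whole timeline (a late-December peak spills
  into the next year).

What a green test on this generator does **not** establish: the generator has
no population structure, no age/sex stratification, no reporting delays and a
single fixed dispersion, so method rankings transfer to real data only to the
extent those features are irrelevant to trend extrapolation.

## Spline bases

- **Cyclic cubic (seasonality):** periodic cubic B-splines on `k = 10`
  uniform knots over the unit period (C2 at the wrap), exact
  integrated-squared-second-derivative penalty via 2-point Gauss quadrature
  (the integrand is piecewise quadratic, so the rule is exact). The penalty's
  null space is the constants; a sum-to-zero centering constraint is absorbed
  by a QR-derived contrast, leaving `k - 1` columns identifiable next to an
  intercept. The dimension 10 is a configuration knob (`seasonal_k`).
- **Natural cubic (AI trend):** truncated-power construction with the natural
  constraints absorbed, boundary knots at the training range, internal knots
  equally spaced, covariate rescaled to [0, 1] internally for conditioning.
  Linear outside the boundary knots by construction, so the forecast-period
  evaluation is the exact linear extrapolation.
- **Thin plate (WHO trend):** 1-D order-2 thin-plate spline, radial basis
  `|r|^3 / 12`, rank-reduced to `k` by keeping the eigencomponents of the
  radial matrix largest in magnitude, with the side condition absorbing
  `{1, t}` as the unpenalized null space. Tiny negative penalty eigenvalues
  from truncation round-off are clipped to zero. Because the penalty is the
  squared second derivative, the fitted trend extrapolates linearly.
  The eigendecomposition is cached on the covariate vector, so Monte-Carlo
  studies pay it once per training window rather than per replication.

## Regression engine

Penalized IRLS with a log link. Negative binomial weights `mu/(1 + mu/theta)`,
Poisson weights `mu`; initialization `mu = y + 0.5`; the penalized deviance is
monitored and steps are halved (up to 30 times) if it would increase; inner
tolerance 1e-9 relative, cap 100 iterations.

Smoothing parameters minimize the Laplace-approximate restricted likelihood

```
V(lambda) = -l(beta) + 1/2 beta' S beta + 1/2 log|X'WX + S| - 1/2 log|S|_+
```

over `log10 lambda` in [-8, 12] — Brent for one smooth, Nelder-Mead for two —
with `|S|_+` the pseudo-determinant (per-block `rank * log lambda` plus the
positive-eigenvalue log-determinant). For the negative binomial family,
`theta` is estimated by profile maximum likelihood (bounded scalar search on
`log theta`) alternated with the lambda search. The alternation stops when
the joint change of `(log10 lambda, log10 theta)` falls below 1e-5 or the
criterion stalls (1e-8 relative), capped at 200 rounds; a derivative-free
search cannot meaningfully localize `log lambda` to the nominal 1e-6, and
predictions are insensitive at this level (penalty-rescaling invariance holds
to ~1e-8 in practice). Quasi-Poisson dispersion is the Pearson statistic over
`n - edf`. A GCV criterion (`criterion="gcv"`) exists for cross-checks only.

Validation: fits match `statsmodels` GLM at `lambda = 0`, collapse to the
penalty null space at `lambda = 1e12`, and — on a frozen simulated series —
match R `mgcv::gam(..., family=nb(), method="REML")` predictions to ~1e-5
relative for well-conditioned fits (~0.3% for the deliberately
ill-conditioned 5-year / k=10 configuration), and R `glm + splines::ns`
quasi-Poisson fits to numerical precision.

## The four predictors

All train on `start_year..2019` and predict the 2020–2023 ISO grid. The
`average` and `linear` methods are NB GLMs with the cyclic seasonal smooth
plus a constant or linear trend. The WHO-style method adds the thin-plate
trend of dimension `k` (REML-smoothed). The AI-style method is quasi-Poisson
with two sin/cos harmonic pairs in `w` and a natural-spline trend whose
*dimension* is `floor(tkpy * training_years)` (minimum 1; dimension 1 is a
plain linear trend; a natural spline of dimension m has m − 1 internal
knots). This dimension reading — rather than counting internal knots — is
required to reproduce the reference results, matches R's `ns(x, df = m)`,
and avoids a degenerate 0-knot configuration at `tkpy = 1/12` with 10
training years. With fewer than 7 training years the AI trend is always
linear ("< 7" from the method's running description; the alternative "≤ 7"
appears once in its tabular summary and is treated as a typo). Harmonics use
`w` rather than day-frequency terms; on a weekly grid the two agree up to a
phase reparameterization absorbed by the free coefficients.

The study grid: average starts {2000, 2005, 2010, 2015, 2019}; linear
{2000, 2005, 2010, 2015}; WHO the same starts × k ∈ {3, 5, 10, 15, 20}
(3 included because the published results recommend it); AI the same starts ×
tkpy ∈ {1/4, 1/5, 1/7, 1/9, 1/12}.

## Evaluation

Per replication (seed = `base_seed + rep`, so adding configurations never
perturbs existing results), one dataset is simulated and *every*
configuration is scored on it, enabling paired comparisons. Metrics over
2020–2023: MSE and bias on yearly totals divided by 1000, MAPE in percent.
The thousands scale makes an RMSE of ~8k deaths read as MSE ≈ 70 and is the
only scale consistent with the reference error magnitudes; MAPE is scale-free
and serves as the cross-check. Aggregation uses sample SDs (n−1). Non-
converged fits still contribute predictions, flagged per replication; a
configuration failing on more than 5% of replications aborts the study with
a diagnostic. Best-parametrization selection minimizes mean MSE per method,
with deterministic tie-breaks (earlier start, then smaller `k`/`tkpy`).

Desk-scale defaults: the test suite reproduces the linear-scenario
best-parametrization MSEs at 250 replications (tolerance widened to
3 × reported SD / √250) with the WHO grid reduced to k = 3 (justified by the
separately asserted monotone degradation in k), and the qualitative rankings
at 200 replications. Full-grid, 1000-replication reproduction of every
scenario is a multi-hour run and is not attempted in the default suite.

## Known limitations

- No prediction intervals or coverage assessment (point estimates only).
- No population offsets, age/sex structure, or reporting-delay adjustment.
- REML optimization for two smooths uses Nelder-Mead; pathological smoothing
  landscapes (very short windows with large `k`) can settle in shallow local
  optima — mirroring the instability of the method being studied, but worth
  knowing when comparing against other software at high precision.
- The weekly CSV layout (`iso_year,iso_week,deaths`) is deliberately minimal;
  real exports need pre-aggregation to ISO weeks before use.
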
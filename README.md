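# basemort

Baseline (expected) weekly mortality prediction, and a Monte-Carlo harness for
comparing prediction methods — the machinery behind excess-mortality
calculations.

## The problem

Excess mortality is observed deaths minus a *baseline*: the deaths a country
would have recorded had nothing unusual happened, forecast from pre-event
history. Every excess estimate is therefore only as good as its baseline
model, and seemingly reasonable models can fail dramatically — most famously,
a WHO estimate of ~195k cumulative excess deaths for Germany in 2020–21,
roughly double other estimates, traced to an over-flexible spline whose
extrapolation bent with one noisy year. This package reproduces that failure
mode and quantifies it: it simulates realistic weekly death counts with known
ground truth, applies four standard baseline predictors, and measures which
parametrizations predict well.

## The model and the methods

Synthetic weekly counts on the true ISO-8601 calendar (52/53-week years)
follow a negative binomial model

```
D_t ~ NegBin(mu_t, s),    s = 1000
log mu_t = b0 + b1 t + b2 t^2 + A cos(2 pi w[t] + phi) + peaks
```

with `t` the time in days since 1970-01-01, `w[t]` the week of the year
scaled to [0, 1), and randomly occurring Cauchy-shaped log-scale peaks for
winter flu seasons and summer heat waves. The base case is calibrated to
German-magnitude mortality (~0.8–1.0 million deaths/year); alternative
scenarios make the long-term trend constant, linear, or non-monotone.

Four predictors are fitted on `start_year..2019` and extrapolated to
2020–2023 (yearly totals `Mhat_y` = sums of predicted weekly means):

| method    | trend              | seasonality            | family (log link) |
|-----------|--------------------|------------------------|-------------------|
| `average` | constant           | cyclic cubic spline    | negative binomial |
| `linear`  | `b1 t`             | cyclic cubic spline    | negative binomial |
| `who`     | thin-plate spline (dimension `k`, REML-penalized) | cyclic cubic spline | negative binomial |
| `ai`      | natural cubic spline (`floor(tkpy * years)` df) | two sin/cos harmonics | quasi-Poisson |

The penalized fits use an in-package P-IRLS engine with Laplace-approximate
REML smoothing selection and profile-ML negative-binomial dispersion; both
trend splines carry second-derivative penalties, so every forecast is a
linear extrapolation of the trend. Prediction quality over 2020–2023 is
scored per replication by MSE and bias on the thousands-of-deaths scale and
by MAPE (percent), then averaged over replications.

## A worked example

`python examples/predict_baseline.py` fits all four methods on one simulated
base-case series and prints (thousands of deaths):

```
ground truth (thousands): [989.4, 951.5, 954.1, 1005.4]
average(2015)        -> [918.8, 901.4, 901.4, 901.4]
linear(2005)         -> [939.1, 928.6, 935.7, 942.9]
who(2005, k=3)       -> [952.4, 945.3, 956.2, 967.3]
ai(2005, tkpy=1/7)   -> [953.7, 947.1, 958.4, 969.9]
who(2015, k=10)      -> [1223.8, 1607.4, 2146.0, 2865.0]
```

The average of past (higher-mortality) years under-shoots a rising finish;
the linear and small-basis spline fits track the truth within ~2%; and the
flexible spline on a five-year window (`who(2015, k=10)` — the configuration
implicated in the German estimate) predicts almost triple the true 2023
mortality. `examples/run_study.py` repeats this over 40 simulated datasets:
the linear method's best configuration reaches mean MSE ≈ 70 (thousands²,
i.e. ~8.4k deaths RMSE on ~950k/year), with the natural-spline and
small-`k` thin-plate methods close behind and averaging far worse — the
ordering reported by the full-scale study.

Other examples: `examples/simulate_mortality.py` (anatomy of the generator),
`examples/render_report.py` (best-parametrization table and comparison
figures from a two-scenario study).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computation from scratch — a Monte-Carlo study on
the linear-trend scenario with one representative configuration per method —
prints the best-parametrization error summary, and writes the results JSON.

## Layout

- `src/basemort/timebase.py` — ISO-week grid, time covariates, weekly CSV I/O
- `src/basemort/simulate.py` — scenario parameters and the synthetic generator
- `src/basemort/splines.py` — cyclic cubic, natural cubic and thin-plate bases
- `src/basemort/glm.py` — penalized IRLS + REML engine (NB / quasi-Poisson)
- `src/basemort/methods.py` — the four predictors and the study grid
- `src/basemort/evaluation.py` — metrics, Monte-Carlo studies, paired comparisons
- `src/basemort/reporting.py` — fixtures, tables and figures
- `docs/methods.md` — modelling assumptions, conventions, and limitations
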
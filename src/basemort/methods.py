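"""The four baseline-mortality predictors.

Each method maps a training weekly series (``start_year``..2019) to predicted
weekly expected counts on the target-year ISO grid, summed to yearly totals:

- ``average`` — NB GLM, log mu = b0 + f_cc(w): seasonality plus a constant,
  i.e. the seasonal-adjusted average of the training years;
- ``linear``  — NB GLM, log mu = b0 + b1 t + f_cc(w): linear long-term trend;
- ``who``     — NB GLM, log mu = f_tp(t) + f_cc(w): penalized thin-plate trend
  of basis dimension ``k``, smoothing chosen by REML; the second-derivative
  penalty makes the forecast a linear extrapolation of the trend;
- ``ai``      — quasi-Poisson GLM, log mu = b0 + f_nc(t) + two sin/cos
  harmonic pairs in w: natural cubic spline trend of dimension
  ``floor(tkpy * training_years)`` (tkpy = trend knots per year; the spline
  dimension counts one more than its internal knots, and dimension 1 is a
  plain linear trend); with fewer than 7 training years the trend is always
  the linear term b1 t.

Because predictions are sums of predicted weekly means on the true ISO
calendar, 53-week target years (e.g. 2020) automatically get higher totals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from . import glm
from .splines import cyclic_cubic_basis, natural_cubic_basis, tprs_basis
from .timebase import build_week_grid, weeks_in_iso_year, yearly_totals

TRAIN_END = 2019  # last pre-target training year
METHODS = ("average", "linear", "who", "ai")

#: default dimension (knot count) of the cyclic seasonal spline
SEASONAL_K = 10

#: hyperparameter grids of the comparison study
START_YEARS_AVERAGE = (2000, 2005, 2010, 2015, 2019)
START_YEARS = (2000, 2005, 2010, 2015)
WHO_K_GRID = (3, 5, 10, 15, 20)
AI_TKPY_GRID = (
    Fraction(1, 4),
    Fraction(1, 5),
    Fraction(1, 7),
    Fraction(1, 9),
    Fraction(1, 12),
)

#: below this many training years the AI trend is a plain linear term
AI_LINEAR_SWITCH_YEARS = 7


@dataclass(frozen=True)
class MethodConfig:
    """One predictor with its hyperparameters.

    ``k`` (trend-basis dimension) applies only to ``who``; ``tkpy`` (trend
    knots per year of training data) only to ``ai``.
    """

    method: str
    start_year: int
    k: int | None = None
    tkpy: Fraction | float | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.start_year > TRAIN_END:
            raise ValueError(f"start_year must be <= {TRAIN_END}")
        if (self.k is not None) != (self.method == "who"):
            raise ValueError("k is required for 'who' and forbidden otherwise")
        if (self.tkpy is not None) != (self.method == "ai"):
            raise ValueError("tkpy is required for 'ai' and forbidden otherwise")

    def label(self) -> str:
        extra = ""
        if self.k is not None:
            extra = f", k={self.k}"
        if self.tkpy is not None:
            extra = f", tkpy={self.tkpy}"
        return f"{self.method}({self.start_year}{extra})"


def method_grid() -> list[MethodConfig]:
    """The investigated hyperparameter grid of the comparison study.

    WHO basis dimensions are the union {3, 5, 10, 15, 20}: the study grid
    plus the small value the results recommend.
    """
    grid = [MethodConfig("average", s) for s in START_YEARS_AVERAGE]
    grid += [MethodConfig("linear", s) for s in START_YEARS]
    grid += [MethodConfig("who", s, k=k) for s in START_YEARS for k in WHO_K_GRID]
    grid += [
        MethodConfig("ai", s, tkpy=t) for s in START_YEARS for t in AI_TKPY_GRID
    ]
    return grid


def _check_training_coverage(train: pd.DataFrame, start_year: int) -> None:
    for year in range(start_year, TRAIN_END + 1):
        have = int((train["iso_year"] == year).sum())
        need = weeks_in_iso_year(year)
        if have != need:
            raise ValueError(
                f"training window {start_year}..{TRAIN_END} is not fully "
                f"covered: year {year} has {have} of {need} ISO weeks"
            )


def _build_design(train: pd.DataFrame, config: MethodConfig, seasonal_k: int):
    """Training design, smooth blocks, family, and an evaluator for new rows."""
    t = train["t_days"].to_numpy(dtype=float)
    w = train["w"].to_numpy(dtype=float)
    n = len(t)
    ones = np.ones((n, 1))

    if config.method == "ai":
        n_years = TRAIN_END - config.start_year + 1
        if n_years < AI_LINEAR_SWITCH_YEARS:
            t_mean, t_sd = t.mean(), t.std()
            trend_train = ((t - t_mean) / t_sd)[:, None]

            def trend_eval(t_new):
                return ((t_new - t_mean) / t_sd)[:, None]

        else:
            # floor(tkpy * years) is the trend's spline dimension (df); a
            # natural cubic spline with df columns has df - 1 internal knots,
            # and df = 1 degenerates to a plain linear trend
            df = max(1, math.floor(float(config.tkpy) * n_years))
            nc = natural_cubic_basis(t, df - 1)
            trend_train = nc.matrix
            trend_eval = nc.evaluate

        def harmonics(w_arr):
            tau = 2.0 * np.pi * w_arr
            return np.column_stack(
                [np.sin(tau), np.cos(tau), np.sin(2 * tau), np.cos(2 * tau)]
            )

        X = np.hstack([ones, trend_train, harmonics(w)])

        def evaluate(grid):
            t_new = grid["t_days"].to_numpy(dtype=float)
            w_new = grid["w"].to_numpy(dtype=float)
            return np.hstack(
                [
                    np.ones((len(t_new), 1)),
                    trend_eval(t_new),
                    harmonics(w_new),
                ]
            )

        return X, [], "quasipoisson", evaluate

    cc = cyclic_cubic_basis(w, seasonal_k)
    m_cc = cc.matrix.shape[1]

    if config.method == "average":
        X = np.hstack([ones, cc.matrix])
        blocks = [glm.SmoothBlock(1, 1 + m_cc, cc.penalty)]

        def evaluate(grid):
            w_new = grid["w"].to_numpy(dtype=float)
            return np.hstack([np.ones((len(w_new), 1)), cc.evaluate(w_new)])

    elif config.method == "linear":
        t_mean, t_sd = t.mean(), t.std()
        X = np.hstack([ones, ((t - t_mean) / t_sd)[:, None], cc.matrix])
        blocks = [glm.SmoothBlock(2, 2 + m_cc, cc.penalty)]

        def evaluate(grid):
            t_new = grid["t_days"].to_numpy(dtype=float)
            w_new = grid["w"].to_numpy(dtype=float)
            return np.hstack(
                [
                    np.ones((len(t_new), 1)),
                    ((t_new - t_mean) / t_sd)[:, None],
                    cc.evaluate(w_new),
                ]
            )

    else:  # who
        tp = tprs_basis(t, config.k)
        m_tp = tp.matrix.shape[1]  # k - 1 columns (k - 2 penalized + linear)
        X = np.hstack([ones, tp.matrix, cc.matrix])
        blocks = [
            glm.SmoothBlock(1, 1 + m_tp, tp.penalty),
            glm.SmoothBlock(1 + m_tp, 1 + m_tp + m_cc, cc.penalty),
        ]

        def evaluate(grid):
            t_new = grid["t_days"].to_numpy(dtype=float)
            w_new = grid["w"].to_numpy(dtype=float)
            return np.hstack(
                [
                    np.ones((len(t_new), 1)),
                    tp.evaluate(t_new),
                    cc.evaluate(w_new),
                ]
            )

    return X, blocks, "negbin", evaluate


def fit_and_predict(
    series: pd.DataFrame,
    config: MethodConfig,
    target_years,
    seasonal_k: int = SEASONAL_K,
) -> pd.DataFrame:
    """Fit one predictor on ``start_year``..2019 and predict yearly totals.

    Weekly expected counts are predicted on the target years' ISO grid
    (honoring 53-week years) and summed per year. Returns a DataFrame indexed
    by year with a ``predicted`` column — and an ``actual`` column when the
    input series itself covers the target years (simulated data). A fit that
    hits its iteration cap still predicts, with a warning and
    ``result.attrs["converged"] = False``.
    """
    target_years = sorted(int(y) for y in target_years)
    train = series.loc[
        (series["iso_year"] >= config.start_year) & (series["iso_year"] <= TRAIN_END)
    ]
    _check_training_coverage(train, config.start_year)
    if target_years and target_years[0] <= TRAIN_END:
        raise ValueError("target years must follow the training window")

    X, blocks, family, evaluate = _build_design(train, config, seasonal_k)
    y = train["deaths"].to_numpy(dtype=float)
    fit_result = glm.fit(y, glm.ModelSpec(X=X, family=family, blocks=blocks))
    if not fit_result.converged:
        warnings.warn(
            f"{config.label()}: underlying fit did not converge; "
            "predictions are reported anyway",
            glm.NonConvergenceWarning,
            stacklevel=2,
        )

    out = pd.DataFrame(index=pd.Index(target_years, name="year"))
    if target_years:
        grid = build_week_grid(target_years[0], target_years[-1])
        grid = grid.loc[grid["iso_year"].isin(target_years)]
        mu = glm.predict_mean(fit_result, evaluate(grid))
        out["predicted"] = (
            pd.Series(mu, index=grid["iso_year"].to_numpy()).groupby(level=0).sum()
        )
        weekly = grid.copy()
        weekly["mu"] = mu
        out.attrs["weekly"] = weekly
        covered = [
            yr
            for yr in target_years
            if (series["iso_year"] == yr).sum() == weeks_in_iso_year(yr)
        ]
        if covered == target_years:
            out["actual"] = yearly_totals(series, target_years)
    out.attrs["converged"] = fit_result.converged
    out.attrs["fit"] = fit_result
    return out
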
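"""Monte-Carlo comparison of the baseline predictors.

Each replication simulates one weekly series (2000–2023), evaluates every
method configuration on that same dataset, and scores the predicted yearly
totals for 2020–2023 against the simulated truth with

    MSE  = 1/4 * sum_y (M_y - Mhat_y)^2      (thousands-of-deaths scale)
    MAPE = 1/4 * sum_y |M_y - Mhat_y| / M_y  (reported in percent)
    Bias = 1/4 * sum_y (M_y - Mhat_y)        (thousands-of-deaths scale)

Yearly totals are divided by 1000 before MSE and bias so that the reported
magnitudes are comparable across studies of ~10^6-deaths/year populations;
MAPE is scale-free. Replication ``r`` uses seed ``base_seed + r``, so results
are reproducible and adding configurations never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methods import MethodConfig, fit_and_predict
from .simulate import scenario_params, simulate
from .timebase import build_week_grid, yearly_totals

TARGET_YEARS = (2020, 2021, 2022, 2023)

#: study abort threshold: a config failing on more than this share of
#: replications aborts with a diagnostic
MAX_FAILURE_RATE = 0.05

_SCALE = 1000.0  # deaths -> thousands of deaths


def metrics(actual: pd.Series, predicted: pd.Series) -> tuple[float, float, float]:
    """(MSE, MAPE, bias) of predicted vs actual yearly totals.

    MSE and bias are computed on the thousands-of-deaths scale; MAPE is in
    percent. Both inputs must be indexed by the same years.
    """
    actual = pd.Series(actual).astype(float)
    predicted = pd.Series(predicted).astype(float)
    if set(actual.index) != set(predicted.index):
        raise ValueError("actual and predicted must cover the same years")
    predicted = predicted.reindex(actual.index)
    if (actual == 0).any():
        bad = list(actual.index[actual == 0])
        raise ValueError(f"MAPE undefined: zero actual totals in years {bad}")
    err = (actual - predicted) / _SCALE
    mse = float((err**2).mean())
    mape = float((np.abs(actual - predicted) / actual).mean() * 100.0)
    bias = float(err.mean())
    return mse, mape, bias


@dataclass
class StudyResult:
    """Per-replication metric records of one Monte-Carlo study."""

    scenario: str
    raw: pd.DataFrame  # one row per (config, replication)
    n_reps: int
    base_seed: int

    def summary(self) -> pd.DataFrame:
        """Aggregated mean and SD (n-1 denominator) per config and metric.

        Long format: ``scenario, method, start_year, k, tkpy, metric, mean,
        sd, n_reps`` — SD is NaN for single-replication studies.
        """
        keys = ["scenario", "method", "start_year", "k", "tkpy"]
        long = self.raw.melt(
            id_vars=keys + ["rep"],
            value_vars=["mse", "mape", "bias"],
            var_name="metric",
        )
        agg = (
            long.groupby(keys + ["metric"], dropna=False)["value"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1), n_reps="count")
            .reset_index()
        )
        return agg


def _config_key(cfg: MethodConfig) -> dict:
    return {
        "method": cfg.method,
        "start_year": cfg.start_year,
        "k": cfg.k if cfg.k is not None else np.nan,
        "tkpy": float(cfg.tkpy) if cfg.tkpy is not None else np.nan,
    }


def run_study(
    scenario: str,
    configs: list[MethodConfig],
    n_reps: int,
    base_seed: int,
    target_years=TARGET_YEARS,
) -> StudyResult:
    """Simulate ``n_reps`` datasets and score every config on each of them.

    All configs see the same simulated series within a replication, so
    per-replication errors are directly comparable across methods. Any config
    failing to fit on more than 5% of replications aborts the study with a
    diagnostic naming the failing replications.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not configs:
        raise ValueError("at least one method configuration is required")
    params = scenario_params(scenario)
    grid = build_week_grid(2000, max(target_years))
    rows = []
    failures: dict[str, list[int]] = {cfg.label(): [] for cfg in configs}
    max_failures = int(np.floor(MAX_FAILURE_RATE * n_reps))
    for rep in range(n_reps):
        rng = np.random.default_rng(base_seed + rep)
        series = simulate(grid, params, rng)
        actual = yearly_totals(series, target_years)
        for cfg in configs:
            try:
                pred = fit_and_predict(series, cfg, target_years)
                mse, mape, bias = metrics(actual, pred["predicted"])
            except Exception as exc:  # noqa: BLE001 - failure policy below
                failures[cfg.label()].append(rep)
                if len(failures[cfg.label()]) > max_failures:
                    raise RuntimeError(
                        f"config {cfg.label()} failed on more than "
                        f"{MAX_FAILURE_RATE:.0%} of replications "
                        f"(replications {failures[cfg.label()]}): {exc}"
                    ) from exc
                continue
            rows.append(
                {
                    "scenario": scenario,
                    **_config_key(cfg),
                    "rep": rep,
                    "mse": mse,
                    "mape": mape,
                    "bias": bias,
                    "converged": bool(pred.attrs["converged"]),
                }
            )
    return StudyResult(
        scenario=scenario,
        raw=pd.DataFrame(rows),
        n_reps=n_reps,
        base_seed=base_seed,
    )


def best_parametrization(summary: pd.DataFrame) -> pd.DataFrame:
    """Per method, the configuration minimizing mean MSE.

    Input is the long-format study summary. Ties break deterministically:
    earlier ``start_year``, then smaller ``k``, then smaller ``tkpy``.
    Returns the summary rows (all three metrics) of each winning config.
    """
    if summary is None or len(summary) == 0:
        raise ValueError("empty study summary")
    mse = summary.loc[summary["metric"] == "mse"].copy()
    mse = mse.sort_values(
        ["mean", "start_year", "k", "tkpy"], na_position="first", kind="stable"
    )
    winners = mse.drop_duplicates("method", keep="first")
    # NaN hyperparameters don't survive an equi-join; realign explicitly
    out = []
    for _, win in winners.iterrows():
        mask = (summary["method"] == win["method"]) & (
            summary["start_year"] == win["start_year"]
        )
        for col in ("k", "tkpy"):
            if np.isnan(win[col]):
                mask &= summary[col].isna()
            else:
                mask &= summary[col] == win[col]
        out.append(summary.loc[mask])
    return pd.concat(out, ignore_index=True)


def compare_paired(
    raw: pd.DataFrame, config_a: MethodConfig, config_b: MethodConfig
) -> dict:
    """Paired per-replication MSE comparison of two configs.

    Both configs must have been evaluated on the same replication stream.
    Returns the per-replication MSE differences (a - b), their mean and SD,
    and the fraction of replications where a beats b (ties count 1/2, so a
    config compared with itself scores exactly 0.5).
    """

    def _select(cfg):
        mask = (raw["method"] == cfg.method) & (raw["start_year"] == cfg.start_year)
        mask &= raw["k"].isna() if cfg.k is None else raw["k"] == cfg.k
        mask &= (
            raw["tkpy"].isna() if cfg.tkpy is None else raw["tkpy"] == float(cfg.tkpy)
        )
        return raw.loc[mask].set_index("rep")["mse"]

    a, b = _select(config_a), _select(config_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both configurations must be present in the records")
    if not a.index.equals(b.index):
        raise ValueError(
            "configurations were not evaluated on the same replication stream"
        )
    diff = a - b
    return {
        "diff": diff,
        "mean_diff": float(diff.mean()),
        "sd_diff": float(diff.std(ddof=1)) if len(diff) > 1 else float("nan"),
        "frac_a_better": float((a < b).mean() + 0.5 * (a == b).mean()),
        "n_reps": int(len(diff)),
    }
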
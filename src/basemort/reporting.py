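"""Study configuration, fixture generation, and table/figure rendering.

This package is used from Python; the operations here are the plumbing a
study script needs: a declarative :class:`StudyConfig`, a deterministic CSV
fixture generator (standing in for Eurostat-style weekly mortality exports),
and renderers that turn a study summary into the standard artifacts — a
best-parametrization table (mean ± SD of MSE per scenario), a metric panel
over all parametrizations, and an MSE-vs-starting-year line chart on a log
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")  # headless rendering; figures are written, not shown
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evaluation import best_parametrization
from .methods import MethodConfig, method_grid
from .simulate import SCENARIOS, simulate_scenario
from .timebase import write_weekly_csv

#: canonical row order of the method-comparison table
METHOD_ORDER = ("ai", "average", "linear", "who")
METHOD_LABELS = {"ai": "AI", "average": "Average", "linear": "Linear", "who": "WHO"}

SUMMARY_COLUMNS = [
    "scenario",
    "method",
    "start_year",
    "k",
    "tkpy",
    "metric",
    "mean",
    "sd",
    "n_reps",
]


@dataclass
class StudyConfig:
    """Declarative description of one Monte-Carlo study."""

    scenarios: tuple[str, ...] = ("quadratic",)
    n_reps: int = 1000
    base_seed: int = 1
    configs: list[MethodConfig] = field(default_factory=method_grid)
    strict: bool = False  # exclude non-converged fits from aggregation

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        unknown = [s for s in self.scenarios if s not in SCENARIOS]
        if unknown:
            raise ValueError(f"unknown scenarios: {unknown}")


def make_fixture(seed: int, out_path) -> pd.DataFrame:
    """Write one base-case simulated series (2000–2023) as a weekly CSV.

    Deterministic given ``seed``; used by tests and examples in place of a
    downloaded national mortality export.
    """
    series = simulate_scenario("quadratic", seed)
    write_weekly_csv(series, out_path)
    return series


def _validate_summary(summary: pd.DataFrame) -> None:
    missing = [c for c in SUMMARY_COLUMNS if c not in summary.columns]
    if missing:
        raise ValueError(f"study summary is missing columns: {missing}")


def _fmt_pm(mean: float, sd: float) -> str:
    return f"{mean:.1f} ± {sd:.1f}"


def best_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Best-parametrization MSE table: methods x scenarios, "mean ± SD" cells.

    Rows are ordered AI, Average, Linear, WHO; for each method and scenario
    the configuration with the lowest mean MSE is reported.
    """
    _validate_summary(summary)
    if len(summary) == 0:
        warnings.warn("empty study summary: rendering an empty table")
        return pd.DataFrame()
    cells = {}
    for scenario, sub in summary.groupby("scenario"):
        best = best_parametrization(sub)
        best = best.loc[best["metric"] == "mse"]
        for _, row in best.iterrows():
            cells.setdefault(scenario, {})[row["method"]] = _fmt_pm(
                row["mean"], row["sd"]
            )
    table = pd.DataFrame(cells)
    table = table.reindex([m for m in METHOD_ORDER if m in table.index])
    table.index = [METHOD_LABELS[m] for m in table.index]
    table.index.name = "Method"
    return table


def _config_label(row) -> str:
    bits = [f"{int(row['start_year'])}"]
    if not np.isnan(row["k"]):
        bits.append(f"k={int(row['k'])}")
    if not np.isnan(row["tkpy"]):
        bits.append(f"tkpy=1/{round(1 / row['tkpy'])}")
    return ",".join(bits)


def metric_panel(summary: pd.DataFrame, scenario: str) -> plt.Figure:
    """log(MSE), MAPE and bias of every parametrization of every method."""
    _validate_summary(summary)
    sub = summary.loc[summary["scenario"] == scenario]
    fig, axes = plt.subplots(3, 1, figsize=(10, 9), sharex=True)
    if len(sub) == 0:
        warnings.warn(f"no records for scenario {scenario!r}: empty panel")
        return fig
    wide = sub.pivot_table(
        index=["method", "start_year", "k", "tkpy"],
        columns="metric",
        values="mean",
        dropna=False,
    ).reset_index()
    wide = wide.sort_values(["method", "start_year", "k", "tkpy"], na_position="first")
    labels = [
        f"{METHOD_LABELS[r['method']]} {_config_label(r)}" for _, r in wide.iterrows()
    ]
    x = np.arange(len(wide))
    if (wide["mse"] <= 0).any():
        raise ValueError("MSE must be positive for the log-scale panel")
    for ax, metric, tr in (
        (axes[0], "mse", np.log),
        (axes[1], "mape", None),
        (axes[2], "bias", None),
    ):
        vals = wide[metric].to_numpy(dtype=float)
        ax.plot(x, tr(vals) if tr else vals, "o")
        ax.set_ylabel("logMSE" if metric == "mse" else metric.upper())
        ax.grid(True, alpha=0.3)
    axes[2].set_xticks(x)
    axes[2].set_xticklabels(labels, rotation=90, fontsize=6)
    fig.suptitle(f"Error metrics by parametrization — scenario: {scenario}")
    fig.tight_layout()
    return fig


def mse_by_start_year(summary: pd.DataFrame) -> plt.Figure:
    """MSE against starting year per method and scenario, log y-scale.

    Where a method has several parametrizations per starting year, the best
    (lowest mean MSE) is shown.
    """
    _validate_summary(summary)
    scenarios = list(dict.fromkeys(summary["scenario"]))
    n = max(len(scenarios), 1)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False, sharey=True)
    if len(summary) == 0:
        warnings.warn("empty study summary: rendering an empty figure")
        return fig
    mse = summary.loc[summary["metric"] == "mse"]
    if (mse["mean"] <= 0).any():
        raise ValueError("MSE must be positive for a log-scale plot")
    for ax, scenario in zip(axes[0], scenarios):
        sub = mse.loc[mse["scenario"] == scenario]
        for method in METHOD_ORDER:
            msub = sub.loc[sub["method"] == method]
            if len(msub) == 0:
                continue
            series = msub.groupby("start_year")["mean"].min()
            ax.plot(series.index, series.values, "o-", label=METHOD_LABELS[method])
        ax.set_yscale("log")
        ax.set_title(scenario)
        ax.set_xlabel("starting year")
        ax.grid(True, alpha=0.3)
    axes[0][0].set_ylabel("MSE (thousands$^2$)")
    axes[0][0].legend()
    fig.tight_layout()
    return fig


def render_report(summary: pd.DataFrame, out_dir=None) -> dict:
    """Render the standard report artifacts from a study summary.

    Returns a dict with the best-parametrization table and both figures;
    when ``out_dir`` is given, also writes ``best_mse.csv``,
    ``metric_panel_<scenario>.png`` and ``mse_by_start_year.png`` there.
    Deterministic given the input records.
    """
    _validate_summary(summary)
    table = best_table(summary)
    artifacts = {"best_table": table, "panels": {}, "start_year_figure": None}
    if len(summary):
        for scenario in dict.fromkeys(summary["scenario"]):
            artifacts["panels"][scenario] = metric_panel(summary, scenario)
        artifacts["start_year_figure"] = mse_by_start_year(summary)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "best_mse.csv")
        for scenario, figure in artifacts["panels"].items():
            figure.savefig(out / f"metric_panel_{scenario}.png", dpi=120)
        if artifacts["start_year_figure"] is not None:
            artifacts["start_year_figure"].savefig(
                out / "mse_by_start_year.png", dpi=120
            )
    return artifacts
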
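"""Metrics, Monte-Carlo study mechanics, best-config selection, pairing."""

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from basemort import evaluation
from basemort.evaluation import (
    best_parametrization,
    compare_paired,
    metrics,
    run_study,
)
from basemort.methods import MethodConfig

YEARS = [2020, 2021, 2022, 2023]


def _totals(vals):
    return pd.Series(vals, index=YEARS, dtype=float)


class TestMetrics:
    def test_worked_example(self):
        # totals of 1 000 000 predicted as 990 000: errors of 10 (thousands)
        actual = _totals([1_000_000] * 4)
        predicted = _totals([990_000] * 4)
        mse, mape, bias = metrics(actual, predicted)
        assert mse == pytest.approx(100.0)
        assert mape == pytest.approx(1.0)  # percent
        assert bias == pytest.approx(10.0)

    def test_perfect_prediction(self):
        actual = _totals([950_000, 940_000, 960_000, 955_000])
        assert metrics(actual, actual) == (0.0, 0.0, 0.0)

    def test_bias_sign_sensitivity(self):
        a = _totals([1_000_000, 1_010_000, 990_000, 1_005_000])
        b = _totals([995_000, 1_020_000, 980_000, 1_010_000])
        mse_ab, mape_ab, bias_ab = metrics(a, b)
        mse_ba, mape_ba, bias_ba = metrics(b, a)
        assert bias_ab == pytest.approx(-bias_ba)
        assert mse_ab == pytest.approx(mse_ba)
        # MAPE is normalized by the actual, so it is not exactly symmetric
        assert mape_ab == pytest.approx(mape_ba, rel=0.05)

    def test_zero_actual_rejected(self):
        with pytest.raises(ValueError, match="MAPE undefined"):
            metrics(_totals([0, 1, 1, 1]), _totals([1, 1, 1, 1]))

    def test_mismatched_years_rejected(self):
        with pytest.raises(ValueError, match="same years"):
            metrics(_totals([1] * 4), pd.Series([1.0], index=[2020]))


@pytest.fixture(scope="module")
def tiny_study():
    configs = [MethodConfig("average", 2015), MethodConfig("average", 2019)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study("constant", configs, n_reps=3, base_seed=77)


class TestRunStudy:
    def test_reproducible_from_seed(self, tiny_study):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = run_study(
                "constant",
                [MethodConfig("average", 2015), MethodConfig("average", 2019)],
                n_reps=3,
                base_seed=77,
            )
        pd.testing.assert_frame_equal(tiny_study.raw, again.raw)

    def test_adding_configs_preserves_existing_records(self, tiny_study):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bigger = run_study(
                "constant",
                [
                    MethodConfig("average", 2015),
                    MethodConfig("average", 2019),
                    MethodConfig("linear", 2015),
                ],
                n_reps=3,
                base_seed=77,
            )
        old = tiny_study.raw.set_index(["method", "start_year", "rep"])["mse"]
        new = bigger.raw.set_index(["method", "start_year", "rep"])["mse"]
        assert (new.loc[old.index] == old).all()

    def test_single_rep_has_no_sd(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_study(
                "constant", [MethodConfig("average", 2019)], n_reps=1, base_seed=5
            )
        summ = res.summary()
        assert summ["sd"].isna().all()
        assert (summ["n_reps"] == 1).all()
        raw_mse = res.raw["mse"].iloc[0]
        assert summ.loc[summ["metric"] == "mse", "mean"].iloc[0] == raw_mse

    def test_aggregation_matches_raw(self, tiny_study):
        summ = tiny_study.summary()
        for (_, start), sub in tiny_study.raw.groupby(["method", "start_year"]):
            row = summ[
                (summ["start_year"] == start) & (summ["metric"] == "mse")
            ].iloc[0]
            assert row["mean"] == pytest.approx(sub["mse"].mean())
            assert row["sd"] == pytest.approx(sub["mse"].std(ddof=1))

    def test_failing_config_aborts_with_diagnostic(self, monkeypatch):
        real = evaluation.fit_and_predict

        def sabotage(series, cfg, years, **kw):
            if cfg.method == "linear":
                raise RuntimeError("boom")
            return real(series, cfg, years, **kw)

        monkeypatch.setattr(evaluation, "fit_and_predict", sabotage)
        with pytest.raises(RuntimeError, match="linear\\(2015\\)"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                run_study(
                    "constant",
                    [MethodConfig("average", 2019), MethodConfig("linear", 2015)],
                    n_reps=2,
                    base_seed=5,
                )

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            run_study("constant", [MethodConfig("average", 2019)], 0, 1)
        with pytest.raises(ValueError):
            run_study("constant", [], 2, 1)


def _summary_row(method, start, mse, k=np.nan, tkpy=np.nan, sd=1.0):
    return {
        "scenario": "constant",
        "method": method,
        "start_year": start,
        "k": k,
        "tkpy": tkpy,
        "metric": "mse",
        "mean": mse,
        "sd": sd,
        "n_reps": 10,
    }


class TestBestParametrization:
    def test_single_config(self, tiny_study):
        summ = tiny_study.summary()
        one = summ[summ["start_year"] == 2019]
        best = best_parametrization(one)
        assert set(best["start_year"]) == {2019}

    def test_picks_minimum_mse(self):
        summ = pd.DataFrame(
            [
                _summary_row("who", 2000, 5.0, k=3),
                _summary_row("who", 2005, 3.0, k=10),
                _summary_row("average", 2019, 7.0),
            ]
        )
        best = best_parametrization(summ)
        who = best[best["method"] == "who"].iloc[0]
        assert (who["start_year"], who["k"]) == (2005, 10)

    def test_tie_break_is_deterministic(self):
        summ = pd.DataFrame(
            [
                _summary_row("who", 2005, 3.0, k=10),
                _summary_row("who", 2000, 3.0, k=15),
                _summary_row("who", 2000, 3.0, k=5),
            ]
        )
        best = best_parametrization(summ)
        who = best[best["method"] == "who"].iloc[0]
        assert (who["start_year"], who["k"]) == (2000, 5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            best_parametrization(pd.DataFrame())


class TestComparePaired:
    def test_self_comparison(self, tiny_study):
        cfg = MethodConfig("average", 2015)
        res = compare_paired(tiny_study.raw, cfg, cfg)
        assert res["mean_diff"] == 0.0
        assert res["frac_a_better"] == 0.5
        assert (res["diff"] == 0).all()

    def test_paired_mean_equals_difference_of_means(self, tiny_study):
        a, b = MethodConfig("average", 2015), MethodConfig("average", 2019)
        res = compare_paired(tiny_study.raw, a, b)
        raw = tiny_study.raw
        mean_a = raw[raw["start_year"] == 2015]["mse"].mean()
        mean_b = raw[raw["start_year"] == 2019]["mse"].mean()
        assert res["mean_diff"] == pytest.approx(mean_a - mean_b)

    def test_mismatched_streams_rejected(self, tiny_study):
        raw = tiny_study.raw
        chopped = raw.drop(raw[(raw["start_year"] == 2019) & (raw["rep"] == 2)].index)
        with pytest.raises(ValueError, match="replication stream"):
            compare_paired(
                chopped, MethodConfig("average", 2015), MethodConfig("average", 2019)
            )

    def test_absent_config_rejected(self, tiny_study):
        with pytest.raises(ValueError, match="present"):
            compare_paired(
                tiny_study.raw,
                MethodConfig("average", 2015),
                MethodConfig("ai", 2015, tkpy=Fraction(1, 7)),
            )
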
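"""Penalized GLM engine: oracle limits, REML invariances, dispersion recovery."""

import numpy as np
import pytest
import statsmodels.api as sm

from basemort import glm
from basemort.splines import cyclic_cubic_basis, tprs_basis


def _nb_draws(rng, mu, theta):
    return rng.negative_binomial(theta, theta / (theta + mu))


@pytest.fixture(scope="module")
def seasonal_counts():
    """Ten years of weekly NB counts with a smooth seasonal pattern."""
    rng = np.random.default_rng(42)
    w = np.tile(np.arange(52) / 52.0, 10)
    mu = np.exp(9.0 + 0.1 * np.cos(2 * np.pi * w - 0.5))
    y = _nb_draws(rng, mu, 800.0)
    cc = cyclic_cubic_basis(w, k=10)
    X = np.hstack([np.ones((len(w), 1)), cc.matrix])
    spec = glm.ModelSpec(
        X=X, family="negbin", blocks=[glm.SmoothBlock(1, 10, cc.penalty)]
    )
    return y, X, cc, spec


class TestValidation:
    def test_rejects_negative_and_fractional_counts(self):
        X = np.ones((10, 1))
        spec = glm.ModelSpec(X=X, family="negbin")
        with pytest.raises(ValueError, match="nonnegative integer"):
            glm.fit(np.array([1.0] * 9 + [-1.0]), spec)
        with pytest.raises(ValueError, match="nonnegative integer"):
            glm.fit(np.array([1.5] * 10), spec)

    def test_rejects_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            glm.ModelSpec(X=np.ones((5, 1)), family="gaussian")

    def test_block_shape_checked(self):
        with pytest.raises(ValueError, match="penalty shape"):
            glm.SmoothBlock(0, 3, np.eye(2))

    def test_predict_conformability(self):
        fit = glm.fit(
            np.array([3, 4, 5, 4, 3]), glm.ModelSpec(X=np.ones((5, 1)), family="negbin")
        )
        with pytest.raises(ValueError, match="columns"):
            glm.predict_mean(fit, np.ones((2, 3)))


class TestUnpenalized:
    def test_nb_parameter_recovery(self):
        # log-linear NB data: coefficients within 3 SE, theta within 25%
        rng = np.random.default_rng(1)
        n, theta = 2000, 1000.0
        x = rng.uniform(-1, 1, n)
        X = np.column_stack([np.ones(n), x])
        mu = np.exp(6.0 + 0.5 * x)
        y = _nb_draws(rng, mu, theta)
        fit = glm.fit(y, glm.ModelSpec(X=X, family="negbin"))
        oracle = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=1.0 / fit.theta)
        ).fit()
        se = oracle.bse
        assert abs(fit.coef[0] - 6.0) < 3 * se[0]
        assert abs(fit.coef[1] - 0.5) < 3 * se[1]
        assert fit.theta == pytest.approx(theta, rel=0.25)
        # and the coefficients agree with the independent IRLS oracle
        assert fit.coef == pytest.approx(oracle.params, rel=1e-5)

    def test_intercept_only_prediction(self):
        y = np.array([10, 12, 9, 11, 10, 8])
        fit = glm.fit(y, glm.ModelSpec(X=np.ones((6, 1)), family="quasipoisson"))
        pred = glm.predict_mean(fit, np.ones((3, 1)))
        assert pred == pytest.approx(np.exp(fit.coef[0]))
        assert pred[0] == pytest.approx(y.mean(), rel=1e-8)

    def test_quasipoisson_dispersion(self):
        # overdispersed data: Pearson dispersion well above 1
        rng = np.random.default_rng(2)
        mu = 200.0
        y = _nb_draws(rng, np.full(3000, mu), 50.0)
        fit = glm.fit(y, glm.ModelSpec(X=np.ones((3000, 1)), family="quasipoisson"))
        expected = 1.0 + mu / 50.0  # Var/mu for NB
        assert fit.pearson_dispersion == pytest.approx(expected, rel=0.15)


class TestPenalizedLimits:
    def test_lambda_zero_matches_unpenalized_oracle(self, seasonal_counts):
        y, X, cc, spec = seasonal_counts
        qspec = glm.ModelSpec(X=X, family="quasipoisson", blocks=spec.blocks)
        ours = glm.fit(y, qspec, lambdas=np.array([0.0]))
        oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert glm.predict_mean(ours, X) == pytest.approx(
            oracle.mu, rel=1e-6
        )

    def test_huge_lambda_collapses_to_null_space(self, seasonal_counts):
        # the centered cyclic penalty is PD, so lambda -> inf leaves only the
        # intercept; for a thin-plate block it leaves the affine trend
        y, X, cc, spec = seasonal_counts
        qspec = glm.ModelSpec(X=X, family="quasipoisson", blocks=spec.blocks)
        ours = glm.fit(y, qspec, lambdas=np.array([1e12]))
        oracle = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Poisson()).fit()
        assert glm.predict_mean(ours, X) == pytest.approx(oracle.mu, rel=1e-4)

        t = np.arange(300.0)
        rng = np.random.default_rng(9)
        y2 = rng.poisson(np.exp(4.0 + 0.002 * t))
        tp = tprs_basis(t, k=8)
        X2 = np.hstack([np.ones((300, 1)), tp.matrix])
        spec2 = glm.ModelSpec(
            X=X2,
            family="quasipoisson",
            blocks=[glm.SmoothBlock(1, 8, tp.penalty)],
        )
        ours2 = glm.fit(y2, spec2, lambdas=np.array([1e12]))
        affine = sm.GLM(
            y2, np.column_stack([np.ones(300), t]), family=sm.families.Poisson()
        ).fit()
        assert glm.predict_mean(ours2, X2) == pytest.approx(affine.mu, rel=1e-4)

    def test_edf_between_null_space_and_basis_dim(self, seasonal_counts):
        y, X, cc, spec = seasonal_counts
        fit = glm.fit(y, spec)
        assert 0.0 < fit.edf[0] <= 9.0
        forced = glm.fit(y, spec, lambdas=np.array([1e12]))
        assert forced.edf[0] == pytest.approx(0.0, abs=1e-3)


class TestREML:
    def test_penalty_rescaling_invariance(self, seasonal_counts):
        y, X, cc, spec = seasonal_counts
        scaled = glm.ModelSpec(
            X=X,
            family="negbin",
            blocks=[glm.SmoothBlock(1, 10, 100.0 * cc.penalty)],
        )
        f1, f2 = glm.fit(y, spec), glm.fit(y, scaled)
        assert f1.lambdas[0] == pytest.approx(100.0 * f2.lambdas[0], rel=1e-4)
        assert glm.predict_mean(f1, X) == pytest.approx(
            glm.predict_mean(f2, X), rel=1e-6
        )

    def test_gcv_flag_available_but_not_default(self, seasonal_counts):
        y, X, cc, spec = seasonal_counts
        f_gcv = glm.fit(y, spec, criterion="gcv")
        assert np.isfinite(f_gcv.lambdas[0]) and f_gcv.lambdas[0] > 0
        with pytest.raises(ValueError, match="criterion"):
            glm.fit(y, spec, criterion="aic")

    def test_quasipoisson_matches_negbin_when_near_poisson(self):
        # huge theta: the two families should give nearly identical fits
        rng = np.random.default_rng(4)
        w = np.tile(np.arange(52) / 52.0, 6)
        mu = np.exp(8.0 + 0.05 * np.cos(2 * np.pi * w))
        y = rng.poisson(mu)
        cc = cyclic_cubic_basis(w, k=10)
        X = np.hstack([np.ones((len(w), 1)), cc.matrix])
        blocks = [glm.SmoothBlock(1, 10, cc.penalty)]
        f_nb = glm.fit(y, glm.ModelSpec(X=X, family="negbin", blocks=blocks))
        f_qp = glm.fit(y, glm.ModelSpec(X=X, family="quasipoisson", blocks=blocks))
        assert f_nb.theta > 1e4  # detected as near-Poisson
        assert f_qp.pearson_dispersion == pytest.approx(1.0, abs=0.15)
        assert glm.predict_mean(f_nb, X) == pytest.approx(
            glm.predict_mean(f_qp, X), rel=1e-3
        )


class TestIRLSBehavior:
    def test_penalized_deviance_monotone_across_restarts(self, seasonal_counts):
        # restarting P-IRLS from its own solution cannot increase the
        # penalized deviance (the inner objective is monitored and halved)
        y, X, cc, spec = seasonal_counts
        S = np.zeros((10, 10))
        S[1:, 1:] = cc.penalty
        first = glm._pirls(y, X, S, "negbin", 800.0)
        second = glm._pirls(y, X, S, "negbin", 800.0, beta0=first["beta"])
        assert second["pdev"] <= first["pdev"] + 1e-8 * abs(first["pdev"])

    def test_nonconvergence_warns_and_flags(self, seasonal_counts, monkeypatch):
        y, X, cc, spec = seasonal_counts
        monkeypatch.setattr(glm, "_PIRLS_MAXIT", 1)
        qspec = glm.ModelSpec(X=X, family="quasipoisson", blocks=spec.blocks)
        with pytest.warns(glm.NonConvergenceWarning):
            fit = glm.fit(y, qspec, lambdas=np.array([1.0]))
        assert fit.converged is False
        assert np.all(np.isfinite(fit.coef))
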
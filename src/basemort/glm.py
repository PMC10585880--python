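"""Penalized count GLMs with REML smoothing selection.

Fits log-link generalized linear models for weekly death counts with two
families:

- negative binomial with unknown dispersion ``theta`` (variance
  ``mu + mu^2/theta``), the family of the average / linear / WHO-style
  predictors;
- quasi-Poisson (Poisson estimating equations, multiplicative dispersion from
  the Pearson statistic), the family of the Acosta–Irizarry-style predictor.

The design is an ordinary matrix plus zero or more *smooth blocks*, each a
contiguous column range with a symmetric positive-semidefinite penalty. For a
given smoothing vector ``lambda`` and dispersion, coefficients come from
penalized iteratively reweighted least squares (P-IRLS). ``lambda`` is chosen
by minimizing the Laplace-approximate restricted marginal likelihood

    V(lambda) = -l(beta_hat) + 1/2 beta_hat' S_l beta_hat
                + 1/2 log|X'WX + S_l| - 1/2 log|S_l|_+

over log(lambda) (Brent for one smooth, Nelder-Mead for several), where
``S_l = sum_j lambda_j S_j`` and ``|.|_+`` is the pseudo-determinant over the
penalized space. For the negative binomial family, ``theta`` is estimated by
profile maximum likelihood in an outer alternation with the lambda search.
A GCV criterion is available behind a flag for cross-checks; REML is always
the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve

FAMILIES = ("negbin", "quasipoisson")

_MAX_OUTER = 200  # cap on theta/lambda alternation rounds
_ALTERNATION_TOL = 1e-5  # joint change of (log10 lambda, log10 theta)
_PIRLS_TOL = 1e-9
_PIRLS_MAXIT = 100
_LOG10_LAMBDA_BOUNDS = (-8.0, 12.0)


class NonConvergenceWarning(UserWarning):
    """Emitted when a fit hits its iteration cap without converging."""


@dataclass(frozen=True)
class SmoothBlock:
    """A penalized contiguous column range of the design matrix."""

    start: int
    stop: int
    penalty: np.ndarray

    def __post_init__(self):
        m = self.stop - self.start
        if self.penalty.shape != (m, m):
            raise ValueError(
                f"penalty shape {self.penalty.shape} does not match "
                f"block width {m}"
            )


@dataclass
class ModelSpec:
    """Design matrix, family, and smooth blocks of one model."""

    X: np.ndarray
    family: str
    blocks: list[SmoothBlock] = field(default_factory=list)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        p = self.X.shape[1]
        prev_stop = 0
        for b in sorted(self.blocks, key=lambda b: b.start):
            if b.start < prev_stop or b.stop > p:
                raise ValueError("smooth blocks overlap or exceed the design")
            prev_stop = b.stop


@dataclass
class FitResult:
    """A fitted penalized GLM."""

    coef: np.ndarray
    family: str
    theta: float | None  # NB dispersion, None for quasi-Poisson
    pearson_dispersion: float | None  # quasi-Poisson scale, None for NB
    lambdas: np.ndarray  # per-smooth smoothing parameters
    edf: np.ndarray  # effective degrees of freedom per smooth
    edf_total: float
    converged: bool
    iterations: int
    deviance: float
    n_obs: int


def _nb_loglik(y, mu, theta):
    return np.sum(
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * np.log(theta)
        + special.xlogy(y, mu)
        - (y + theta) * np.log(mu + theta)
    )


def _poisson_loglik(y, mu):
    return np.sum(special.xlogy(y, mu) - mu - special.gammaln(y + 1.0))


def _deviance(y, mu, family, theta):
    if family == "negbin":
        return 2.0 * np.sum(
            special.xlogy(y, y / mu) - (y + theta) * np.log((y + theta) / (mu + theta))
        )
    return 2.0 * np.sum(special.xlogy(y, y / mu) - (y - mu))


def _ml_theta(y, mu, lo=1e-2, hi=1e8):
    """Profile-ML negative-binomial dispersion at fixed means."""
    res = optimize.minimize_scalar(
        lambda lt: -_nb_loglik(y, mu, np.exp(lt)),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def _pirls(y, X, S, family, theta, beta0=None):
    """Penalized IRLS at fixed (lambda, theta). Returns the converged state.

    The penalized deviance is monitored and never allowed to increase: if a
    step increases it, the step is halved (up to 30 times) before the fit is
    flagged non-convergent.
    """
    n, p = X.shape
    if beta0 is None:
        eta = np.log(np.maximum(y, 0.0) + 0.5)
        beta = None
    else:
        beta = beta0
        eta = X @ beta
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    # the data-based initialization is not a model iterate: never use it as the
    # step-halving benchmark, or the first step could be rejected outright
    pdev = (
        _deviance(y, mu, family, theta) + beta @ S @ beta
        if beta is not None
        else np.inf
    )
    converged = False
    it = 0
    for it in range(1, _PIRLS_MAXIT + 1):
        wgt = mu / (1.0 + mu / theta) if family == "negbin" else mu
        z = eta + (y - mu) / mu
        XtW = X.T * wgt
        A = XtW @ X + S
        b = XtW @ z
        try:
            cf = cho_factor(A, lower=True)
            beta_new = cho_solve(cf, b)
        except np.linalg.LinAlgError:
            A = A + 1e-8 * np.eye(p) * np.trace(A) / p
            cf = cho_factor(A, lower=True)
            beta_new = cho_solve(cf, b)

        step = beta_new if beta is None else beta_new - beta
        base = np.zeros(p) if beta is None else beta
        frac = 1.0
        for _ in range(30):
            cand = base + frac * step
            eta_c = np.clip(X @ cand, -30.0, 30.0)
            mu_c = np.exp(eta_c)
            pdev_c = _deviance(y, mu_c, family, theta) + cand @ S @ cand
            if np.isfinite(pdev_c) and (pdev_c <= pdev + 1e-12 * (abs(pdev) + 1.0)):
                break
            frac *= 0.5
        else:
            # could not decrease the penalized deviance
            beta, eta, mu = cand, eta_c, mu_c
            break
        beta, eta, mu = cand, eta_c, mu_c
        if abs(pdev - pdev_c) < _PIRLS_TOL * (abs(pdev_c) + 0.1):
            pdev = pdev_c
            converged = True
            break
        pdev = pdev_c

    wgt = mu / (1.0 + mu / theta) if family == "negbin" else mu
    return {
        "beta": beta,
        "mu": mu,
        "wgt": wgt,
        "pdev": pdev,
        "dev": _deviance(y, mu, family, theta),
        "iterations": it,
        "converged": converged,
    }


def _assemble_penalty(p, blocks, lambdas):
    S = np.zeros((p, p))
    for b, lam in zip(blocks, lambdas):
        S[b.start : b.stop, b.start : b.stop] += lam * b.penalty
    return S


def _penalty_eig(blocks):
    """Per-block penalty rank and positive-part log-determinant."""
    ranks, logdets = [], []
    for b in blocks:
        ev = np.linalg.eigvalsh(b.penalty)
        tol = ev.max() * len(ev) * np.finfo(float).eps if len(ev) else 0.0
        pos = ev[ev > tol]
        ranks.append(len(pos))
        logdets.append(float(np.sum(np.log(pos))))
    return np.array(ranks), np.array(logdets)


def _edf(X, wgt, S, blocks):
    XtWX = (X.T * wgt) @ X
    F = np.linalg.solve(XtWX + S, XtWX)
    per_block = np.array([np.trace(F[b.start : b.stop, b.start : b.stop]) for b in blocks])
    return per_block, float(np.trace(F))


def fit(
    y: np.ndarray,
    spec: ModelSpec,
    lambdas: np.ndarray | None = None,
    criterion: str = "reml",
) -> FitResult:
    """Fit a penalized count GLM, selecting smoothing parameters by REML.

    ``lambdas`` forces the smoothing parameters (one per smooth block),
    bypassing the REML search — used for limiting-case checks (``0`` gives the
    unpenalized fit, very large values shrink each smooth to its penalty null
    space). ``criterion="gcv"`` swaps the selection criterion for generalized
    cross-validation (cross-check only; REML is the default).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(spec.X, dtype=float)
    if y.ndim != 1 or len(y) != X.shape[0]:
        raise ValueError("y must be a vector conforming to the design rows")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must contain nonnegative integer counts")
    if criterion not in ("reml", "gcv"):
        raise ValueError(f"criterion must be 'reml' or 'gcv', got {criterion!r}")
    n, p = X.shape
    blocks = sorted(spec.blocks, key=lambda b: b.start)
    ranks, logdets = _penalty_eig(blocks)
    n_unpenalized = p - int(ranks.sum())
    if n <= n_unpenalized:
        raise ValueError(
            f"need more observations ({n}) than unpenalized dimensions "
            f"({n_unpenalized})"
        )

    family = spec.family
    state = {"beta": None}

    def run_pirls(lams, theta):
        S = _assemble_penalty(p, blocks, lams)
        res = _pirls(y, X, S, family, theta, beta0=state["beta"])
        if not np.all(np.isfinite(res["beta"])):
            res = _pirls(y, X, S, family, theta, beta0=None)
        state["beta"] = res["beta"]
        return res, S

    def crit_value(rho, theta):
        lams = 10.0**rho
        res, S = run_pirls(lams, theta)
        beta, wgt = res["beta"], res["wgt"]
        A = (X.T * wgt) @ X + S
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        if criterion == "gcv":
            _, edf_tot = _edf(X, wgt, S, blocks)
            return n * res["dev"] / (n - edf_tot) ** 2
        ll = (
            _nb_loglik(y, res["mu"], theta)
            if family == "negbin"
            else _poisson_loglik(y, res["mu"])
        )
        logdet_S = float(np.sum(ranks * rho * np.log(10.0)) + logdets.sum())
        return -ll + 0.5 * beta @ S @ beta + 0.5 * logdet_A - 0.5 * logdet_S

    theta = 1000.0 if family == "negbin" else np.inf
    pirls_converged = True
    outer_iters = 0

    if not blocks:
        # plain (unpenalized) GLM; for NB alternate IRLS with theta ML
        S0 = np.zeros((p, p))
        if family == "negbin":
            res = _pirls(y, X, S0, family, theta)
            for outer_iters in range(1, _MAX_OUTER + 1):
                theta_new = _ml_theta(y, res["mu"])
                res = _pirls(y, X, S0, family, theta_new, beta0=res["beta"])
                done = abs(np.log10(theta_new) - np.log10(theta)) < 1e-7
                theta = theta_new
                if done:
                    break
        else:
            res = _pirls(y, X, S0, family, theta)
            outer_iters = 1
        lam_out = np.array([])
    elif lambdas is not None:
        lam_out = np.asarray(lambdas, dtype=float)
        if len(lam_out) != len(blocks):
            raise ValueError("one forced lambda per smooth block required")
        if family == "negbin":
            res, _ = run_pirls(lam_out, theta)
            for outer_iters in range(1, _MAX_OUTER + 1):
                theta_new = _ml_theta(y, res["mu"])
                res, _ = run_pirls(lam_out, theta_new)
                done = abs(np.log10(theta_new) - np.log10(theta)) < 1e-7
                theta = theta_new
                if done:
                    break
        else:
            res, _ = run_pirls(lam_out, theta)
            outer_iters = 1
    else:
        lo, hi = _LOG10_LAMBDA_BOUNDS
        rho = np.zeros(len(blocks))

        def optimize_rho(rho0, wide):
            if len(blocks) == 1:
                lo1, hi1 = (lo, hi) if wide else (rho0[0] - 0.7, rho0[0] + 0.7)
                r = optimize.minimize_scalar(
                    lambda r1: crit_value(np.array([r1]), theta),
                    bounds=(lo1, hi1),
                    method="bounded",
                    options={"xatol": 0.05 if wide else 0.005},
                )
                return np.array([r.x]), r.fun
            r = optimize.minimize(
                lambda rv: crit_value(np.clip(rv, lo, hi), theta),
                rho0,
                method="Nelder-Mead",
                options={
                    "xatol": 0.05 if wide else 0.01,
                    "fatol": 1e-6 * (abs(crit0) + 1.0),
                    "maxfev": 200 if wide else 80,
                    "initial_simplex": np.vstack(
                        [rho0]
                        + [
                            rho0 + (1.5 if wide else 0.3) * e
                            for e in np.eye(len(rho0))
                        ]
                    ),
                },
            )
            return np.clip(r.x, lo, hi), r.fun

        crit0 = crit_value(rho, theta)
        crit_prev = np.inf
        for outer_iters in range(1, _MAX_OUTER + 1):
            rho_new, crit = optimize_rho(rho, wide=(outer_iters == 1))
            if family == "negbin":
                res, _ = run_pirls(10.0**rho_new, theta)
                theta_new = _ml_theta(y, res["mu"])
            else:
                theta_new = theta
            change = np.max(np.abs(rho_new - rho))
            if family == "negbin":
                change = max(change, abs(np.log10(theta_new) - np.log10(theta)))
            rho, theta = rho_new, theta_new
            if change < _ALTERNATION_TOL or abs(crit_prev - crit) < 1e-8 * (
                abs(crit) + 1.0
            ):
                break
            crit_prev = crit
        lam_out = 10.0**rho
        res, _ = run_pirls(lam_out, theta)

    if not res["converged"]:
        pirls_converged = False
        warnings.warn(
            "penalized IRLS did not converge within its iteration cap",
            NonConvergenceWarning,
            stacklevel=2,
        )
    if outer_iters >= _MAX_OUTER:
        pirls_converged = False
        warnings.warn(
            "dispersion/smoothing alternation hit its outer iteration cap",
            NonConvergenceWarning,
            stacklevel=2,
        )

    S_final = _assemble_penalty(p, blocks, lam_out) if blocks else np.zeros((p, p))
    edf_blocks, edf_total = _edf(X, res["wgt"], S_final, blocks)
    pearson = None
    theta_out = None
    if family == "negbin":
        theta_out = float(theta)
    else:
        mu = res["mu"]
        pearson = float(np.sum((y - mu) ** 2 / mu) / (n - edf_total))

    return FitResult(
        coef=res["beta"],
        family=family,
        theta=theta_out,
        pearson_dispersion=pearson,
        lambdas=lam_out,
        edf=edf_blocks,
        edf_total=edf_total,
        converged=pirls_converged,
        iterations=outer_iters,
        deviance=res["dev"],
        n_obs=n,
    )


def predict_mean(fit_result: FitResult, new_rows: np.ndarray) -> np.ndarray:
    """Expected counts ``exp(X_new beta)`` on new design rows."""
    X_new = np.asarray(new_rows, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != len(fit_result.coef):
        raise ValueError(
            f"new rows have {X_new.shape[1] if X_new.ndim == 2 else 'bad'} "
            f"columns; the fit has {len(fit_result.coef)} coefficients"
        )
    return np.exp(X_new @ fit_result.coef)
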
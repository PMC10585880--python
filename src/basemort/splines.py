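"""Spline bases and roughness penalties for the baseline predictors.

Three constructions are provided, matching the trend/seasonality components of
the four predictors:

- :func:`cyclic_cubic_basis` — a periodic cubic regression spline on ``k``
  uniformly spaced knots over [0, 1] (value, first- and second-derivative
  continuity at the wrap point), with the exact integrated-squared-second-
  derivative penalty, column-centered for identifiability next to an
  intercept. Used for seasonality by the average, linear and WHO-style models.
- :func:`natural_cubic_basis` — a natural cubic spline (linear beyond its
  boundary knots), so forecasts extrapolate linearly by construction. Used for
  the long-term trend of the Acosta–Irizarry-style model.
- :func:`tprs_basis` — a one-dimensional thin-plate regression spline of
  order 2 (radial basis ``|r|^3 / 12``), rank-reduced by eigen-truncation of
  the full radial penalty, with unpenalized null space {1, t}. Because the
  penalty is on the second derivative, out-of-sample forecasting is a linear
  extrapolation. Used for the long-term trend of the WHO-style model.

Each constructor returns a basis object carrying the training design
(``.matrix``), the conforming penalty (``.penalty``, where applicable) and an
``.evaluate(x)`` method that reproduces the training columns on new covariate
values, including values beyond the training range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space


# ---------------------------------------------------------------------------
# cyclic cubic regression spline
# ---------------------------------------------------------------------------


def _wrapped_bspline_design(x: np.ndarray, k: int, deriv: int = 0) -> np.ndarray:
    """Design matrix of the k wrapped (period-1) cubic B-splines at ``x``.

    Knots sit at j/k; basis function m is the periodic summation of the
    uniform cubic B-splines with index congruent to m mod k.
    """
    knots = np.arange(-3, k + 4, dtype=float) / k  # k + 7 knots, k + 3 splines
    n_full = k + 3
    if deriv == 0:
        full = BSpline.design_matrix(x, knots, 3).toarray()
    else:
        full = np.empty((x.size, n_full))
        for i in range(n_full):
            c = np.zeros(n_full)
            c[i] = 1.0
            full[:, i] = BSpline(knots, c, 3).derivative(deriv)(x)
    out = np.zeros((x.size, k))
    for i in range(n_full):
        out[:, i % k] += full[:, i]
    return out


@dataclass
class CyclicCubicBasis:
    """Centered periodic cubic regression spline basis on [0, 1)."""

    k: int
    matrix: np.ndarray  # n x (k-1), centered over the training rows
    penalty: np.ndarray  # (k-1) x (k-1), integrated squared second derivative
    null_space_dim: int  # of the penalty *before* centering (constants)
    _Z: np.ndarray = field(repr=False, default=None)  # k x (k-1) centering map

    def evaluate(self, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        if np.any((w < 0.0) | (w >= 1.0)):
            raise ValueError("cyclic covariate values must lie in [0, 1)")
        return _wrapped_bspline_design(w, self.k) @ self._Z


def cyclic_cubic_basis(w: np.ndarray, k: int = 10) -> CyclicCubicBasis:
    """Periodic cubic spline basis with exact second-derivative penalty.

    ``k`` is the number of (uniform) knots over the period; after absorbing
    the sum-to-zero (centering) constraint the basis has ``k - 1`` columns.
    The penalty's null space before centering is the constants, so after
    centering the penalty is positive definite.
    """
    w = np.asarray(w, dtype=float)
    if k < 4:
        raise ValueError(f"cyclic cubic basis needs k >= 4, got {k}")
    if np.any((w < 0.0) | (w >= 1.0)):
        raise ValueError("cyclic covariate values must lie in [0, 1)")

    # Exact penalty by 2-point Gauss quadrature per inter-knot interval:
    # second derivatives of cubics are piecewise linear, so the integrand is
    # piecewise quadratic and the rule is exact.
    h = 1.0 / k
    mids = (np.arange(k) + 0.5) * h
    off = h / (2.0 * np.sqrt(3.0))
    xq = np.concatenate([mids - off, mids + off])
    d2 = _wrapped_bspline_design(xq, k, deriv=2)
    S = (h / 2.0) * d2.T @ d2
    S = 0.5 * (S + S.T)

    X = _wrapped_bspline_design(w, k)
    # absorb the centering constraint 1'Xb = 0
    c = X.sum(axis=0)[:, None]
    Z = null_space(c.T)  # k x (k-1)
    return CyclicCubicBasis(
        k=k,
        matrix=X @ Z,
        penalty=Z.T @ S @ Z,
        null_space_dim=1,
        _Z=Z,
    )


# ---------------------------------------------------------------------------
# natural cubic spline
# ---------------------------------------------------------------------------


@dataclass
class NaturalCubicBasis:
    """Natural cubic spline basis: linear beyond the boundary knots.

    Built from the truncated-power representation with the natural
    constraints absorbed, on the covariate rescaled to [0, 1] over the
    training range; dimension is ``n_internal_knots + 1`` (no intercept
    column). Evaluation outside the boundary knots is exactly linear, so the
    same closed form serves for forecasting.
    """

    lo: float
    hi: float
    knots_u: np.ndarray  # all knots on the unit scale, boundary included
    matrix: np.ndarray

    @property
    def dim(self) -> int:
        return len(self.knots_u) - 1

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        u = (np.asarray(t, dtype=float) - self.lo) / (self.hi - self.lo)
        xi = self.knots_u
        K = len(xi)

        def d(j):  # truncated-power building block
            return (
                np.maximum(u - xi[j], 0.0) ** 3 - np.maximum(u - xi[K - 1], 0.0) ** 3
            ) / (xi[K - 1] - xi[j])

        cols = [u]
        d_last = d(K - 2)
        for j in range(K - 2):
            cols.append(d(j) - d_last)
        return np.column_stack(cols)


def natural_cubic_basis(
    t: np.ndarray, n_knots: int, range_: tuple[float, float] | None = None
) -> NaturalCubicBasis:
    """Natural cubic spline basis with equally spaced internal knots.

    ``n_knots`` internal knots are placed uniformly between the boundary
    knots ``range_`` (default: the observed covariate range); total dimension
    is ``n_knots + 1`` excluding the intercept. ``n_knots = 0`` degenerates to
    a single linear column.
    """
    t = np.asarray(t, dtype=float)
    if n_knots < 0:
        raise ValueError(f"n_knots must be >= 0, got {n_knots}")
    lo, hi = range_ if range_ is not None else (t.min(), t.max())
    if not lo < hi:
        raise ValueError(f"degenerate covariate range ({lo}, {hi})")
    knots_u = np.linspace(0.0, 1.0, n_knots + 2)
    basis = NaturalCubicBasis(lo=float(lo), hi=float(hi), knots_u=knots_u, matrix=None)
    basis.matrix = basis.evaluate(t)
    return basis


# ---------------------------------------------------------------------------
# thin plate regression spline (1-D, order-2 penalty)
# ---------------------------------------------------------------------------

_EIG_CACHE: dict = {}
_EIG_CACHE_MAX = 8


def _radial_eig(u: np.ndarray):
    """Cached eigendecomposition of the full radial matrix E_ij = |u_i-u_j|^3/12."""
    key = (u.tobytes(), len(u))
    hit = _EIG_CACHE.get(key)
    if hit is not None:
        return hit
    E = np.abs(u[:, None] - u[None, :]) ** 3 / 12.0
    vals, vecs = np.linalg.eigh(E)
    if len(_EIG_CACHE) >= _EIG_CACHE_MAX:
        _EIG_CACHE.pop(next(iter(_EIG_CACHE)))
    _EIG_CACHE[key] = (vals, vecs)
    return vals, vecs


@dataclass
class ThinPlateBasis:
    """Rank-``k`` thin-plate regression spline block for a 1-D covariate.

    ``matrix`` holds ``k - 2`` penalized columns followed by the (scaled)
    linear column; together with an external intercept this spans the full
    TPRS space. ``penalty`` is the conforming ``(k-1) x (k-1)`` matrix, zero
    on the linear column (the affine functions are the penalty null space).
    """

    k: int
    lo: float
    hi: float
    u_train: np.ndarray = field(repr=False)
    proj: np.ndarray = field(repr=False)  # n_train x (k-2): U_k Z
    matrix: np.ndarray = None
    penalty: np.ndarray = None
    null_space_dim: int = 2  # {1, t}; the intercept lives outside the block

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        u = (np.asarray(t, dtype=float) - self.lo) / (self.hi - self.lo)
        E_new = np.abs(u[:, None] - self.u_train[None, :]) ** 3 / 12.0
        return np.column_stack([E_new @ self.proj, u])


def tprs_basis(t: np.ndarray, k: int) -> ThinPlateBasis:
    """Low-rank 1-D thin-plate regression spline with 2nd-derivative penalty.

    The full radial smoother (basis ``|x - x_i|^3 / 12`` plus affine terms,
    side condition T'delta = 0 with T = [1, x]) is rank-reduced by keeping the
    ``k`` eigencomponents of the radial matrix largest in magnitude; the side
    condition is then absorbed exactly, leaving ``k - 2`` penalized columns.
    Because the retained penalty is the integrated squared second derivative,
    a fitted trend extrapolates linearly beyond the data.
    """
    t = np.asarray(t, dtype=float)
    if k < 3:
        raise ValueError(f"thin-plate basis needs k >= 3, got {k}")
    uniq = np.unique(t)
    if len(uniq) < k:
        raise ValueError(
            f"need at least k={k} distinct covariate values, got {len(uniq)}"
        )
    lo, hi = t.min(), t.max()
    u = (t - lo) / (hi - lo)

    vals, vecs = _radial_eig(u)
    order = np.argsort(-np.abs(vals), kind="stable")[:k]
    dk = vals[order]
    Uk = vecs[:, order]

    T = np.column_stack([np.ones_like(u), u])
    Z = null_space(T.T @ Uk)  # k x (k-2)
    proj = Uk @ Z
    X_pen = Uk @ (dk[:, None] * Z)  # = E @ proj, since Uk are exact eigenvectors

    S_pen = Z.T @ (dk[:, None] * Z)
    S_pen = 0.5 * (S_pen + S_pen.T)
    # E is conditionally PSD on {T'delta = 0}; clip eigen-roundoff
    ev, evec = np.linalg.eigh(S_pen)
    if ev.min() < 0:
        S_pen = (evec * np.maximum(ev, 0.0)) @ evec.T

    penalty = np.zeros((k - 1, k - 1))
    penalty[: k - 2, : k - 2] = S_pen

    basis = ThinPlateBasis(
        k=k,
        lo=float(lo),
        hi=float(hi),
        u_train=u,
        proj=proj,
        penalty=penalty,
    )
    basis.matrix = np.column_stack([X_pen, u])
    return basis
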
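"""Synthetic weekly mortality: negative-binomial counts around a structured mean.

The generator produces weekly all-cause death counts on an ISO week grid from

    log(mu_t) = beta0 + beta1 * t + beta2 * t^2 + A * cos(2*pi*w[t] + phi)
                + sum_peaks  h * gamma^2 / ((x_t - loc)^2 + gamma^2)
    D_t ~ NegBin(mu_t, size)        (variance mu + mu^2 / size)

with ``t`` the actual time in days since 1970-01-01 and ``w[t]`` the week of
the year scaled to [0, 1). The log-scale quadratic captures slow demographic
change, the single harmonic the regular winter/summer seasonality, and the
randomly occurring peaks emulate flu seasons (winter: broad, Cauchy scale
8.41–35.36 days) and heat waves (summer: sharp, 0.86–9.24 days). Each peak is
a Cauchy (Lorentzian) kernel rescaled so its mode adds exactly ``h`` to the
log-mean; tails extend over the whole timeline, so a late-December flu peak
spills into the next ISO year.

Default parameters are the base case calibrated to German-magnitude mortality
(~0.9–1.3 million deaths/year); three alternative long-term-trend scenarios
(constant, linear, non-monotone) share all other parameters.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .timebase import build_week_grid

_EPOCH = _dt.date(1970, 1, 1)

SCENARIOS = ("constant", "linear", "quadratic", "nonmonotone")


@dataclass(frozen=True)
class PeakLaw:
    """Yearly law of one random seasonal peak.

    With probability ``probability`` the season of a given year receives one
    peak; its height (log-scale, at the mode) is uniform on
    ``[height_min, height_max]``, its Cauchy scale uniform on
    ``[width_min, width_max]`` (days), and its location uniform in time over
    ISO weeks ``week_lo..week_hi`` of that year.
    """

    probability: float
    height_min: float
    height_max: float
    width_min: float
    width_max: float
    week_lo: int
    week_hi: int

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability must be in [0, 1], got {self.probability}")
        if self.height_min > self.height_max:
            raise ValueError("height_min must be <= height_max")
        if self.width_min > self.width_max:
            raise ValueError("width_min must be <= width_max")
        if self.week_lo > self.week_hi:
            raise ValueError("week_lo must be <= week_hi")


@dataclass(frozen=True)
class ScenarioParams:
    """All generative constants of one simulation scenario.

    beta0/beta1/beta2 are the log-scale trend coefficients on days since
    1970-01-01; A and phi the seasonal amplitude (log scale) and phase
    (radians); size the negative-binomial size parameter s
    (variance = mu + mu^2/s).
    """

    beta0: float
    beta1: float
    beta2: float
    A: float
    phi: float
    size: float
    winter: PeakLaw
    summer: PeakLaw

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError(f"size must be > 0, got {self.size}")
        if self.A < 0:
            raise ValueError(f"A must be >= 0, got {self.A}")


def base_case_params() -> ScenarioParams:
    """The base-case (quadratic-trend) generative constants."""
    return ScenarioParams(
        beta0=10.11,
        beta1=-7.36e-5,
        beta2=3.04e-9,
        A=0.07,
        phi=-0.61,
        size=1000.0,
        winter=PeakLaw(
            probability=0.45,
            height_min=0.11,
            height_max=0.33,
            width_min=8.41,
            width_max=35.36,
            week_lo=1,
            week_hi=11,
        ),
        summer=PeakLaw(
            probability=0.40,
            height_min=0.10,
            height_max=0.24,
            width_min=0.86,
            width_max=9.24,
            week_lo=26,
            week_hi=37,
        ),
    )


def scenario_params(name: str) -> ScenarioParams:
    """Generative constants for one of the four long-term-trend scenarios.

    ``quadratic`` is the base case; ``linear`` zeroes beta2; ``constant``
    zeroes beta1 and beta2; ``nonmonotone`` uses a downturned parabola
    (beta0 = 10, beta1 = 9.5e-5, beta2 = -3e-9). Everything else is shared.
    """
    base = base_case_params()
    if name == "quadratic":
        return base
    if name == "linear":
        return replace(base, beta2=0.0)
    if name == "constant":
        return replace(base, beta1=0.0, beta2=0.0)
    if name == "nonmonotone":
        return replace(base, beta0=10.0, beta1=9.5e-5, beta2=-3e-9)
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")


def _week_start_days(year: int, week: int) -> int:
    return (_dt.date.fromisocalendar(year, week, 1) - _EPOCH).days


def sample_peaks(
    grid: pd.DataFrame, params: ScenarioParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the random seasonal peaks for every ISO year covered by ``grid``.

    For each year and each season independently: a Bernoulli draw with the
    law's probability decides occurrence; the location is continuous uniform
    over the day span of the season's ISO-week window (Monday of ``week_lo``
    through the end of ``week_hi``); width and height are uniform within the
    law's bounds. At most one peak per season per year.

    Returns a DataFrame with columns ``season, year, location, width, height``
    (location and width in days on the ``t_days`` timeline).
    """
    if grid.empty:
        raise ValueError("grid must be nonempty")
    rows = []
    for year in sorted(grid["iso_year"].unique()):
        for season in ("winter", "summer"):
            law: PeakLaw = getattr(params, season)
            if rng.random() >= law.probability:
                continue
            lo = _week_start_days(int(year), law.week_lo)
            hi = _week_start_days(int(year), law.week_hi) + 7  # end of week_hi
            rows.append(
                (
                    season,
                    int(year),
                    rng.uniform(lo, hi),
                    rng.uniform(law.width_min, law.width_max),
                    rng.uniform(law.height_min, law.height_max),
                )
            )
    return pd.DataFrame(
        rows, columns=["season", "year", "location", "width", "height"]
    )


def mean_curve(
    grid: pd.DataFrame, params: ScenarioParams, peaks: pd.DataFrame | None = None
) -> np.ndarray:
    """Expected weekly deaths mu_t on the grid (trend + seasonality + peaks).

    Each peak contributes ``h * gamma^2 / ((x - loc)^2 + gamma^2)`` to the
    log-mean over the *whole* timeline (x = t_days), i.e. a Cauchy density
    rescaled to equal the sampled height at its mode.
    """
    t = grid["t_days"].to_numpy(dtype=float)
    w = grid["w"].to_numpy(dtype=float)
    log_mu = (
        params.beta0
        + params.beta1 * t
        + params.beta2 * t**2
        + params.A * np.cos(2.0 * np.pi * w + params.phi)
    )
    if peaks is not None and len(peaks):
        loc = peaks["location"].to_numpy(dtype=float)
        gam = peaks["width"].to_numpy(dtype=float)
        h = peaks["height"].to_numpy(dtype=float)
        log_mu = log_mu + (
            h * gam**2 / ((t[:, None] - loc) ** 2 + gam**2)
        ).sum(axis=1)
    mu = np.exp(log_mu)
    if not np.all(np.isfinite(mu)):
        raise ArithmeticError("non-finite expected counts in mean curve")
    return mu


def simulate(
    grid: pd.DataFrame, params: ScenarioParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate one weekly series: grid columns plus true ``mu`` and ``deaths``.

    Counts are independent NegBin(mu_t, size) draws. The realized peaks are
    attached as ``result.attrs["peaks"]`` (ground truth for tests and
    diagnostics).
    """
    peaks = sample_peaks(grid, params, rng)
    mu = mean_curve(grid, params, peaks)
    p = params.size / (params.size + mu)
    deaths = rng.negative_binomial(params.size, p)
    out = grid.copy()
    out["mu"] = mu
    out["deaths"] = deaths.astype(np.int64)
    out.attrs["peaks"] = peaks
    return out


def simulate_scenario(
    scenario: str,
    seed: int,
    start_year: int = 2000,
    end_year: int = 2023,
) -> pd.DataFrame:
    """Convenience wrapper: grid + scenario constants + fresh seeded RNG."""
    grid = build_week_grid(start_year, end_year)
    return simulate(grid, scenario_params(scenario), np.random.default_rng(seed))
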
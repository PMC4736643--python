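"""The five fitting methods compared by this package.

Given interval counts from a feeding trial, a parametric retention-time
distribution can be fitted by

* treating an interval bound as if it were the exact retention time of
  every propagule in the interval — methods ``lower``, ``mid`` and
  ``upper`` (plain maximum likelihood on the expanded points); or
* working with the cumulative distribution of the censored data — either
  the interval-censored maximum likelihood ``cd_ml`` (each interval
  contributes count x log[F(upper) - F(lower)], plus a survival term for
  the right-censored remainder) or non-linear least squares ``cd_nls``
  fitted to the empirical cumulative proportions at the interval upper
  bounds.

Bound-based methods ignore the censoring and are the benchmark's
"what practitioners commonly do"; the cumulative-distribution methods
account for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .distributions import FAMILIES, RetentionDistribution
from .sampling import CensoredSample

__all__ = [
    "METHODS",
    "BOUND_METHODS",
    "CD_METHODS",
    "FitResult",
    "expand_to_points",
    "fit_bound_ml",
    "censored_nll",
    "fit_cd_ml",
    "empirical_cumulative",
    "fit_cd_nls",
    "fit",
]

BOUND_METHODS = ("lower", "mid", "upper")
CD_METHODS = ("cd_ml", "cd_nls")
METHODS = BOUND_METHODS + CD_METHODS

#: Floor substituted for the zero lower bound of the first interval when
#: expanding to points (log-densities are undefined at 0 for some shapes).
ZERO_FLOOR_H = 0.01

_MAXITER = 500


@dataclass(frozen=True)
class FitResult:
    """Outcome of one fit: estimates, objective and an honest convergence flag.

    ``objective`` is the final negative log-likelihood (ML methods) or the
    residual sum of squares (``cd_nls``).  Unconverged fits carry NaN
    estimates; they are reported, never raised.
    """

    family: str
    method: str
    mu_hat: float
    sigma_hat: float
    objective: float
    converged: bool
    n_used: int
    message: str = ""


def _failure(family: str, method: str, n_used: int, message: str) -> FitResult:
    return FitResult(family, method, np.nan, np.nan, np.nan, False, n_used, message)


def expand_to_points(sample: CensoredSample, bound: str, zero_floor: float = ZERO_FLOOR_H) -> np.ndarray:
    """Expand interval counts to point data at the chosen interval bound.

    Each interval contributes ``count`` copies of its lower, mid or upper
    bound; the zero lower bound of the first interval is floored at
    ``zero_floor`` hours; right-censored propagules are dropped (bound
    methods have no point to place them at).
    """
    if bound not in BOUND_METHODS:
        raise ValueError(f"bound must be one of {BOUND_METHODS}")
    if bound == "lower":
        values = sample.lower.copy()
        values[values <= 0] = zero_floor
    elif bound == "mid":
        values = 0.5 * (sample.lower + sample.upper)
    else:
        values = sample.upper.copy()
    return np.repeat(values, sample.counts)


def _points_nll(family: str, mu: float, sigma: float, points: np.ndarray) -> float:
    dist = RetentionDistribution(family, mu, sigma)
    with np.errstate(divide="ignore"):
        logpdf = dist.frozen.logpdf(points)
    if not np.all(np.isfinite(logpdf)):
        return np.inf
    return float(-np.sum(logpdf))


def fit_bound_ml(sample: CensoredSample, family: str, bound: str,
                 zero_floor: float = ZERO_FLOOR_H) -> FitResult:
    """Maximum-likelihood fit to interval-bound point data.

    Lognormal estimates are closed form (mean and population sd of log
    times); gamma and Weibull use scipy's constrained ML solvers with the
    location pinned at zero.
    """
    points = expand_to_points(sample, bound, zero_floor)
    n = len(points)
    if np.unique(points).size < 2:
        return _failure(family, bound, n, "fewer than 2 distinct time points")
    try:
        if family == "lognormal":
            logs = np.log(points)
            mu_hat = float(np.mean(logs))
            sigma_hat = float(np.std(logs))  # population sd: the ML estimate
        elif family == "gamma":
            shape, _, scale = stats.gamma.fit(points, floc=0)
            mu_hat, sigma_hat = float(shape), float(1.0 / scale)
        elif family == "weibull":
            shape, _, scale = stats.weibull_min.fit(points, floc=0)
            mu_hat, sigma_hat = float(shape), float(scale)
        else:
            raise ValueError(f"unknown family {family!r}")
    except Exception as exc:  # scipy fit can fail on pathological data
        return _failure(family, bound, n, f"ML fit failed: {exc}")
    if not (np.isfinite(mu_hat) and np.isfinite(sigma_hat)) or sigma_hat <= 0 or mu_hat <= 0 and family != "lognormal":
        return _failure(family, bound, n, "estimate outside the parameter space")
    objective = _points_nll(family, mu_hat, sigma_hat, points)
    if not np.isfinite(objective):
        return _failure(family, bound, n, "non-finite likelihood at the estimate")
    return FitResult(family, bound, mu_hat, sigma_hat, objective, True, n)


def censored_nll(params, sample: CensoredSample, family: str) -> float:
    """Interval-censored negative log-likelihood.

    Sum over intervals of count x log[F(upper) - F(lower)] plus
    right_censored x log[1 - F(horizon)], negated.  Returns +inf whenever a
    cell with positive count has zero probability (or the parameters fall
    outside the family's space), so optimizers can retreat.
    """
    mu, sigma = params
    try:
        dist = RetentionDistribution(family, float(mu), float(sigma))
    except ValueError:
        return np.inf
    bp = sample.breakpoints
    cdf = dist.frozen.cdf(np.clip(bp, 0.0, None))
    probs = np.diff(cdf)
    ll = 0.0
    observed = sample.counts > 0
    if np.any(probs[observed] <= 0):
        return np.inf
    ll += float(np.sum(sample.counts[observed] * np.log(probs[observed])))
    if sample.right_censored > 0:
        survival = 1.0 - cdf[-1]
        if survival <= 0:
            return np.inf
        ll += sample.right_censored * np.log(survival)
    return -ll


def _moment_start(sample: CensoredSample, family: str) -> tuple:
    """Moment-style initial values from mid-expanded points."""
    points = expand_to_points(sample, "mid")
    if points.size == 0:
        raise ValueError("sample has no retrieved propagules")
    m = float(np.mean(points))
    s = float(np.std(points))
    s = max(s, 1e-3)
    if family == "lognormal":
        logs = np.log(points)
        return float(np.mean(logs)), max(float(np.std(logs)), 1e-3)
    if family == "gamma":
        shape = max((m / s) ** 2, 1e-2)
        rate = max(m / s**2, 1e-4)
        return shape, rate
    # Weibull: standard CV-based approximation for the shape
    shape = float(np.clip((s / m) ** -1.086, 0.1, 50.0))
    scale = m / special.gamma(1.0 + 1.0 / shape)
    return shape, float(scale)


def _to_internal(family: str, mu: float, sigma: float) -> np.ndarray:
    # positivity enforced by optimizing on log scale (lognormal mu is free)
    if family == "lognormal":
        return np.array([mu, np.log(sigma)])
    return np.array([np.log(mu), np.log(sigma)])


def _from_internal(family: str, x: np.ndarray) -> tuple:
    if family == "lognormal":
        return float(x[0]), float(np.exp(x[1]))
    return float(np.exp(x[0])), float(np.exp(x[1]))


def fit_cd_ml(sample: CensoredSample, family: str) -> FitResult:
    """Interval-censored maximum-likelihood fit (CD-ML).

    Minimizes :func:`censored_nll` by Nelder-Mead on log-scale parameters,
    started from moment estimates on mid-expanded points.  Deterministic.
    """
    n = sample.n_total
    if int(np.sum(sample.counts > 0)) < 2:
        return _failure(family, "cd_ml", n, "fewer than 2 informative intervals")
    try:
        start = _moment_start(sample, family)
    except ValueError as exc:
        return _failure(family, "cd_ml", n, str(exc))

    # optimize the per-propagule NLL so the objective tolerance is relative
    def objective(x):
        mu, sigma = _from_internal(family, x)
        return censored_nll((mu, sigma), sample, family) / n

    res = optimize.minimize(
        objective, _to_internal(family, *start), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": _MAXITER, "maxfev": 4 * _MAXITER},
    )
    mu_hat, sigma_hat = _from_internal(family, res.x)
    if not res.success or not np.isfinite(res.fun):
        return _failure(family, "cd_ml", n, f"optimizer did not converge: {res.message}")
    nll = censored_nll((mu_hat, sigma_hat), sample, family)
    return FitResult(family, "cd_ml", mu_hat, sigma_hat, float(nll), True, n)


def empirical_cumulative(sample: CensoredSample) -> tuple:
    """Empirical cumulative proportions at the interval upper bounds.

    One point per interval; proportions are running count sums divided by
    the total fed (right-censored mass keeps the last point below 1).
    """
    if sample.n_total < 1:
        raise ValueError("sample must contain at least one propagule")
    uppers = sample.upper.copy()
    props = np.cumsum(sample.counts) / sample.n_total
    return uppers, props


def fit_cd_nls(sample: CensoredSample, family: str) -> FitResult:
    """Non-linear least squares fit to the empirical cumulative distribution
    (CD-NLS): minimizes sum_i (p_i - F(u_i; mu, sigma))^2.

    Needs at least 3 cumulative points; may genuinely fail to converge for
    low-variance samples, which is reported via ``converged``.
    """
    n = sample.n_total
    uppers, props = empirical_cumulative(sample)
    if len(uppers) < 3:
        return _failure(family, "cd_nls", n, "fewer than 3 cumulative points")
    try:
        start = _moment_start(sample, family)
    except ValueError as exc:
        return _failure(family, "cd_nls", n, str(exc))

    def residuals(x):
        mu, sigma = _from_internal(family, x)
        try:
            dist = RetentionDistribution(family, mu, sigma)
        except ValueError:
            return np.full_like(props, 1e6)
        return props - dist.frozen.cdf(uppers)

    try:
        res = optimize.least_squares(
            residuals, _to_internal(family, *start), method="lm",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=100 * _MAXITER,
        )
    except Exception as exc:
        return _failure(family, "cd_nls", n, f"least squares failed: {exc}")
    mu_hat, sigma_hat = _from_internal(family, res.x)
    rss = float(2.0 * res.cost)
    # runaway log-scale parameters signal a flat, unidentified objective
    if not res.success or not np.isfinite(rss) or np.any(np.abs(res.x) > 20):
        return _failure(family, "cd_nls", n, f"did not converge: {res.message}")
    return FitResult(family, "cd_nls", mu_hat, sigma_hat, rss, True, n)


def fit(sample: CensoredSample, family: str, method: str) -> FitResult:
    """Dispatch to one of the five fitting methods."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if method in BOUND_METHODS:
        return fit_bound_ml(sample, family, method)
    if method == "cd_ml":
        return fit_cd_ml(sample, family)
    if method == "cd_nls":
        return fit_cd_nls(sample, family)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
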
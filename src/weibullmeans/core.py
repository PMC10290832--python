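"""Weibull point estimation and common-mean pooling.

This module carries the shared substrate of every interval method in the
package: two-parameter Weibull maximum-likelihood fits, the distribution
mean ``c * gamma(1 + 1/k)`` and its delta-method variance, inverse-variance
pooling of several per-group mean estimates into a single common-mean
estimate, and an AIC screen that compares the Weibull fit against five
rival families.

Parametrization
---------------
Throughout, ``c`` is the scale (same units as the data) and ``k`` the
dimensionless shape of the density

    f(x; c, k) = (k / c) * (x / c)**(k - 1) * exp(-(x / c)**k),  x > 0.

The shape MLE solves the profile score

    1/k - sum(x**k * log x) / sum(x**k) + mean(log x) = 0,

which is strictly decreasing in ``k`` for non-degenerate data, so a
bracketed root finder cannot miss it; the scale then follows in closed
form as ``(mean(x**k))**(1/k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "EstimationError",
    "ObservedSample",
    "WeibullFit",
    "MeanEstimate",
    "CommonMeanEstimate",
    "CandidateFitRow",
    "Interval",
    "fit_weibull_mle",
    "fit_weibull_shape_many",
    "weibull_mean",
    "weibull_loglik",
    "profile_score",
    "observed_information",
    "expected_information",
    "delta_variance",
    "delta_variance_at",
    "mean_estimate",
    "pool_common_mean",
    "compare_distributions",
]

_EULER = np.euler_gamma


class EstimationError(RuntimeError):
    """A maximum-likelihood fit could not be completed."""


@dataclass(frozen=True)
class ObservedSample:
    """One group of strictly positive observations.

    Parameters
    ----------
    group_id : str
        Label of the group (e.g. a measurement site).
    values : ndarray
        The observations; every value must be > 0 and at least two are
        required.
    """

    group_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError(
                f"group {self.group_id!r}: need at least 2 observations in a "
                f"1-d array, got shape {values.shape}"
            )
        if not np.all(values > 0):
            raise ValueError(f"group {self.group_id!r}: all values must be > 0")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class WeibullFit:
    """Maximum-likelihood estimates for one group."""

    c_hat: float
    k_hat: float
    n: int
    loglik: float


@dataclass(frozen=True)
class MeanEstimate:
    """A group's mean estimate with its delta-method variance.

    ``info_inverse`` is the inverse observed information in ``(k, c)``
    ordering, i.e. ``[[var(k_hat), cov], [cov, var(c_hat)]]``.
    """

    mu_hat: float
    var_hat: float
    info_inverse: np.ndarray


@dataclass(frozen=True)
class CommonMeanEstimate:
    """Inverse-variance-weighted pooled mean over ``p`` groups."""

    mu_pooled: float
    weights: np.ndarray
    p: int


@dataclass(frozen=True)
class CandidateFitRow:
    """One family's maximum-likelihood fit in the AIC comparison."""

    family: str
    n_params: int
    loglik: float
    aic: float
    ok: bool = True


@dataclass(frozen=True)
class Interval:
    """A two-sided confidence or credible interval."""

    lower: float
    upper: float
    level: float
    method: str
    length: float = field(init=False)

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval lower bound exceeds upper bound")
        object.__setattr__(self, "length", self.upper - self.lower)

    def contains(self, value: float) -> bool:
        """Closed-interval membership, ``lower <= value <= upper``."""
        return self.lower <= value <= self.upper


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

def profile_score(k: float, values: np.ndarray) -> float:
    """Profile score for the shape parameter; zero at the MLE."""
    xk = values ** k
    return 1.0 / k - np.sum(xk * np.log(values)) / np.sum(xk) + np.mean(np.log(values))


def weibull_loglik(values: np.ndarray, c: float, k: float) -> float:
    """Log-likelihood of a Weibull(c, k) sample."""
    n = values.size
    return float(
        n * np.log(k)
        - n * k * np.log(c)
        + (k - 1.0) * np.sum(np.log(values))
        - np.sum((values / c) ** k)
    )


def _shape_start(log_values: np.ndarray) -> float:
    sd = np.std(log_values)
    # moment-style start; the log of a Weibull has sd = pi/(k*sqrt(6)) ~ 1.28/k
    return 1.2 / sd if sd > 0 else 1.0


def fit_weibull_mle(sample: ObservedSample, xtol: float = 1e-10) -> WeibullFit:
    """Fit Weibull scale and shape by maximum likelihood.

    The shape solves the profile score with ``brentq`` on the bracket
    ``[k0/100, 100*k0]`` around a moment-style start ``k0``; the scale is
    then exact given the shape.

    Raises
    ------
    EstimationError
        If the data are all identical (the shape MLE diverges) or the
        score cannot be bracketed.
    """
    x = sample.values
    if np.all(x == x[0]):
        raise EstimationError(
            f"group {sample.group_id!r}: all observations identical, "
            "shape MLE diverges"
        )
    # the shape MLE is invariant to rescaling; dividing by the maximum keeps
    # x**k bounded by 1 over the whole bracket (the max itself contributes 1
    # to sum(x**k), so no division by zero either)
    x_max = x.max()
    y = x / x_max
    k0 = _shape_start(np.log(y))
    lo, hi = k0 / 100.0, k0 * 100.0
    try:
        if profile_score(lo, y) * profile_score(hi, y) > 0:
            raise ValueError("score not bracketed")
        k_hat = optimize.brentq(profile_score, lo, hi, args=(y,), xtol=xtol)
    except (ValueError, RuntimeError) as exc:
        raise EstimationError(
            f"group {sample.group_id!r}: shape root finding failed ({exc})"
        ) from exc
    c_hat = float(x_max * np.mean(y ** k_hat) ** (1.0 / k_hat))
    return WeibullFit(
        c_hat=c_hat,
        k_hat=float(k_hat),
        n=sample.n,
        loglik=weibull_loglik(x, c_hat, k_hat),
    )


def fit_weibull_shape_many(
    X: np.ndarray, tol: float = 1e-10, maxit: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Weibull MLEs for a batch of samples.

    Safeguarded Newton iteration on the profile score, vectorized over the
    rows of ``X``; used on simulation hot paths where thousands of small
    samples are refit per interval.  The score is strictly decreasing with
    negative derivative everywhere, so plain Newton from the moment-style
    start converges quadratically; steps to a non-positive shape are
    replaced by halving.  Rows that fail to converge are re-solved with the
    scalar bracketed fitter.

    Returns
    -------
    (k, c) : pair of ndarray
        Shape and scale MLEs per row.
    """
    X = np.asarray(X, dtype=float)
    x_max = X.max(axis=1, keepdims=True)
    X = X / x_max  # shape is scale invariant; keeps X**k bounded
    lx = np.log(X)
    mlx = lx.mean(axis=1)
    sd = lx.std(axis=1)
    k = np.where(sd > 0, 1.2 / np.where(sd > 0, sd, 1.0), 1.0)
    converged = np.zeros(X.shape[0], dtype=bool)
    for _ in range(maxit):
        xk = X ** k[:, None]
        s0 = xk.sum(axis=1)
        s1 = (xk * lx).sum(axis=1)
        s2 = (xk * lx * lx).sum(axis=1)
        f = 1.0 / k - s1 / s0 + mlx
        fp = -1.0 / k ** 2 - (s2 * s0 - s1 ** 2) / s0 ** 2
        step = f / fp
        k_new = np.where(k - step > 0, k - step, k / 2.0)
        converged = np.abs(k_new - k) < tol * np.maximum(k, 1.0)
        k = k_new
        if converged.all():
            break
    if not converged.all():
        for i in np.flatnonzero(~converged):
            fit = fit_weibull_mle(ObservedSample(f"row{i}", X[i]))
            k[i] = fit.k_hat
    c = x_max[:, 0] * np.mean(X ** k[:, None], axis=1) ** (1.0 / k)
    return k, c


def weibull_mean(c, k):
    """Mean of a Weibull(c, k) distribution, ``c * gamma(1 + 1/k)``."""
    c = np.asarray(c, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(c <= 0) or np.any(k <= 0):
        raise ValueError("scale and shape must be positive")
    out = c * special.gamma(1.0 + 1.0 / k)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# information and the delta method
# ---------------------------------------------------------------------------

def observed_information(fit: WeibullFit, sample: ObservedSample) -> np.ndarray:
    """Observed information: negative Hessian of the log-likelihood.

    Evaluated analytically at the MLE, in ``(k, c)`` ordering.  Its inverse
    estimates the covariance of ``(k_hat, c_hat)``.
    """
    x = sample.values
    c, k = fit.c_hat, fit.k_hat
    n = sample.n
    z = x / c
    zk = z ** k
    lz = np.log(z)
    i_kk = n / k ** 2 + np.sum(zk * lz ** 2)
    i_cc = -n * k / c ** 2 + k * (k + 1.0) / c ** 2 * np.sum(zk)
    i_kc = n / c - np.sum(zk) / c - k / c * np.sum(zk * lz)
    info = np.array([[i_kk, i_kc], [i_kc, i_cc]])
    if np.linalg.det(info) <= 0:
        raise EstimationError(
            f"group {sample.group_id!r}: observed information not positive "
            "definite"
        )
    return info


def expected_information(c, k, n):
    """Expected (Fisher) information of a Weibull(c, k) sample of size n.

    Closed form in ``(k, c)`` ordering, vectorized over ``c`` and ``k``:

        I_kk = n * ((1 - g)**2 + pi**2/6) / k**2
        I_cc = n * k**2 / c**2
        I_kc = -n * (1 - g) / c

    with ``g`` the Euler-Mascheroni constant.  Unlike the observed
    information it is positive definite at any parameter point, which makes
    it the right plug-in when the delta-method variance must be evaluated
    away from the MLE (pivotal or posterior draws).
    """
    c = np.asarray(c, dtype=float)
    k = np.asarray(k, dtype=float)
    i_kk = n * ((1.0 - _EULER) ** 2 + np.pi ** 2 / 6.0) / k ** 2
    i_cc = n * k ** 2 / c ** 2
    i_kc = -n * (1.0 - _EULER) / c
    return np.stack(
        [np.stack([i_kk, i_kc], axis=-1), np.stack([i_kc, i_cc], axis=-1)],
        axis=-2,
    )


def _mean_gradient(c, k):
    """Partials of the Weibull mean in ``(k, c)`` ordering (analytic)."""
    g = special.gamma(1.0 + 1.0 / k)
    d_k = -(c / k ** 2) * g * special.digamma(1.0 + 1.0 / k)
    d_c = g
    return d_k, d_c


def delta_variance(fit: WeibullFit, info_inverse: np.ndarray) -> float:
    """First-order (delta-method) variance of the estimated mean.

    ``var(k)*dmu_dk**2 + 2*cov*dmu_dk*dmu_dc + var(c)*dmu_dc**2`` with the
    analytic partials ``dmu_dc = gamma(1 + 1/k)`` and
    ``dmu_dk = -(c/k**2) * gamma(1 + 1/k) * digamma(1 + 1/k)``.
    """
    d_k, d_c = _mean_gradient(fit.c_hat, fit.k_hat)
    grad = np.array([d_k, d_c])
    return float(grad @ info_inverse @ grad)


def delta_variance_at(c, k, n):
    """Delta-method variance of the mean at arbitrary ``(c, k)``.

    Uses the closed-form expected information, so it is defined (and
    positive) at any parameter point and vectorizes over draws.
    """
    c = np.asarray(c, dtype=float)
    k = np.asarray(k, dtype=float)
    coeff = (1.0 - _EULER) ** 2 + np.pi ** 2 / 6.0
    det = (np.pi ** 2 / 6.0) * n ** 2 / c ** 2
    var_k = (n * k ** 2 / c ** 2) / det
    var_c = (n * coeff / k ** 2) / det
    cov = (n * (1.0 - _EULER) / c) / det
    d_k, d_c = _mean_gradient(c, k)
    out = var_k * d_k ** 2 + 2.0 * cov * d_k * d_c + var_c * d_c ** 2
    return float(out) if np.ndim(out) == 0 else out


def mean_estimate(sample: ObservedSample, fit: WeibullFit | None = None) -> MeanEstimate:
    """Mean estimate and delta-method variance for one group."""
    if fit is None:
        fit = fit_weibull_mle(sample)
    info = observed_information(fit, sample)
    info_inverse = np.linalg.inv(info)
    mu_hat = weibull_mean(fit.c_hat, fit.k_hat)
    var_hat = delta_variance(fit, info_inverse)
    if var_hat <= 0:
        raise EstimationError(
            f"group {sample.group_id!r}: non-positive delta-method variance"
        )
    return MeanEstimate(mu_hat=mu_hat, var_hat=var_hat, info_inverse=info_inverse)


def pool_common_mean(estimates: Sequence[MeanEstimate]) -> CommonMeanEstimate:
    """Inverse-variance-weighted pooled common mean.

    ``mu = sum(mu_i / var_i) / sum(1 / var_i)``; a convex combination of
    the group means.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one mean estimate to pool")
    mus = np.array([e.mu_hat for e in estimates])
    variances = np.array([e.var_hat for e in estimates])
    if np.any(variances <= 0):
        raise ValueError("all variances must be positive")
    w = 1.0 / variances
    w = w / w.sum()
    return CommonMeanEstimate(
        mu_pooled=float(np.sum(w * mus)), weights=w, p=len(estimates)
    )


# ---------------------------------------------------------------------------
# AIC distribution comparison
# ---------------------------------------------------------------------------

def _loglik_weibull(x):
    return fit_weibull_mle(ObservedSample("aic", x)).loglik


def _loglik_gamma(x):
    a, _, scale = stats.gamma.fit(x, floc=0)
    return float(np.sum(stats.gamma.logpdf(x, a, 0, scale)))


def _loglik_lognormal(x):
    m = np.mean(np.log(x))
    s = np.std(np.log(x))  # MLE, not ddof=1
    return float(np.sum(stats.lognorm.logpdf(x, s, 0, np.exp(m))))


def _loglik_normal(x):
    return float(np.sum(stats.norm.logpdf(x, np.mean(x), np.std(x))))


def _loglik_exponential(x):
    # MLE rate 1/xbar: loglik = -n*(log(xbar) + 1)
    return float(-x.size * (np.log(np.mean(x)) + 1.0))


def _loglik_cauchy(x):
    loc, scale = stats.cauchy.fit(x)
    return float(np.sum(stats.cauchy.logpdf(x, loc, scale)))


_FAMILIES: dict[str, tuple[int, object]] = {
    "weibull": (2, _loglik_weibull),
    "gamma": (2, _loglik_gamma),
    "lognormal": (2, _loglik_lognormal),
    "normal": (2, _loglik_normal),
    "exponential": (1, _loglik_exponential),
    "cauchy": (2, _loglik_cauchy),
}


def compare_distributions(sample: ObservedSample) -> list[CandidateFitRow]:
    """Fit six candidate families by ML and rank them by AIC.

    Families: weibull, gamma, lognormal, normal, exponential, cauchy.
    ``AIC = 2 * n_params - 2 * loglik`` with natural logs.  A family whose
    fit fails is returned flagged (``ok=False``) and sorts last.
    """
    x = sample.values
    rows: list[CandidateFitRow] = []
    for family, (n_params, loglik_fn) in _FAMILIES.items():
        try:
            loglik = loglik_fn(x)
            rows.append(
                CandidateFitRow(
                    family=family, n_params=n_params, loglik=loglik,
                    aic=2.0 * n_params - 2.0 * loglik,
                )
            )
        except Exception:
            rows.append(
                CandidateFitRow(
                    family=family, n_params=n_params, loglik=np.nan,
                    aic=np.inf, ok=False,
                )
            )
    rows.sort(key=lambda r: (not r.ok, r.aic))
    return rows
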
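"""Meal criterion: mixture modelling of log intermeal intervals.

Closed-door gaps between feeding events are strongly right-skewed and, on
the natural-log scale, cluster into within-meal pauses, drink pauses and
true between-meal intervals.  Fitting a K-component Gaussian mixture to
``ln(duration in seconds)`` and intersecting the densities of the two
rightmost components yields the minimum intermeal interval (MII): the
shortest closed gap that separates two distinct meals.

The intersection uses unit-mass (unweighted) component densities.  With
means mu1 < mu2 and unequal SDs, equating the two normal log-densities
gives a quadratic in x whose root inside (mu1, mu2) is the criterion C;
``exp(C) / 60`` converts it to minutes.  When the SDs coincide the
quadratic degenerates and the midpoint (mu1 + mu2)/2 is the limit.

Intervals shorter than 2 min are excluded before fitting: at a 30-s epoch
the short-pause regime is undersampled and would otherwise dominate the
left tail.

The EM implementation is univariate and deliberately small: quantile-based
initial means, pooled initial SD, uniform weights, multiple jittered
restarts, and a hard assertion that the log-likelihood never decreases
between iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, DataError, FitError, InsufficientDataError

_SIGMA_FLOOR = 1e-6
_EQUAL_SIGMA_TOL = 1e-9


@dataclass
class LogIntervalVector:
    """Natural-log interval durations surviving the short-interval filter."""

    values: np.ndarray
    n_excluded_short: int
    min_interval_s: float

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class MixtureModel:
    """A fitted K-component univariate Gaussian mixture on the log-second scale.

    Components are sorted by ascending mean.  ``k_free = 3K - 1`` free
    parameters: K means, K SDs, K - 1 independent weights.
    """

    K: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    minus2LL: float
    n: int
    aicc: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.means = np.asarray(self.means, float)[order]
        self.sds = np.asarray(self.sds, float)[order]
        self.weights = np.asarray(self.weights, float)[order]
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise DataError("mixture weights must be positive and sum to 1")
        if np.any(self.sds <= 0):
            raise DataError("mixture SDs must be positive")
        _, self.aicc, self.bic = information_criteria(self.minus2LL, self.k_free, self.n)

    @property
    def k_free(self) -> int:
        return 3 * self.K - 1

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        comp = norm.logpdf(
            np.asarray(x, float)[:, None], self.means[None, :], self.sds[None, :]
        ) + np.log(self.weights[None, :])
        from scipy.special import logsumexp

        return logsumexp(comp, axis=1)


@dataclass
class MealCriterion:
    """The minimum intermeal interval derived from a fitted mixture."""

    C: float  # intersection point, log-seconds
    mii_minutes: float
    source_components: tuple[int, int]


def prepare_intervals(
    intervals, min_interval_s: float = 120.0, min_n: int = 50
) -> LogIntervalVector:
    """Log-transform interval durations, dropping those below the cutoff.

    ``intervals`` may be a sequence of durations in seconds or a frame with
    a ``duration_s`` column.  Fewer than ``min_n`` survivors raises
    :class:`InsufficientDataError` (a mixture fit would be unstable).
    """
    if isinstance(intervals, pd.DataFrame):
        durations = intervals["duration_s"].to_numpy(float)
    else:
        durations = np.asarray(intervals, dtype=float)
    if np.any(durations <= 0):
        raise DataError("interval durations must be positive")
    keep = durations >= min_interval_s
    n_excluded = int(np.count_nonzero(~keep))
    values = np.log(durations[keep])
    if len(values) < min_n:
        raise InsufficientDataError(
            f"only {len(values)} intervals survive the {min_interval_s:g}-s filter "
            f"(need >= {min_n})"
        )
    return LogIntervalVector(
        values=values, n_excluded_short=n_excluded, min_interval_s=min_interval_s
    )


def information_criteria(minus2ll: float, k_free: int, n: int) -> tuple[float, float, float]:
    """Small-sample-corrected AIC and BIC from -2 log-likelihood.

    AICc = -2LL + 2k + 2k(k+1)/(n-k-1);  BIC = -2LL + k ln(n).
    """
    if n <= k_free + 1:
        raise DataError(f"AICc undefined for n={n} with k={k_free} free parameters")
    aicc = minus2ll + 2 * k_free + 2 * k_free * (k_free + 1) / (n - k_free - 1)
    bic = minus2ll + k_free * np.log(n)
    return minus2ll, aicc, bic


def _em_once(
    x: np.ndarray,
    K: int,
    means0: np.ndarray,
    sds0: np.ndarray,
    weights0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One EM run; returns (weights, means, sds, loglik) or raises FitError
    on a degenerate (collapsing) component."""
    from scipy.special import logsumexp

    n = len(x)
    w, mu, sd = weights0.copy(), means0.copy(), sds0.copy()
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_comp = norm.logpdf(x[:, None], mu[None, :], sd[None, :]) + np.log(w[None, :])
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        # EM guarantee: monotone ascent (tiny float slack only)
        if ll < prev_ll - 1e-7:
            raise FitError(f"log-likelihood decreased ({prev_ll} -> {ll})")
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise FitError("component weight collapsed to zero")
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        if np.any(sd < _SIGMA_FLOOR):
            raise FitError("component SD collapsed toward zero")
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
    return w, mu, sd, prev_ll


def fit_mixture(
    data: LogIntervalVector | np.ndarray,
    K: int,
    n_restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureModel:
    """Maximum-likelihood K-component Gaussian mixture via EM.

    The first start uses quantile-based means (the (i + 1/2)/K quantiles),
    the pooled SD and uniform weights; remaining restarts jitter the means.
    The best run by likelihood wins.  K = 1 reduces to the closed-form
    sample mean and MLE standard deviation.
    """
    x = data.values if isinstance(data, LogIntervalVector) else np.asarray(data, float)
    n = len(x)
    if K < 1:
        raise ConfigError("K must be >= 1")
    k_free = 3 * K - 1
    if n <= 10 * k_free:
        raise InsufficientDataError(f"n={n} too small for K={K} (need > {10 * k_free})")

    if K == 1:
        mu, sd = float(np.mean(x)), float(np.std(x))
        ll = float(norm.logpdf(x, mu, sd).sum())
        return MixtureModel(
            K=1, weights=np.array([1.0]), means=np.array([mu]),
            sds=np.array([sd]), minus2LL=-2 * ll, n=n,
        )

    rng = np.random.default_rng(seed)
    pooled_sd = float(np.std(x))
    q_means = np.quantile(x, (np.arange(K) + 0.5) / K)
    best = None
    for r in range(max(1, n_restarts)):
        means0 = q_means if r == 0 else q_means + rng.normal(0, 0.5 * pooled_sd, size=K)
        try:
            w, mu, sd, ll = _em_once(
                x, K, np.sort(means0), np.full(K, pooled_sd), np.full(K, 1.0 / K),
                max_iter, tol,
            )
        except FitError:
            continue  # degenerate run; try the next restart
        if best is None or ll > best[3]:
            best = (w, mu, sd, ll)
    if best is None:
        raise FitError(f"all {n_restarts} EM restarts degenerated for K={K}")
    w, mu, sd, ll = best
    return MixtureModel(K=K, weights=w, means=mu, sds=sd, minus2LL=-2 * ll, n=n)


def select_model(models: list[MixtureModel], rule: str = "bic") -> MixtureModel:
    """Pick the candidate with the lowest value of the chosen criterion.

    All candidates must have been fitted on the same data (same n).  Ties
    go to the earliest candidate in construction order.
    """
    if len(models) < 2:
        raise ConfigError("model selection needs at least 2 candidates")
    ns = {m.n for m in models}
    if len(ns) != 1:
        raise DataError(f"candidates fitted on different n: {sorted(ns)}")
    key = {"bic": lambda m: m.bic, "aicc": lambda m: m.aicc, "m2ll": lambda m: m.minus2LL}
    if rule not in key:
        raise ConfigError(f"unknown selection rule {rule!r} (use bic|aicc|m2ll)")
    crit = [key[rule](m) for m in models]
    return models[int(np.argmin(crit))]


def intersection_point(mu1: float, sigma1: float, mu2: float, sigma2: float) -> float:
    """Crossing point of two unit-mass normal densities, between the means.

    Solves ``N(x; mu1, sigma1) = N(x; mu2, sigma2)`` by equating
    log-densities, a quadratic in x; the root inside (mu1, mu2) is
    returned.  Requires mu1 < mu2.  With |sigma1 - sigma2| below 1e-9 the
    quadratic degenerates to a line and the limit is the midpoint.
    """
    if not (sigma1 > 0 and sigma2 > 0):
        raise ConfigError("sigmas must be positive")
    if not mu1 < mu2:
        raise ConfigError(f"mu1 must be < mu2 (got {mu1} >= {mu2})")
    if abs(sigma1 - sigma2) < _EQUAL_SIGMA_TOL:
        return 0.5 * (mu1 + mu2)
    v1, v2 = sigma1**2, sigma2**2
    a = 1.0 / v2 - 1.0 / v1
    b = 2.0 * (mu1 / v1 - mu2 / v2)
    c = mu2**2 / v2 - mu1**2 / v1 - 2.0 * np.log(sigma1 / sigma2)
    disc = b * b - 4 * a * c
    if disc < 0:
        raise DataError("no real density intersection (negative discriminant)")
    roots = ((-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a))
    inside = [r for r in roots if mu1 < r < mu2]
    if not inside:
        raise DataError(f"no density intersection inside ({mu1}, {mu2})")
    C = float(inside[0])
    # contract: the two densities agree at C
    assert abs(norm.pdf(C, mu1, sigma1) - norm.pdf(C, mu2, sigma2)) < 1e-8
    return C


def meal_criterion_from_model(model: MixtureModel, weighted: bool = False) -> MealCriterion:
    """Derive the MII from the two rightmost components of a fitted mixture.

    ``weighted=True`` intersects the weight-scaled densities instead of the
    unit-mass ones (off by default; the standard criterion uses only the
    component means and SDs).
    """
    if model.K < 2:
        raise ConfigError("meal criterion undefined for a single-component model")
    i, j = model.K - 2, model.K - 1
    mu1, s1 = float(model.means[i]), float(model.sds[i])
    mu2, s2 = float(model.means[j]), float(model.sds[j])
    if weighted:
        C = _weighted_intersection(mu1, s1, mu2, s2, float(model.weights[i]), float(model.weights[j]))
    else:
        C = intersection_point(mu1, s1, mu2, s2)
    return MealCriterion(C=C, mii_minutes=float(np.exp(C) / 60.0), source_components=(i, j))


def _weighted_intersection(mu1, s1, mu2, s2, w1, w2) -> float:
    """Crossing of the weight-scaled densities, by bisection on (mu1, mu2)."""
    from scipy.optimize import brentq

    f = lambda x: np.log(w1) + norm.logpdf(x, mu1, s1) - np.log(w2) - norm.logpdf(x, mu2, s2)
    if f(mu1) * f(mu2) > 0:
        raise DataError("weighted densities do not cross between the means")
    return float(brentq(f, mu1, mu2, xtol=1e-12))
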
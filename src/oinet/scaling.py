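"""Two-regime exceedance fitting and log-log scaling relationships.

The exceedance model for a positive scalar Y (RSA, OTE, degree, alpha...)
allows three regimes:

    P(Y >= y) ~ exp(-lambda1 y)          for y <  y_star
               ~ y^(-epsilon + 1) f(y/m)  for y_star <= y < m
               ~ exp(-lambda2 y)          for y >= m

i.e. an exponential bulk, a power-law (Pareto) middle with pdf exponent
epsilon between a lower truncation y_star and an upper cutoff m, and an
exponential finite-size tail.  epsilon = 2 is the classical Zipf law.
The truncation y_star is chosen Clauset-style by scanning candidates and
minimizing the Kolmogorov-Smirnov distance of the tail fit; epsilon is
the truncated-Pareto maximum-likelihood estimate on [y_star, m]; the
power-law regime is only reported when it beats an exponential tail fit
by log-likelihood.  f(y/m) is fixed to the exponential cutoff family.

`ExceedanceModel` and `LogLogScaling` follow the scikit-learn estimator
protocol; `fit_exceedance` / `scaling_fit` are functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .containers import DiversityTrack

__all__ = [
    "ExceedanceFit",
    "ScalingFit",
    "ExceedanceModel",
    "LogLogScaling",
    "fit_exceedance",
    "scaling_fit",
    "gamma_vs_events",
]


@dataclass
class ExceedanceFit:
    lambda1: float
    lambda2: float
    epsilon: float
    y_star: float
    m: float
    regime_flags: tuple[str, ...]
    ks_distance: float
    n_tail: int


@dataclass
class ScalingFit:
    exponent: float
    intercept: float
    r2: float
    x_range: float  # decades spanned by x


def _truncated_pareto_eps(y: np.ndarray, y_star: float, m: float) -> float:
    """ML pdf exponent of a Pareto truncated to [y_star, m]."""
    logs = np.log(y / y_star)
    mean_log = logs.mean()
    ratio = m / y_star
    if ratio <= 1 + 1e-12:
        return np.inf

    def neg_ll(eps):
        a = eps - 1.0
        if a <= 1e-9:
            norm = np.log(np.log(ratio))
        else:
            norm = np.log((1.0 - ratio ** (-a)) / a)
        return eps * mean_log + norm + np.log(y_star)

    res = optimize.minimize_scalar(neg_ll, bounds=(1.0 + 1e-6, 20.0),
                                   method="bounded")
    return float(res.x)


def _pareto_ks(y: np.ndarray, y_star: float, eps: float, m: float) -> float:
    """KS distance between the empirical tail and the truncated Pareto."""
    ys = np.sort(y)
    n = len(ys)
    a = eps - 1.0
    denom = 1.0 - (m / y_star) ** (-a)
    cdf = (1.0 - (ys / y_star) ** (-a)) / denom
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(max(np.abs(emp_hi - cdf).max(), np.abs(emp_lo - cdf).max()))


def _trunc_exp_rate(y: np.ndarray, upper: float) -> float:
    """ML rate of an exponential on (0, upper) observed below the cutoff."""
    mean = y.mean()

    def gap(lam):
        return 1.0 / lam - upper / np.expm1(lam * upper) - mean

    lo, hi = 1e-8, 1.0
    while gap(hi) > 0 and hi < 1e8:
        hi *= 10.0
    if gap(lo) < 0:  # mean >= upper/2: flat within the window
        return 1.0 / mean
    return float(optimize.brentq(gap, lo, hi))


class ExceedanceModel(BaseEstimator):
    """Fit the two-regime exceedance distribution to positive scalars.

    Parameters
    ----------
    m_quantile : float
        Quantile defining the upper cutoff m; the super-cutoff tail is
        fit with its own exponential rate lambda2.
    min_tail : int
        Minimum number of points required in the power-law regime.
    max_candidates : int
        Cap on the number of y_star candidates scanned.

    Attributes (fitted)
    -------------------
    lambda1_, lambda2_, epsilon_, y_star_, m_, regime_flags_, ks_distance_
    """

    def __init__(self, m_quantile: float = 0.99, min_tail: int = 20,
                 max_candidates: int = 100):
        self.m_quantile = m_quantile
        self.min_tail = min_tail
        self.max_candidates = max_candidates

    def fit(self, y, X=None):
        y = np.asarray(y, dtype=float).ravel()
        y = y[np.isfinite(y)]
        if len(y) < 50:
            raise ValueError(f"need >= 50 values, got {len(y)}")
        if (y <= 0).any():
            raise ValueError("values must be strictly positive")
        if np.allclose(y, y[0]):
            raise ValueError("all values equal; no distribution to fit")

        m = float(np.quantile(y, self.m_quantile))
        body = y[y < m]
        sup = y[y >= m]

        # Clauset-style scan of the truncation point on the sub-cutoff body
        cands = np.unique(body)
        cands = cands[cands < m]
        if len(cands) > self.max_candidates:
            idx = np.linspace(0, len(cands) - 1, self.max_candidates).astype(int)
            cands = cands[idx]
        best = None
        for ys in cands:
            tail = body[body >= ys]
            if len(tail) < self.min_tail:
                continue
            eps = _truncated_pareto_eps(tail, ys, m)
            if not np.isfinite(eps):
                continue
            ks = _pareto_ks(tail, ys, eps, m)
            if best is None or ks < best[0]:
                best = (ks, float(ys), eps, len(tail))

        flags = []
        if best is not None:
            ks, y_star, eps, n_tail = best
            tail = body[body >= y_star]
            # likelihood-ratio screen: power law must beat an exponential
            # fit of the same tail for the regime to be declared
            a = eps - 1.0
            norm = np.log((1.0 - (m / y_star) ** (-a)) / a) + np.log(y_star)
            ll_pl = float((-eps * np.log(tail / y_star) - norm).sum())
            lam_t = 1.0 / max(tail.mean() - y_star, 1e-300)
            ll_ex = float((np.log(lam_t) - lam_t * (tail - y_star)).sum())
            # a power-law regime must beat the exponential tail fit AND
            # span at least a decade (the usual minimal-evidence bar)
            if ll_pl > ll_ex and eps > 1.0 and m / y_star >= 10.0:
                flags.append("power_law")
        if best is None or "power_law" not in flags:
            y_star, eps, ks, n_tail = float(np.max(y)), float("nan"), float("nan"), 0

        if "power_law" in flags:
            below = y[y < y_star]
            lambda1 = _trunc_exp_rate(below, y_star) if len(below) >= 10 else float("nan")
        else:
            lambda1 = 1.0 / y.mean()
        if np.isfinite(lambda1):
            flags.insert(0, "exponential_bulk")

        if len(sup) >= 10:
            lambda2 = 1.0 / max(sup.mean() - m, 1e-300)
            flags.append("exponential_tail")
        else:
            lambda2 = float("nan")

        self.lambda1_ = float(lambda1)
        self.lambda2_ = float(lambda2)
        self.epsilon_ = float(eps)
        self.y_star_ = float(y_star)
        self.m_ = m
        self.regime_flags_ = tuple(flags)
        self.ks_distance_ = float(ks)
        self.n_tail_ = int(n_tail)
        return self

    def result(self) -> ExceedanceFit:
        return ExceedanceFit(
            lambda1=self.lambda1_, lambda2=self.lambda2_, epsilon=self.epsilon_,
            y_star=self.y_star_, m=self.m_, regime_flags=self.regime_flags_,
            ks_distance=self.ks_distance_, n_tail=self.n_tail_,
        )


class LogLogScaling(BaseEstimator):
    """Ordinary least squares on (log10 x, log10 y).

    Fitted attributes: ``exponent_`` (slope), ``intercept_``, ``r2_``,
    ``x_range_`` (decades spanned by x).
    """

    def fit(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(x) != len(y):
            raise ValueError("x and y lengths differ")
        if len(x) < 3:
            raise ValueError("need at least 3 points")
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log-log fit requires strictly positive values")
        lx, ly = np.log10(x), np.log10(y)
        slope, intercept = np.polyfit(lx, ly, 1)
        resid = ly - (slope * lx + intercept)
        ss_tot = float(((ly - ly.mean()) ** 2).sum())
        ss_res = float((resid ** 2).sum())
        if ss_tot <= 1e-30:
            r2 = 1.0 if ss_res <= 1e-30 else 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        self.exponent_ = float(slope)
        self.intercept_ = float(intercept)
        self.r2_ = float(r2)
        self.x_range_ = float(lx.max() - lx.min())
        return self

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return 10.0 ** self.intercept_ * x ** self.exponent_

    def result(self) -> ScalingFit:
        return ScalingFit(exponent=self.exponent_, intercept=self.intercept_,
                          r2=self.r2_, x_range=self.x_range_)


def fit_exceedance(values, **kwargs) -> ExceedanceFit:
    """Fit the two-regime exceedance model; see :class:`ExceedanceModel`."""
    return ExceedanceModel(**kwargs).fit(values).result()


def scaling_fit(x, y) -> ScalingFit:
    """OLS log-log scaling fit; see :class:`LogLogScaling`."""
    return LogLogScaling().fit(x, y).result()


def gamma_vs_events(track: DiversityTrack) -> ScalingFit:
    """Scaling of cumulative diversity gamma(t) against speciation events M(t)."""
    m = np.asarray(track.m_events, dtype=float)
    g = np.asarray(track.gamma, dtype=float)
    mask = (m > 0) & (g > 0)
    if mask.sum() < 3:
        raise ValueError("track too degenerate for a scaling fit")
    return scaling_fit(m[mask], g[mask])
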
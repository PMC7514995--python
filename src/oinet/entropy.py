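"""Discretization, Shannon entropy, mutual information and transfer entropy.

All estimators are plug-in (maximum-likelihood) entropies over
equal-frequency (quantile) symbol alphabets, in bits.  Transfer entropy
from a source series X to a target series Y at lag tau uses a single
lagged value as the history (Markov order 1 at lag tau):

    TE(X -> Y; tau) = sum p(y_t, y_{t-tau}, x_{t-tau})
                      * log2 [ p(y_t | y_{t-tau}, x_{t-tau})
                             / p(y_t | y_{t-tau}) ]

which is nonnegative and zero when X's past adds nothing beyond Y's own
past.  Significance of an estimated TE is judged against a circular-shift
permutation null of the source.  The functional distance between two
species is d_f = exp(-MI) minimized over lags (equivalently, MI maximized).

The quantile-bin count defaults to max(2, floor((T/20)^(1/3))) — the
median split for anything shorter than a few thousand points — and the
maximal lag to min(5, floor(T/6)); both are deliberately conservative
for the short series this package targets.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .containers import PairwiseInfo

__all__ = [
    "DiscretizedSeries",
    "default_n_bins",
    "default_tau_max",
    "discretize",
    "shannon_entropy",
    "mutual_information",
    "transfer_entropy",
    "conditional_te",
    "select_lag",
    "sign_of_interaction",
    "functional_distance",
    "permutation_null",
]

_LOG2 = math.log(2.0)


class DiscretizedSeries:
    """A series of quantile-bin symbols.

    Attributes
    ----------
    symbols : ndarray of int
        Bin index per time point, each in ``[0, n_bins)``.
    n_bins : int
    bin_edges : ndarray
        Strictly increasing interior thresholds actually used (duplicates
        produced by ties are dropped, so fewer than ``n_bins - 1`` edges
        may remain; an all-constant series has none and maps to symbol 0).
    """

    def __init__(self, symbols: np.ndarray, n_bins: int, bin_edges: np.ndarray):
        self.symbols = np.asarray(symbols, dtype=np.int64)
        self.n_bins = int(n_bins)
        self.bin_edges = np.asarray(bin_edges, dtype=float)

    def __len__(self) -> int:
        return len(self.symbols)


def default_n_bins(n_time: int) -> int:
    # the TE plug-in fills a B^3-cell lag-triple histogram (B^4+ once
    # conditioners join); require ~20 counts per cell, so the median
    # split (B=2) rules until series run to thousands of points
    return max(2, int(np.floor((n_time / 20.0) ** (1.0 / 3.0))))


def default_tau_max(n_time: int) -> int:
    return max(1, min(5, n_time // 6))


def discretize(series, n_bins: int | None = None) -> DiscretizedSeries:
    """Equal-frequency (quantile) binning of an abundance series."""
    x = np.asarray(series, dtype=float)
    t = len(x)
    if t < 2:
        raise ValueError("series must have at least 2 points")
    if n_bins is None:
        n_bins = default_n_bins(t)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > t:
        raise ValueError(f"n_bins={n_bins} exceeds series length {t}")
    xs = np.sort(x)
    positions = (np.arange(1, n_bins) * t) // n_bins
    edges = np.unique(xs[positions])
    if edges.size and edges[0] <= xs[0]:
        # guard: an edge at the minimum would leave bin 0 empty
        edges = edges[edges > xs[0]]
    symbols = np.searchsorted(edges, x, side="right")
    return DiscretizedSeries(symbols=symbols, n_bins=n_bins, bin_edges=edges)


def _symbols(d) -> np.ndarray:
    return d.symbols if isinstance(d, DiscretizedSeries) else np.asarray(d, dtype=np.int64)


def _plugin_entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def shannon_entropy(d) -> float:
    """Plug-in Shannon entropy H = -sum p log2 p of the symbol frequencies."""
    s = _symbols(d)
    if s.size == 0:
        raise ValueError("empty series")
    return _plugin_entropy(np.bincount(s))


def _lagged_pair(x: np.ndarray, y: np.ndarray, lag: int):
    """Return (x(t - lag), y(t)) aligned arrays; lag may be negative."""
    t = len(x)
    if abs(lag) >= t:
        raise ValueError(f"lag {lag} >= series length {t}")
    if lag >= 0:
        return x[: t - lag] if lag else x, y[lag:] if lag else y
    return x[-lag:], y[: t + lag]


def mutual_information(x, y, lag: int = 0) -> float:
    """Plug-in mutual information (bits) between x(t - lag) and y(t)."""
    xs, ys = _lagged_pair(_symbols(x), _symbols(y), lag)
    if len(xs) != len(ys):
        raise ValueError("series lengths differ")
    bx = int(xs.max()) + 1
    by = int(ys.max()) + 1
    joint = np.bincount(xs * by + ys, minlength=bx * by).reshape(bx, by).astype(float)
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float((p[mask] * np.log2(p[mask] / (px @ py)[mask])).sum())
    return max(mi, 0.0)


def transfer_entropy(source, target, tau: int = 1) -> float:
    """Plug-in transfer entropy (bits) from source to target at lag tau.

    The history is the single value at lag tau for both series.  A
    constant target (or a source identical to the target: self-transfer)
    returns 0 by convention.
    """
    xs = _symbols(source)
    ys = _symbols(target)
    if len(xs) != len(ys):
        raise ValueError("series lengths differ")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau >= len(ys):
        raise ValueError(f"tau {tau} >= series length {len(ys)}")
    if np.array_equal(xs, ys):
        return 0.0
    yt = ys[tau:]
    yp = ys[:-tau]
    xp = xs[:-tau]
    return _te_from_lagged(yt, yp, xp)


def _te_from_lagged(yt: np.ndarray, yp: np.ndarray, xp: np.ndarray) -> float:
    if yt.max() == yt.min():
        return 0.0
    byt = int(yt.max()) + 1
    byp = int(yp.max()) + 1
    bxp = int(xp.max()) + 1
    code = (yt * byp + yp) * bxp + xp
    joint = np.bincount(code, minlength=byt * byp * bxp).astype(float)
    joint = joint.reshape(byt, byp, bxp)
    n = joint.sum()
    p = joint / n
    p_yp_xp = p.sum(axis=0, keepdims=True)          # p(y_past, x_past)
    p_yt_yp = p.sum(axis=2, keepdims=True)          # p(y_t, y_past)
    p_yp = p.sum(axis=(0, 2), keepdims=True)        # p(y_past)
    mask = p > 0
    num = p[mask] * np.broadcast_to(p_yp, p.shape)[mask]
    den = (np.broadcast_to(p_yp_xp, p.shape)[mask]
           * np.broadcast_to(p_yt_yp, p.shape)[mask])
    te = float((p[mask] * np.log2(num / den)).sum())
    return max(te, 0.0)


def conditional_te(source, target, conditioners, tau: int = 1,
                   cond_lags: list[int] | None = None) -> float:
    """Transfer entropy of source -> target conditioned on other species.

    Each conditioner contributes its lagged value (its own lag if
    ``cond_lags`` is given, else ``tau``) to the history alongside the
    target's own past.  With an empty conditioner set this reduces
    exactly to :func:`transfer_entropy`.  Used to separate information
    flow (direct influence) from information transfer mediated by an
    intermediate species.
    """
    conds = [_symbols(c) for c in conditioners]
    if not conds:
        return transfer_entropy(source, target, tau)
    xs = _symbols(source)
    ys = _symbols(target)
    for c in conds:
        if np.array_equal(c, xs) or np.array_equal(c, ys):
            raise ValueError("conditioner equals source or target")
    if cond_lags is None:
        cond_lags = [tau] * len(conds)
    max_lag = max([tau] + list(cond_lags))
    if max_lag >= len(ys):
        raise ValueError("lag exceeds series length")
    yt = ys[max_lag:]
    if yt.max() == yt.min():
        return 0.0
    yp = ys[max_lag - tau: len(ys) - tau]
    xp = xs[max_lag - tau: len(xs) - tau]
    hist = [yp]
    for c, cl in zip(conds, cond_lags):
        hist.append(c[max_lag - cl: len(c) - cl])
    # encode the joint history (y past + conditioner pasts) as one symbol
    hcode = np.zeros_like(yt)
    for h in hist:
        hcode = hcode * (int(h.max()) + 1) + h
    _, hcode = np.unique(hcode, return_inverse=True)
    return _te_from_lagged(yt, hcode, xp)


def select_lag(source, target, tau_max: int) -> tuple[int, float]:
    """Pick the lag in 1..tau_max minimizing the functional distance.

    d_f = exp(-MI(x(t - tau), y(t))) is minimized, i.e. MI is maximized;
    ties break toward the smallest lag.  Returns ``(tau_star, mi_star)``.
    """
    if tau_max < 1:
        raise ValueError("tau_max must be >= 1")
    best_tau, best_mi = 1, -1.0
    for tau in range(1, tau_max + 1):
        mi = mutual_information(source, target, lag=tau)
        if mi > best_mi + 1e-15:
            best_tau, best_mi = tau, mi
    return best_tau, best_mi


def sign_of_interaction(source_values, target_values, tau: int) -> int:
    """Sign of the Spearman correlation of source(t - tau) with target(t)."""
    xs, ys = _lagged_pair(np.asarray(source_values, float),
                          np.asarray(target_values, float), tau)
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return 1
    rho = stats.spearmanr(xs, ys).statistic
    if not np.isfinite(rho) or rho >= 0:
        return 1
    return -1


def functional_distance(x, y, tau_max: int, signed_lags: bool = True) -> float:
    """d_f = exp(-MI) minimized over lags (both signs by default, incl. 0)."""
    lags = range(-tau_max, tau_max + 1) if signed_lags else range(0, tau_max + 1)
    best = 0.0
    for lag in lags:
        best = max(best, mutual_information(x, y, lag=lag))
    return math.exp(-best)


def permutation_null(source, target, tau: int, n_perm: int,
                     rng: np.random.Generator,
                     conditioners=(), cond_lags=None,
                     tau_max: int | None = None,
                     margin: int | None = None) -> np.ndarray:
    """Circular-shift permutation null for (conditional) transfer entropy.

    The source is circularly shifted by a uniform random offset for each
    permutation, which destroys the lagged coupling while preserving the
    source's marginal distribution and autocorrelation.  Shifts within
    ``margin`` of 0 or T are excluded: a shift of s re-aligns a true
    coupling at lag L with the tested lag whenever s = L - tau (mod T),
    so without the guard the null is contaminated by the very coupling
    under test.  ``margin`` defaults to ``(tau_max or tau) + 1``.  When
    ``tau_max`` is given (unconditional case) the lag is re-selected
    within each permutation, so the max-over-lags selection bias of the
    observed statistic is present in the null too.
    """
    xs = _symbols(source)
    t = len(xs)
    if margin is None:
        margin = (tau_max if tau_max is not None else tau) + 1
    lo, hi = margin, t - margin
    if lo >= hi:
        lo, hi = 1, t
    null = np.empty(n_perm)
    for i in range(n_perm):
        shift = int(rng.integers(lo, hi))
        xr = np.roll(xs, shift)
        if conditioners:
            null[i] = conditional_te(xr, target, conditioners, tau, cond_lags)
        elif tau_max is not None:
            tau_i, _ = select_lag(xr, target, tau_max)
            null[i] = transfer_entropy(xr, target, tau_i)
        else:
            null[i] = transfer_entropy(xr, target, tau)
    return null


def pairwise_info(source_values, target_values, source_sym, target_sym,
                  source_label: str, target_label: str,
                  tau_max: int) -> PairwiseInfo:
    """Full directed pairwise summary at the MI-selected lag."""
    tau, mi = select_lag(source_sym, target_sym, tau_max)
    te = transfer_entropy(source_sym, target_sym, tau)
    sign = sign_of_interaction(source_values, target_values, tau)
    return PairwiseInfo(source=source_label, target=target_label,
                        te=te, lag=tau, mi=mi, sign=sign)
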
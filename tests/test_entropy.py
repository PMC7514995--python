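"""Information-theoretic core: discretization, entropy, MI, TE.

TE and MI are checked against an independent brute-force oracle that
loops over every symbol tuple of the joint histogram with plain Python
dict counting.
"""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oinet import entropy as ent


# ---------------------------------------------------------------- oracles
def te_oracle(x, y, tau):
    """Exhaustive plug-in TE summation over all symbol triples."""
    x = list(x)
    y = list(y)
    triples = [(y[t], y[t - tau], x[t - tau]) for t in range(tau, len(y))]
    n = len(triples)
    c3 = Counter(triples)
    c_yp_xp = Counter((yp, xp) for _, yp, xp in triples)
    c_yt_yp = Counter((yt, yp) for yt, yp, _ in triples)
    c_yp = Counter(yp for _, yp, _ in triples)
    te = 0.0
    for (yt, yp, xp), c in c3.items():
        p = c / n
        te += p * math.log2((c * c_yp[yp]) / (c_yp_xp[(yp, xp)] * c_yt_yp[(yt, yp)]))
    return te


def mi_oracle(x, y):
    n = len(x)
    cxy = Counter(zip(x, y))
    cx = Counter(x)
    cy = Counter(y)
    return sum(c / n * math.log2(c * n / (cx[a] * cy[b]))
               for (a, b), c in cxy.items())


# ----------------------------------------------------------- discretize
def test_discretize_median_split():
    d = ent.discretize([0.1, 0.2, 0.3, 0.4], n_bins=2)
    assert list(d.symbols) == [0, 0, 1, 1]


def test_discretize_constant_series_single_symbol():
    d = ent.discretize([0.5] * 10, n_bins=3)
    assert set(d.symbols) == {0}


def test_discretize_equal_frequency_on_zipf_sample(rng):
    x = rng.pareto(1.0, size=800) + 1.0
    d = ent.discretize(x, n_bins=8)
    counts = np.bincount(d.symbols, minlength=8)
    assert counts.max() - counts.min() <= 1


def test_discretize_rejects_too_many_bins():
    with pytest.raises(ValueError):
        ent.discretize([0.1, 0.2], n_bins=3)


def test_discretize_edges_strictly_increasing(rng):
    x = rng.choice([0.1, 0.2, 0.2, 0.3], size=50)
    d = ent.discretize(x, n_bins=4)
    assert np.all(np.diff(d.bin_edges) > 0)


# ------------------------------------------------------- shannon entropy
@pytest.mark.parametrize("symbols,expected", [
    ([0, 1, 2, 3], 2.0),
    ([0, 0, 0, 0], 0.0),
    ([0, 0, 1, 2], 1.5),
])
def test_shannon_entropy_closed_forms(symbols, expected):
    assert ent.shannon_entropy(np.array(symbols)) == pytest.approx(expected)


# ---------------------------------------------------- mutual information
def test_mi_self_equals_entropy(rng):
    x = rng.integers(0, 3, size=300)
    assert ent.mutual_information(x, x) == pytest.approx(ent.shannon_entropy(x))


def test_mi_lagged_copy_equals_window_entropy(rng):
    x = rng.integers(0, 2, size=400)
    y = np.roll(x, 1)
    h_window = ent.shannon_entropy(x[:-1])
    assert ent.mutual_information(x, y, lag=1) == pytest.approx(h_window)


def test_mi_independent_streams_small(rng):
    x = rng.integers(0, 2, size=10_000)
    y = rng.integers(0, 2, size=10_000)
    assert ent.mutual_information(x, y) < 0.02


def test_mi_matches_oracle(rng):
    x = rng.integers(0, 3, size=120)
    y = rng.integers(0, 4, size=120)
    assert ent.mutual_information(x, y) == pytest.approx(mi_oracle(x, y), abs=1e-12)


def test_mi_symmetric_at_lag_zero(rng):
    x = rng.integers(0, 3, size=200)
    y = (x + rng.integers(0, 2, size=200)) % 3
    assert ent.mutual_information(x, y) == pytest.approx(
        ent.mutual_information(y, x), abs=1e-12)


# ------------------------------------------------------- transfer entropy
@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 4), st.integers(1, 3),
       st.integers(20, 200))
def test_te_matches_bruteforce_oracle(seed, n_bins, tau, t):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, n_bins, size=t)
    y = rng.integers(0, n_bins, size=t)
    assert ent.transfer_entropy(x, y, tau) == pytest.approx(
        te_oracle(x, y, tau), abs=1e-12)


def test_te_lag1_copy_is_one_bit(rng):
    """A deterministic lag-1 copy of an iid fair coin carries 1 bit."""
    x = rng.integers(0, 2, size=10_000)
    y = np.roll(x, 1)
    assert ent.transfer_entropy(x, y, 1) == pytest.approx(1.0, abs=0.05)


def test_te_independent_streams_near_zero(rng):
    x = rng.integers(0, 2, size=10_000)
    y = rng.integers(0, 2, size=10_000)
    assert ent.transfer_entropy(x, y, 1) < 0.02


def test_te_asymmetric_on_lagged_copy(rng):
    x = rng.integers(0, 2, size=10_000)
    y = np.roll(x, 1)
    fwd = ent.transfer_entropy(x, y, 1)
    back = ent.transfer_entropy(y, x, 1)
    assert fwd - back > 0.5


def test_te_self_transfer_zero(rng):
    x = rng.integers(0, 3, size=200)
    assert ent.transfer_entropy(x, x, 1) == 0.0


def test_te_constant_target_zero(rng):
    x = rng.integers(0, 2, size=100)
    assert ent.transfer_entropy(x, np.zeros(100, dtype=int), 1) == 0.0


def test_te_noisy_binary_channel_matches_analytic(rng):
    """Lag-1 copy through a binary flip channel: TE = 1 - H2(q) exactly.

    The target's own past is independent of its present here, so the
    stationary triple distribution factorizes and the exact value can be
    enumerated over the 8 symbol triples.
    """
    q = 0.2
    t = 100_000
    x = rng.integers(0, 2, size=t)
    flips = rng.random(t) < q
    y = np.where(flips, 1 - np.roll(x, 1), np.roll(x, 1))
    # exact enumeration of the stationary joint p(yt, yp, xp)
    exact = 0.0
    for yt in (0, 1):
        for yp in (0, 1):
            for xp in (0, 1):
                p_yt_given_xp = (1 - q) if yt == xp else q
                p = 0.25 * p_yt_given_xp  # p(xp) p(yp) p(yt | xp)
                exact += p * math.log2(p_yt_given_xp / 0.5)
    assert exact == pytest.approx(1 - (-q * math.log2(q) - (1 - q) * math.log2(1 - q)))
    assert ent.transfer_entropy(x, y, 1) == pytest.approx(exact, abs=0.02)


# -------------------------------------------------------- lag selection
def test_select_lag_finds_construction_lag(rng):
    x = rng.integers(0, 2, size=400)
    y = np.roll(x, 3)
    tau, mi = ent.select_lag(x, y, tau_max=5)
    assert tau == 3
    assert mi > 0.9


def test_select_lag_tie_breaks_small(rng):
    x = rng.integers(0, 2, size=300)
    y = rng.integers(0, 2, size=300)
    tau, _ = ent.select_lag(x, np.zeros(300, dtype=int), tau_max=4)
    assert tau == 1  # constant target: MI = 0 at every lag, smallest wins


def test_functional_distance_one_iff_mi_zero(rng):
    x = rng.integers(0, 2, size=200)
    const = np.zeros(200, dtype=int)
    assert ent.functional_distance(x, const, tau_max=3) == pytest.approx(1.0)
    y = np.roll(x, 1)
    assert ent.functional_distance(x, y, tau_max=3) < 1.0


# ------------------------------------------------------- conditional TE
def test_conditional_te_reduces_to_te_with_no_conditioners(rng):
    x = rng.integers(0, 2, size=300)
    y = rng.integers(0, 2, size=300)
    assert ent.conditional_te(x, y, [], 1) == ent.transfer_entropy(x, y, 1)


def test_conditional_te_rejects_source_conditioner(rng):
    x = rng.integers(0, 2, size=100)
    y = rng.integers(0, 2, size=100)
    with pytest.raises(ValueError):
        ent.conditional_te(x, y, [x], 1)


def test_chain_conditional_te_blocks_indirect_link(chain_series, rng):
    """On X -> Y -> Z, conditioning on Y explains away TE(X -> Z)."""
    x, y, z = chain_series
    xs = x.astype(int)
    ys = y.astype(int)
    zs = z.astype(int)
    te_xz = ent.transfer_entropy(xs, zs, 2)
    cte_xz = ent.conditional_te(xs, zs, [ys], 2, cond_lags=[1])
    null = ent.permutation_null(xs, zs, 2, 200, rng, margin=6)
    cnull = ent.permutation_null(xs, zs, 2, 200, rng,
                                 conditioners=[ys], cond_lags=[1], margin=6)
    assert te_xz > np.quantile(null, 0.95)
    assert cte_xz <= np.quantile(cnull, 0.95)
    # data-processing-style bound up to estimator noise
    assert cte_xz <= te_xz + np.quantile(cnull, 0.95)


def test_independent_triple_conditional_te_near_zero(rng):
    x = rng.integers(0, 2, size=5000)
    y = rng.integers(0, 2, size=5000)
    w = rng.integers(0, 2, size=5000)
    assert ent.conditional_te(x, y, [w], 1) < 0.02


# ---------------------------------------------------------------- sign
def test_sign_positive_for_lagged_copy(rng):
    x = rng.random(200)
    y = np.roll(x, 1)
    assert ent.sign_of_interaction(x, y, 1) == 1


def test_sign_negative_for_anticoupled(rng):
    x = rng.random(200)
    y = 1.0 - np.roll(x, 1)
    assert ent.sign_of_interaction(x, y, 1) == -1


def test_sign_defined_for_independent_pair(rng):
    x = rng.random(200)
    y = rng.random(200)
    assert ent.sign_of_interaction(x, y, 1) in (1, -1)
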
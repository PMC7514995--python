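"""MENet assembly, OIN pruning, network entropy and threshold screens."""

import math

import networkx as nx
import numpy as np
import pytest

from oinet import SimSpec, TransferEntropyNetwork, simulate
from oinet.containers import DirectedWeightedNet
from oinet.network import (
    entropy_flow_pattern,
    pareto_threshold_net,
    prune_to_oin,
    total_network_entropy,
)


def toy_net(edges, entropies=None, kind="MENet"):
    g = nx.DiGraph()
    nodes = {u for e in edges for u in e[:2]}
    for n in sorted(nodes):
        g.add_node(n, entropy=(entropies or {}).get(n, 1.0), keep=1)
    for u, v, te, sign in edges:
        g.add_edge(u, v, te=te, sign=sign, lag=1, mi=te, df=math.exp(-te))
    net = DirectedWeightedNet(graph=g, kind=kind)
    net.refresh_te_totals()
    return net


# ------------------------------------------------------------ inference
@pytest.fixture(scope="module")
def chain_fit():
    series, edges = simulate(SimSpec(n_species=10, n_time=500, topology="chain",
                                     coupling_strength=0.8, sign_balance=0.0,
                                     seed=7))
    est = TransferEntropyNetwork(random_state=7).fit(series.data)
    return est, edges


def test_chain_recovers_all_direct_edges(chain_fit):
    """Every planted chain coupling is detected; the net stays sparse.

    Compositional closure couples all species through the shared
    denominator, so a handful of longer-range edges are genuinely
    present in RSA space; the pruned network must still be dominated by
    the direct couplings.
    """
    est, edges = chain_fit
    found = set(est.menet_.graph.edges)
    true = {(u, v) for u, v, _ in edges}
    assert true <= found
    assert len(found) <= 2 * len(true)


def test_chain_oin_subset_of_menet(chain_fit):
    est, _ = chain_fit
    assert set(est.oin_.graph.nodes) <= set(est.menet_.graph.nodes)
    assert set(est.oin_.graph.edges) <= set(est.menet_.graph.edges)


def test_independent_species_give_empty_menet():
    series, _ = simulate(SimSpec(n_species=6, n_time=400, topology="empty",
                                 seed=3))
    est = TransferEntropyNetwork(random_state=3).fit(series.data)
    assert est.menet_.n_edges == 0


def test_estimator_sklearn_params_roundtrip():
    est = TransferEntropyNetwork(n_bins=3, n_perm=50)
    params = est.get_params()
    assert params["n_bins"] == 3
    est.set_params(n_perm=99)
    assert est.n_perm == 99


def test_fit_rejects_single_species():
    with pytest.raises(ValueError):
        TransferEntropyNetwork().fit(np.tile(np.linspace(0, 1, 50), (1, 1)))


def test_node_te_totals_match_edges(chain_fit):
    est, _ = chain_fit
    g = est.menet_.graph
    for n in g.nodes:
        assert g.nodes[n]["ote"] == pytest.approx(
            sum(d["te"] for _, _, d in g.out_edges(n, data=True)), abs=1e-12)
        assert g.nodes[n]["ite"] == pytest.approx(
            sum(d["te"] for _, _, d in g.in_edges(n, data=True)), abs=1e-12)


# ---------------------------------------------------------- OIN pruning
def test_oin_keeps_net_exporter_drops_sink_and_ties():
    net = toy_net([("a", "b", 0.5, 1), ("b", "c", 0.1, 1), ("d", "a", 0.5, 1),
                   ("a", "d", 0.5, 1)])
    # a: ote 1.0 / ite 0.5 -> kept; b: 0.1/0.5 -> dropped;
    # c: pure sink -> dropped; d: ote == ite -> dropped (tie maps to 0)
    oin = prune_to_oin(net)
    assert set(oin.graph.nodes) == {"a"}
    assert oin.kind == "OIN"
    assert all(d["keep"] == 1 for _, d in oin.graph.nodes(data=True))


def test_oin_totals_recomputed_over_retained_edges():
    net = toy_net([("a", "b", 0.4, 1), ("a", "c", 0.3, 1), ("c", "a", 0.1, 1)])
    oin = prune_to_oin(net)
    for n in oin.graph.nodes:
        assert oin.ote(n) == pytest.approx(
            sum(d["te"] for _, _, d in oin.graph.out_edges(n, data=True)))


# ------------------------------------------------------ network entropy
def test_total_entropy_isolated_node():
    net = toy_net([], {})
    net.graph.add_node("a", entropy=2.0, keep=1)
    assert total_network_entropy(net) == pytest.approx(2.0)


@pytest.mark.parametrize("sign,expected", [(1, 2.3), (-1, 1.7)])
def test_total_entropy_signed_edge(sign, expected):
    net = toy_net([("a", "b", 0.3, sign)])
    assert total_network_entropy(net) == pytest.approx(expected)


# --------------------------------------------------------- entropy flow
def test_entropy_flow_extremes_and_monotone():
    net = toy_net([("a", "b", 0.3, 1), ("b", "c", 0.2, 1), ("c", "a", 0.1, 1)])
    pat = entropy_flow_pattern(net, [0.0, 0.15, 0.25, 1.0])
    assert pat.h_net[0] == pytest.approx(total_network_entropy(net))
    assert pat.h_net[-1] == pytest.approx(3.0)  # node entropies only
    assert np.all(np.diff(pat.h_net) <= 1e-12)


def test_entropy_flow_monotone_with_negative_signs():
    net = toy_net([("a", "b", 0.3, -1), ("b", "c", 0.2, 1)])
    pat = entropy_flow_pattern(net, np.linspace(0, 0.5, 11))
    assert np.all(np.diff(pat.h_net) <= 1e-12)


def test_entropy_flow_rejects_unsorted():
    net = toy_net([("a", "b", 0.3, 1)])
    with pytest.raises(ValueError):
        entropy_flow_pattern(net, [0.2, 0.1])


def test_skewness_separates_sign_regimes():
    """Balanced +/- couplings give |skew| below a positively biased regime.

    Signed TEs are pooled over seeds: single small networks carry too few
    edges for a stable third moment.
    """
    from scipy import stats
    pool = {0.5: [], 0.0: []}
    for seed in range(3):
        for balance in (0.5, 0.0):
            series, _ = simulate(SimSpec(n_species=30, n_time=400,
                                         topology="random", n_edges=40,
                                         sign_balance=balance, seed=seed))
            est = TransferEntropyNetwork(random_state=seed).fit(series.data)
            pool[balance] += [d["sign"] * d["te"]
                              for _, _, d in est.menet_.graph.edges(data=True)]
    neg_bal = np.mean(np.array(pool[0.5]) < 0)
    neg_pos = np.mean(np.array(pool[0.0]) < 0)
    assert abs(neg_bal - 0.5) < abs(neg_pos - 0.5)  # sign balance recovered
    assert abs(stats.skew(pool[0.5])) < abs(stats.skew(pool[0.0]))


# ------------------------------------------------------------- pareto net
def test_pareto_keeps_top_fraction():
    edges = [(f"n{i}", f"n{i+1}", 0.1 * (i + 1), 1) for i in range(10)]
    net = toy_net(edges)
    top = pareto_threshold_net(net, 0.2)
    assert top.n_edges == 2
    assert set(top.graph.edges) == {("n9", "n10"), ("n8", "n9")}


def test_pareto_fraction_one_is_identity():
    net = toy_net([("a", "b", 0.3, 1), ("b", "c", 0.2, 1)])
    assert set(pareto_threshold_net(net, 1.0).graph.edges) == set(net.graph.edges)


def test_pareto_tie_breaks_lexically():
    net = toy_net([("b", "c", 0.2, 1), ("a", "b", 0.2, 1), ("c", "d", 0.5, 1)])
    top = pareto_threshold_net(net, 2 / 3)
    assert set(top.graph.edges) == {("c", "d"), ("a", "b")}


def test_pareto_rejects_empty():
    net = DirectedWeightedNet(graph=nx.DiGraph(), kind="MENet")
    with pytest.raises(ValueError):
        pareto_threshold_net(net, 0.2)
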
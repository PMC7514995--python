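"""Maximum-entropy network assembly and optimal information network pruning.

The Maximum Entropy Network (MENet) over a group's pooled RSA table keeps,
for every ordered species pair, the directed transfer-entropy edge at the
MI-selected lag, provided it (i) exceeds the circular-shift permutation
null and (ii) survives conditional-TE pruning of indirect links (an edge
mediated by a stronger parent of the same target is removed when its
conditional TE falls below the conditional null).  Because every retained
TE term is nonnegative, this edge set maximizes the total network entropy

    H(N) = sum_i H(x_i) g(x_i) + sum_i sum_{j != i} sign(i,j) TE(i->j) g(x_i)

among data-consistent networks.  The Optimal Information Network (OIN) is
the MENet restricted, in a single pass, to nodes whose total outgoing TE
strictly exceeds their total incoming TE (g = 1).

`TransferEntropyNetwork` exposes the whole procedure as a scikit-learn
style estimator (``fit`` on a species-by-time matrix; fitted attributes
``menet_``, ``oin_``, ...); the module-level functions are thin wrappers.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import entropy as ent
from .containers import DirectedWeightedNet, EntropyFlowPattern, GroupEnsemble

__all__ = [
    "TransferEntropyNetwork",
    "build_menet",
    "prune_to_oin",
    "total_network_entropy",
    "entropy_flow_pattern",
    "pareto_threshold_net",
]


class TransferEntropyNetwork(BaseEstimator):
    """Infer a directed transfer-entropy network from RSA time series.

    Parameters
    ----------
    n_bins : int or None
        Quantile bins for discretization; ``None`` uses
        ``max(2, floor((T/20)**(1/3)))`` (the median split for short
        series).
    tau_max : int or None
        Largest lag searched; ``None`` uses ``min(5, floor(T/6))``.
    n_perm : int
        Circular-shift permutations for the significance null.
    alpha : float or None
        ``None`` (default) keeps an edge only when its TE exceeds the
        *entire* permutation null (p < 1/(n_perm + 1)), a family-wise
        guard against the ~n^2 candidate pairs tested; a float keeps
        edges above the ``1 - alpha`` null quantile instead.
    c_max : int
        Size of the conditioning set for indirect-link pruning: the
        strongest alternative predictors of the target, excluding
        proxies of the source's own past.
    prune_alpha : float or None
        Level of the conditional-TE pruning test; ``None`` (default)
        drops an edge unless its conditional TE exceeds the entire
        conditional null.
    random_state : int, Generator or None
        Seeds the permutation null.

    Attributes
    ----------
    species_ : list of str
    entropies_ : dict mapping species to Shannon entropy (bits)
    te_matrix_ : DataFrame of significant direct TEs (0 elsewhere)
    menet_ : DirectedWeightedNet
    oin_ : DirectedWeightedNet
    """

    def __init__(self, n_bins: int | None = None, tau_max: int | None = None,
                 n_perm: int = 200, alpha: float | None = None, c_max: int = 3,
                 prune_alpha: float | None = None, random_state=None):
        self.n_bins = n_bins
        self.tau_max = tau_max
        self.n_perm = n_perm
        self.alpha = alpha
        self.c_max = c_max
        self.prune_alpha = prune_alpha
        self.random_state = random_state

    # -- data marshalling ------------------------------------------------
    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, GroupEnsemble):
            return X.pooled
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-d species-by-time matrix")
        return pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])])

    def fit(self, X, y=None):
        """Infer MENet and OIN from a species-by-time abundance matrix."""
        frame = self._as_frame(X)
        n_species, t = frame.shape
        if t < 6:
            raise ValueError(f"series too short for inference (T={t})")
        values = frame.to_numpy(dtype=float)
        labels = [str(s) for s in frame.index]

        n_bins = self.n_bins or ent.default_n_bins(t)
        tau_max = self.tau_max or ent.default_tau_max(t)
        rng = np.random.default_rng(self.random_state)

        syms = [ent.discretize(values[i], n_bins) for i in range(n_species)]
        entropies = {lab: ent.shannon_entropy(s) for lab, s in zip(labels, syms)}

        usable = [i for i in range(n_species)
                  if syms[i].symbols.max() != syms[i].symbols.min()]
        if len(usable) < 2:
            raise ValueError("need at least 2 species with nonconstant series")

        def _cut(null: np.ndarray) -> float:
            if self.alpha is None:
                return float(null.max())
            return float(np.quantile(null, 1.0 - self.alpha))

        # stage 1: significant direct TEs at the MI-selected lag
        all_pairs: dict[tuple[int, int], dict] = {}
        candidates: dict[tuple[int, int], dict] = {}
        for i in usable:
            for j in usable:
                if i == j:
                    continue
                tau, mi = ent.select_lag(syms[i], syms[j], tau_max)
                te = ent.transfer_entropy(syms[i], syms[j], tau)
                all_pairs[(i, j)] = dict(te=te, lag=tau)
                if te <= 0:
                    continue
                null = ent.permutation_null(syms[i], syms[j], tau,
                                            self.n_perm, rng,
                                            margin=tau_max + 1)
                if te > _cut(null):
                    sign = ent.sign_of_interaction(values[i], values[j], tau)
                    candidates[(i, j)] = dict(te=te, lag=tau, mi=mi, sign=sign,
                                              df=math.exp(-mi))

        # stage 2: conditional-TE pruning of indirect links.  Conditioners
        # are the strongest alternative predictors of the target among all
        # species (not only already-significant parents): an indirect or
        # common-mode dependence can be mediated by a species whose own
        # direct edge did not pass the null.
        kept = {}
        for (i, j), d in candidates.items():
            # Conditioner pool: significant parents of the target are always
            # eligible (genuine mediators); other species are excluded when
            # they are better explained as children of the source than as
            # parents of the target — such proxies of the source's own past
            # would explain away a true direct edge.
            alt = [k for k in usable if k != i and k != j
                   and ((k, j) in candidates
                        or not all_pairs[(i, k)]["te"] > all_pairs[(k, j)]["te"])]
            if alt and self.c_max >= 1:
                alt.sort(key=lambda k: -all_pairs[(k, j)]["te"])
                conds = alt[: self.c_max]
                cond_syms = [syms[k] for k in conds]
                cond_lags = [all_pairs[(k, j)]["lag"] for k in conds]
                try:
                    cte = ent.conditional_te(syms[i], syms[j], cond_syms,
                                             d["lag"], cond_lags)
                    cnull = ent.permutation_null(syms[i], syms[j], d["lag"],
                                                 self.n_perm, rng,
                                                 conditioners=cond_syms,
                                                 cond_lags=cond_lags,
                                                 margin=tau_max + 1)
                    if self.prune_alpha is None:
                        ccut = float(cnull.max())
                    else:
                        ccut = float(np.quantile(cnull, 1.0 - self.prune_alpha))
                    if cte <= ccut:
                        continue
                except ValueError:
                    pass  # degenerate conditioner (identical series): keep edge
            kept[(i, j)] = d

        g = nx.DiGraph()
        for lab in labels:
            g.add_node(lab, entropy=entropies[lab], keep=1)
        for (i, j), d in kept.items():
            g.add_edge(labels[i], labels[j], **d)
        menet = DirectedWeightedNet(graph=g, kind="MENet")
        menet.refresh_te_totals()

        te_mat = pd.DataFrame(0.0, index=labels, columns=labels)
        for (i, j), d in kept.items():
            te_mat.iloc[i, j] = d["te"]

        self.species_ = labels
        self.n_bins_ = n_bins
        self.tau_max_ = tau_max
        self.entropies_ = entropies
        self.te_matrix_ = te_mat
        self.menet_ = menet
        self.oin_ = prune_to_oin(menet)
        return self

    def entropy_flow(self, thresholds) -> EntropyFlowPattern:
        return entropy_flow_pattern(self.menet_, thresholds)

    def pareto_net(self, fraction: float = 0.20) -> DirectedWeightedNet:
        return pareto_threshold_net(self.menet_, fraction)


def build_menet(group, n_bins: int | None = None, tau_max: int | None = None,
                n_perm: int = 200, alpha: float | None = None, c_max: int = 1,
                random_state=None) -> DirectedWeightedNet:
    """Maximum Entropy Network of a group's pooled RSA table."""
    est = TransferEntropyNetwork(n_bins=n_bins, tau_max=tau_max, n_perm=n_perm,
                                 alpha=alpha, c_max=c_max,
                                 random_state=random_state)
    return est.fit(group).menet_


def prune_to_oin(menet: DirectedWeightedNet) -> DirectedWeightedNet:
    """Single-pass OIN pruning: keep nodes with OTE strictly above ITE.

    Nodes with g = 0 (OTE <= ITE) are removed together with their incident
    edges; OTE/ITE used for the keep decision are the MENet values (no
    iteration to a fixed point), while the reported per-node totals are
    recomputed over the retained edges.
    """
    g = menet.graph
    keep = [n for n in g.nodes
            if g.nodes[n].get("ote", 0.0) > g.nodes[n].get("ite", 0.0)]
    h = g.subgraph(keep).copy()
    for n in h.nodes:
        h.nodes[n]["keep"] = 1
    oin = DirectedWeightedNet(graph=h, kind="OIN")
    oin.refresh_te_totals()
    return oin


def total_network_entropy(net: DirectedWeightedNet) -> float:
    """Signed total network entropy H(N) over the retained nodes and edges.

    H(N) = sum_i H(x_i) + sum_edges sign * TE, all in bits; the residual
    noise term is not estimable from the data and is reported as zero.
    """
    g = net.graph
    h = sum(d.get("entropy", 0.0) for _, d in g.nodes(data=True))
    h += sum(d["sign"] * d["te"] for _, _, d in g.edges(data=True))
    return float(h)


def _signed_skewness(values: np.ndarray) -> float:
    if values.size < 2 or np.allclose(values, values[0]):
        return 0.0
    return float(stats.skew(values))


def entropy_flow_pattern(net: DirectedWeightedNet, thresholds) -> EntropyFlowPattern:
    """Network entropy and signed-TE asymmetry along a TE-cutoff grid.

    For each cutoff the network is rebuilt keeping edges with |TE| >=
    cutoff (all nodes retained) and the entropy curve

        h(c) = sum_i H(x_i) + sum_{|TE| >= c} TE

    is reported together with the skewness of the retained *signed* TEs
    (the healthy-state symmetry diagnostic).  The curve uses TE
    magnitudes so that it is non-increasing in the cutoff; the signed sum
    of the full network is available via :func:`total_network_entropy`.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size > 1 and np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    g = net.graph
    h_nodes = sum(d.get("entropy", 0.0) for _, d in g.nodes(data=True))
    tes = np.array([d["te"] for _, _, d in g.edges(data=True)])
    signs = np.array([d["sign"] for _, _, d in g.edges(data=True)])
    h_net = np.empty_like(thresholds)
    asym = np.empty_like(thresholds)
    for k, c in enumerate(thresholds):
        m = tes >= c if tes.size else np.array([], dtype=bool)
        h_net[k] = h_nodes + (tes[m].sum() if tes.size else 0.0)
        asym[k] = _signed_skewness(signs[m] * tes[m]) if tes.size else 0.0
    return EntropyFlowPattern(thresholds=thresholds, h_net=h_net, asymmetry=asym)


def pareto_threshold_net(net: DirectedWeightedNet,
                         fraction: float = 0.20) -> DirectedWeightedNet:
    """Retain the top-``fraction`` of edges by |TE| (80/20 Pareto screen).

    Ties at the cut break by (source, target) lexical order; the node set
    is the endpoints of the retained edges.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("empty network")
    edges = sorted(g.edges(data=True), key=lambda e: (-e[2]["te"], e[0], e[1]))
    k = int(np.ceil(fraction * len(edges)))
    top = edges[:k]
    h = nx.DiGraph()
    for u, v, d in top:
        for n in (u, v):
            if not h.has_node(n):
                h.add_node(n, **g.nodes[n])
        h.add_edge(u, v, **d)
    pnet = DirectedWeightedNet(graph=h, kind="ParetoNet")
    pnet.refresh_te_totals()
    return pnet
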
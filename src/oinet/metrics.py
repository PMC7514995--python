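"""Structural and functional network metrics, stability and resilience.

The functional degree k_f of a node counts incident directed edges (in
plus out, each direction separately); the structural degree k counts
distinct undirected neighbors, so k_f >= k always.  Structural distances
are hop counts on the undirected skeleton.  The functional distance
census computes exp(-MI) at the best lag for every species pair.
Stability is summarized by the spectral radius of the adjacency or TE
matrix; resilience by seeded random node-removal experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from . import entropy as ent
from .containers import DirectedWeightedNet, GroupEnsemble

__all__ = [
    "degrees",
    "structural_distances",
    "functional_distance_census",
    "dominant_eigenvalue",
    "random_attack",
]


def degrees(net: DirectedWeightedNet) -> pd.DataFrame:
    """Per-node structural degree k and functional degree k_f."""
    g = net.graph
    und = g.to_undirected()
    rows = []
    for n in sorted(g.nodes):
        rows.append({"node": n, "k": und.degree(n),
                     "k_f": g.in_degree(n) + g.out_degree(n)})
    return pd.DataFrame(rows).set_index("node")


def structural_distances(net: DirectedWeightedNet) -> pd.DataFrame:
    """All-pairs hop counts on the undirected skeleton (inf across components)."""
    g = net.graph.to_undirected()
    nodes = sorted(g.nodes)
    mat = pd.DataFrame(np.inf, index=nodes, columns=nodes)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            mat.loc[src, dst] = d
    np.fill_diagonal(mat.values, 0.0)
    return mat


def functional_distance_census(group: GroupEnsemble,
                               n_bins: int | None = None,
                               tau_max: int | None = None,
                               decimals: int = 9) -> tuple[int, pd.DataFrame]:
    """All-pairs functional distance d_f = exp(-MI) at the best lag.

    Returns the count of unique d_f values (after rounding to
    ``decimals``) and the symmetric distance matrix.
    """
    labels = group.species_ids
    if len(labels) < 2:
        raise ValueError("need at least 2 species")
    v = group.values
    t = v.shape[1]
    n_bins = n_bins or ent.default_n_bins(t)
    tau_max = tau_max if tau_max is not None else ent.default_tau_max(t)
    syms = [ent.discretize(v[i], n_bins) for i in range(len(labels))]
    mat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    vals = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            df = ent.functional_distance(syms[i], syms[j], tau_max)
            mat.iloc[i, j] = mat.iloc[j, i] = df
            vals.append(round(df, decimals))
    return len(set(vals)), mat


def dominant_eigenvalue(net: DirectedWeightedNet, matrix: str = "adjacency") -> float:
    """Spectral radius of the adjacency (undirected, 0/1) or signed TE matrix."""
    nodes = sorted(net.graph.nodes)
    if not nodes:
        raise ValueError("empty network")
    n = len(nodes)
    idx = {lab: i for i, lab in enumerate(nodes)}
    a = np.zeros((n, n))
    if matrix == "adjacency":
        for u, v in net.graph.edges:
            a[idx[u], idx[v]] = 1.0
            a[idx[v], idx[u]] = 1.0
    elif matrix == "te":
        for u, v, d in net.graph.edges(data=True):
            a[idx[u], idx[v]] = d["sign"] * d["te"]
    else:
        raise ValueError(f"unknown matrix kind: {matrix!r}")
    if not a.any():
        return 0.0
    return float(np.abs(np.linalg.eigvals(a)).max())


def random_attack(net: DirectedWeightedNet, removal_fraction: float,
                  n_trials: int = 20, seed: int | None = None) -> dict:
    """Uniform random node deletion, repeated over seeded trials.

    Reports the mean and sd of (i) the surviving giant-component size as
    a fraction of the original giant component and (ii) the surviving
    total |TE| as a fraction of the original total.
    """
    if not 0 <= removal_fraction < 1:
        raise ValueError("removal_fraction must be in [0, 1)")
    g = net.graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    und = g.to_undirected()
    base_giant = max((len(c) for c in nx.connected_components(und)), default=0)
    base_te = sum(abs(d["te"]) for _, _, d in g.edges(data=True))
    rng = np.random.default_rng(seed)
    n_remove = int(round(removal_fraction * n))
    giants, tes = [], []
    for _ in range(n_trials):
        removed = set(rng.choice(n, size=n_remove, replace=False)) if n_remove else set()
        keep = [nodes[i] for i in range(n) if i not in removed]
        sub = g.subgraph(keep)
        sub_und = sub.to_undirected()
        giant = max((len(c) for c in nx.connected_components(sub_und)), default=0)
        giants.append(giant / base_giant if base_giant else 0.0)
        te = sum(abs(d["te"]) for _, _, d in sub.edges(data=True))
        tes.append(te / base_te if base_te else 0.0)
    return {
        "giant_mean": float(np.mean(giants)),
        "giant_sd": float(np.std(giants)),
        "te_mean": float(np.mean(tes)),
        "te_sd": float(np.std(tes)),
        "n_trials": n_trials,
        "removal_fraction": removal_fraction,
    }
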
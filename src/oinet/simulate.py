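"""Synthetic RSA tables with known ground-truth coupling networks.

The generator runs a first-order autoregressive process on per-species
log-abundances: each species has AR coefficient 0.3, signed directed
couplings on a planted graph (strength scaled per target by
1/sqrt(n_parents)), and Gaussian innovations.  The coupling matrix is
rescaled when its spectral radius would exceed 0.95, keeping the latent
process stationary.  Log-abundances are exponentiated, scaled to
Zipf-ranked species means (mean RSA of rank r proportional to
r^(-1/(epsilon-1)), the classical Zipf law at epsilon = 2), and column-
normalized to compositions, mimicking the compositional closure of real
OTU tables.

Two regimes bracket the study conditions: a healthy-like regime
(scale-free topology, balanced positive/negative couplings) and an
unhealthy-like regime (random topology, positively biased couplings).
Defaults describe the healthy-like community: 47 species, 30 days, Zipf
exponent 2, coupling strength 0.8, half-negative signs, unit innovation
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import RsaSeries

__all__ = ["SimSpec", "simulate", "copy_chain", "reference_cohort"]

_AR_COEF = 0.3
_RADIUS_CAP = 0.95


@dataclass
class SimSpec:
    """Parameters of one synthetic community.

    ``topology`` is one of scale-free, random, chain, star, empty;
    ``sign_balance`` is the fraction of negative couplings (0.5 for the
    healthy-like neutral regime, 0.0 for the positively biased
    unhealthy-like regime); ``abundance_exponent`` is the Zipf pdf
    exponent of the mean-RSA profile.
    """

    n_species: int = 47
    n_time: int = 30
    topology: str = "scale-free"
    coupling_strength: float = 0.8
    sign_balance: float = 0.5
    abundance_exponent: float = 2.0
    noise_sd: float = 1.0
    n_edges: int | None = None
    detection_limit: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1 or self.n_time < 1:
            raise ValueError("n_species and n_time must be >= 1")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must be in [0, 1]")
        if not 0 <= self.sign_balance <= 1:
            raise ValueError("sign_balance must be in [0, 1]")
        if self.topology not in {"scale-free", "random", "chain", "star", "empty"}:
            raise ValueError(f"unknown topology {self.topology!r}")


def _labels(n: int) -> list[str]:
    return [f"sp{i:03d}" for i in range(n)]


def _planted_edges(spec: SimSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Planted directed edges; random/scale-free graphs are acyclic.

    Edges are oriented along a random node order so the coupling matrix
    is triangular up to relabeling: the latent AR process is then
    stationary by construction and every planted coefficient keeps the
    stated coupling strength (cyclic feedback would force a stability
    rescale that silently changes the effective couplings and voids the
    ground truth).
    """
    n = spec.n_species
    if spec.topology == "empty" or n < 2:
        return []
    if spec.topology == "chain":
        return [(i, i + 1) for i in range(n - 1)]
    if spec.topology == "star":
        return [(0, j) for j in range(1, n)]
    n_edges = spec.n_edges if spec.n_edges is not None else n
    order = rng.permutation(n)
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    if spec.topology == "random":
        pairs = [(i, j) for i in range(n) for j in range(n) if rank[i] < rank[j]]
        idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
        return [pairs[k] for k in sorted(idx)]
    # scale-free: preferential-attachment skeleton oriented along the order
    m = max(1, n_edges // n)
    und = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2 ** 31)))
    return [(u, v) if rank[u] < rank[v] else (v, u) for u, v in und.edges]


def simulate(spec: SimSpec) -> tuple[RsaSeries, list[tuple[str, str, int]]]:
    """Generate one RSA table and the planted signed edge list (lag 1)."""
    rng = np.random.default_rng(spec.seed)
    n, t = spec.n_species, spec.n_time
    labels = _labels(n)

    edges = _planted_edges(spec, rng)
    n_neg = int(round(spec.sign_balance * len(edges)))
    signs = np.ones(len(edges), dtype=int)
    if n_neg:
        signs[rng.permutation(len(edges))[:n_neg]] = -1

    w = np.zeros((n, n))
    np.fill_diagonal(w, _AR_COEF)
    n_parents = np.bincount([j for _, j in edges], minlength=n).clip(min=1)
    for (i, j), s in zip(edges, signs):
        w[j, i] = s * spec.coupling_strength / np.sqrt(n_parents[j])
    if edges:
        radius = float(np.abs(np.linalg.eigvals(w)).max())
        if radius > _RADIUS_CAP:
            w *= _RADIUS_CAP / radius

    burn = 50
    z = np.zeros((n, t + burn))
    z[:, 0] = rng.normal(0.0, spec.noise_sd, size=n)
    for k in range(1, t + burn):
        z[:, k] = w @ z[:, k - 1] + rng.normal(0.0, spec.noise_sd, size=n)
    z = z[:, burn:]

    ranks = np.arange(1, n + 1, dtype=float)
    mu = ranks ** (-1.0 / max(spec.abundance_exponent - 1.0, 1e-6))
    x = mu[:, None] * np.exp(z)
    x = x / x.sum(axis=0)
    if spec.detection_limit > 0:
        # sequencing detection floor: shares below it read as absent,
        # giving the presence/absence dynamics real OTU tables show
        x[x < spec.detection_limit] = 0.0
        x = x / x.sum(axis=0)

    frame = pd.DataFrame(x, index=labels, columns=range(t))
    series = RsaSeries.from_frame(f"sim-{spec.seed}", frame)
    edge_list = [(labels[i], labels[j], int(s)) for (i, j), s in zip(edges, signs)]
    return series, edge_list


def copy_chain(n_time: int = 500, flip_p: float = 0.15,
               seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary copy chain X -> Y -> Z at lag 1 with a symbol-flip channel.

    Y copies X at lag 1 and Z copies Y at lag 1, each symbol flipping
    with probability ``flip_p``.  The canonical information-flow fixture:
    TE(X -> Z) is large (two-step transfer) while the conditional
    TE(X -> Z | Y) vanishes, since Y mediates the whole path.
    """
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n_time)
    y = np.where(rng.random(n_time) < flip_p, 1 - np.roll(x, 1), np.roll(x, 1))
    z = np.where(rng.random(n_time) < flip_p, 1 - np.roll(y, 1), np.roll(y, 1))
    return x, y, z


def reference_cohort(seed: int = 0, n_species: int = 200):
    """Six synthetic individuals shaped like the study cohort.

    Member lengths are 30, 15, 15, 9, 9 and 14 days, grouped into
    (healthy: A, B), (transitory: C, C1), (unhealthy: P1, P2) so that the
    group LCM reconstruction lengths are 30, 45 and 126 days.  The pool
    holds 200 species by default — gut 16S tables at species-level
    resolution carry hundreds of OTUs, and a deep Zipf tail below the
    detection floor is what gives realistic species-accumulation and
    turnover dynamics.  Healthy
    and transitory members use scale-free, sign-balanced couplings;
    unhealthy members use random, positively biased couplings.

    Returns ``(members, groups)``: the list of :class:`RsaSeries` and a
    mapping of group label to member ids.
    """
    plan = [
        ("A", 30, "scale-free", 0.5),
        ("B", 15, "scale-free", 0.5),
        ("C", 15, "scale-free", 0.3),
        ("C1", 9, "random", 0.3),
        ("P1", 9, "random", 0.0),
        ("P2", 14, "random", 0.0),
    ]
    members = []
    for k, (name, length, topo, balance) in enumerate(plan):
        spec = SimSpec(n_species=n_species, n_time=length, topology=topo,
                       sign_balance=balance, seed=seed * 31 + k)
        series, _ = simulate(spec)
        series.individual_id = name
        members.append(series)
    groups = {"healthy": ["A", "B"], "transitory": ["C", "C1"],
              "unhealthy": ["P1", "P2"]}
    return members, groups
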
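"""Core in-memory containers shared across the package.

The central object is a taxa-by-time table of relative species abundances
(RSA): rows are species/OTU labels, columns are integer day indices, and
every column is a composition (sums to 1).  Networks inferred from such
tables are directed, signed, transfer-entropy-weighted graphs stored as
:class:`networkx.DiGraph` wrapped in :class:`DirectedWeightedNet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RsaSeries",
    "GroupEnsemble",
    "PairwiseInfo",
    "DirectedWeightedNet",
    "EntropyFlowPattern",
    "DiversityTrack",
]

_COL_TOL = 1e-6


@dataclass
class RsaSeries:
    """One individual's relative-species-abundance time series.

    Parameters
    ----------
    individual_id : str
        Label of the individual the series belongs to.
    data : pandas.DataFrame
        Species-by-time matrix of relative abundances.  The index holds
        unique taxon labels; columns are integer time indices (days).
        Columns are renormalized to sum to 1 on construction via
        :meth:`from_frame`.
    """

    individual_id: str
    data: pd.DataFrame

    @classmethod
    def from_frame(cls, individual_id: str, frame: pd.DataFrame) -> "RsaSeries":
        """Validate and renormalize a species-by-time table.

        Raises
        ------
        ValueError
            If a value is negative or missing, a taxon label is duplicated,
            or a column sums to zero.
        """
        frame = frame.copy()
        if frame.index.duplicated().any():
            dups = sorted(frame.index[frame.index.duplicated()].unique())
            raise ValueError(f"duplicate taxon labels: {dups}")
        values = frame.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at species {frame.index[r]!r}, time {frame.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance {values[r, c]} at species "
                f"{frame.index[r]!r}, time {frame.columns[c]!r}"
            )
        colsums = values.sum(axis=0)
        if (colsums <= 0).any():
            bad = [frame.columns[i] for i in np.nonzero(colsums <= 0)[0]]
            raise ValueError(f"columns sum to zero: {bad}")
        frame = frame.astype(float) / colsums
        frame.columns = range(frame.shape[1])
        return cls(individual_id=individual_id, data=frame)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def times(self) -> list[int]:
        return list(self.data.columns)

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def check(self) -> None:
        """Assert the compositional invariants."""
        v = self.values
        assert ((v >= 0) & (v <= 1 + _COL_TOL)).all()
        assert np.allclose(v.sum(axis=0), 1.0, atol=_COL_TOL)


@dataclass
class GroupEnsemble:
    """A labeled group of individuals merged onto a common time length.

    ``members`` are the LCM-extended series (all the same length) and
    ``pooled`` is the species-by-time table actually fed to the network
    inference: species shared by several members carry the member-averaged
    series, species unique to one member pass through verbatim.
    """

    group_id: str
    members: list[RsaSeries]
    pooled: pd.DataFrame

    @property
    def species_ids(self) -> list[str]:
        return list(self.pooled.index)

    @property
    def n_time(self) -> int:
        return self.pooled.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.pooled.to_numpy(dtype=float)


@dataclass
class PairwiseInfo:
    """Directed pairwise information summary for one ordered species pair.

    ``te`` is the transfer entropy (bits, >= 0) at the selected lag, ``mi``
    the mutual information at that lag, ``sign`` the interaction sign from
    the lagged Spearman correlation, and ``df = exp(-mi)`` the functional
    distance in (0, 1].
    """

    source: str
    target: str
    te: float
    lag: int
    mi: float
    sign: int
    df: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.df is None:
            self.df = math.exp(-self.mi)


@dataclass
class DirectedWeightedNet:
    """A directed TE-weighted species network (MENet, OIN or ParetoNet).

    Node attributes: ``entropy`` (Shannon entropy of the species, bits),
    ``ote`` / ``ite`` (total outgoing / incoming TE over retained edges),
    ``keep`` (the g flag; 1 on every node of an OIN).
    Edge attributes: ``te`` (magnitude, bits), ``sign`` (+1/-1), ``lag``,
    ``mi``, ``df``.
    """

    graph: nx.DiGraph
    kind: str = "MENet"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def refresh_te_totals(self) -> None:
        """Recompute per-node OTE/ITE from the currently retained edges."""
        g = self.graph
        for n in g.nodes:
            g.nodes[n]["ote"] = float(sum(d["te"] for _, _, d in g.out_edges(n, data=True)))
            g.nodes[n]["ite"] = float(sum(d["te"] for _, _, d in g.in_edges(n, data=True)))

    def ote(self, node: str) -> float:
        return float(self.graph.nodes[node].get("ote", 0.0))

    def ite(self, node: str) -> float:
        return float(self.graph.nodes[node].get("ite", 0.0))

    def edge_records(self) -> list[PairwiseInfo]:
        out = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            out.append(
                PairwiseInfo(
                    source=u, target=v, te=float(d["te"]), lag=int(d["lag"]),
                    mi=float(d["mi"]), sign=int(d["sign"]), df=float(d["df"]),
                )
            )
        return out


@dataclass
class EntropyFlowPattern:
    """Network entropy and signed-TE asymmetry along a TE-threshold grid."""

    thresholds: np.ndarray
    h_net: np.ndarray
    asymmetry: np.ndarray


@dataclass
class DiversityTrack:
    """Time-resolved diversity indicators for one group.

    ``alpha``: per-time species richness; ``beta``: turnover between
    consecutive time points (length ``len(times) - 1``); ``gamma``:
    cumulative distinct-species count; ``m_events``: cumulative count of
    (species, time) presence occurrences.
    """

    group_id: str
    times: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    m_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        beta = np.append(self.beta, np.nan)
        return pd.DataFrame(
            {
                "time": self.times,
                "alpha": self.alpha,
                "beta": beta,
                "gamma": self.gamma,
                "m_events": self.m_events,
            }
        )
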
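"""Species-level importance and collectivity indices.

Transfer Entropy Indices (TEI) rank species within an inferred network:
``sigma_i = OTE(i) / H(OIN)`` measures how much a species' outgoing
information flow contributes to the total network entropy (interaction /
activity), and ``mu_i = H(x_i) g(x_i) / H(OIN)`` measures its standalone
information content (importance).  Sigma uses unsigned TE magnitudes
(activity) while H(OIN) is the signed total; both conventions are
reported explicitly so the ratio is unambiguous.

Mutual Information Indices (MII) are the systemic-indicator alternative:
``s_i = MI(X_i; Y) / H(Y)`` and ``s_ij = MI(X_i; X_j | Y) / H(Y)`` for an
output variable Y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import entropy as ent
from .containers import DirectedWeightedNet
from .network import total_network_entropy

__all__ = ["SpeciesIndexRow", "tei", "top_k_by_ote", "mii"]


@dataclass
class SpeciesIndexRow:
    species: str
    sigma: float
    mu: float
    ote: float
    rsa_mean: float


def tei(net: DirectedWeightedNet,
        rsa_means: dict[str, float] | None = None) -> list[SpeciesIndexRow]:
    """Transfer Entropy Indices for every node of an inferred network.

    Rows are sorted by sigma descending, ties by species label.  Raises
    if the total network entropy is not positive.
    """
    h_net = total_network_entropy(net)
    if h_net <= 0:
        raise ValueError(f"total network entropy must be > 0, got {h_net}")
    rows = []
    for n, d in net.graph.nodes(data=True):
        ote = float(sum(e["te"] for _, _, e in net.graph.out_edges(n, data=True)))
        rows.append(SpeciesIndexRow(
            species=n,
            sigma=ote / h_net,
            mu=float(d.get("entropy", 0.0)) * int(d.get("keep", 1)) / h_net,
            ote=ote,
            rsa_mean=float(rsa_means.get(n, np.nan)) if rsa_means else float("nan"),
        ))
    rows.sort(key=lambda r: (-r.sigma, r.species))
    return rows


def tei_frame(rows: list[SpeciesIndexRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("species")


def top_k_by_ote(rows: list[SpeciesIndexRow], k: int = 10) -> list[str]:
    """Labels of the k most active species by OTE (ties by label)."""
    if k > len(rows):
        raise ValueError(f"k={k} exceeds number of rows {len(rows)}")
    ranked = sorted(rows, key=lambda r: (-r.ote, r.species))
    return [r.species for r in ranked[:k]]


def _cmi(x, y, z) -> float:
    """Plug-in conditional mutual information MI(x; y | z) in bits."""
    xs = ent._symbols(x)
    ys = ent._symbols(y)
    zs = ent._symbols(z)
    bx, by, bz = (int(a.max()) + 1 for a in (xs, ys, zs))
    code = (xs * by + ys) * bz + zs
    p = np.bincount(code, minlength=bx * by * bz).astype(float)
    p = p.reshape(bx, by, bz) / len(xs)
    p_xz = p.sum(axis=1, keepdims=True)
    p_yz = p.sum(axis=0, keepdims=True)
    p_z = p.sum(axis=(0, 1), keepdims=True)
    mask = p > 0
    num = p[mask] * np.broadcast_to(p_z, p.shape)[mask]
    den = (np.broadcast_to(p_xz, p.shape)[mask]
           * np.broadcast_to(p_yz, p.shape)[mask])
    return max(float((p[mask] * np.log2(num / den)).sum()), 0.0)


def mii(predictors, y) -> tuple[np.ndarray, np.ndarray]:
    """Mutual Information Indices against an output variable.

    Returns ``(s, s_pair)`` where ``s[i] = MI(X_i; Y) / H(Y)`` and
    ``s_pair[i, j] = MI(X_i; X_j | Y) / H(Y)`` (symmetric, nan diagonal).
    """
    hy = ent.shannon_entropy(y)
    if hy <= 0:
        raise ValueError("output variable is constant (H(Y) = 0)")
    n = len(predictors)
    s = np.array([ent.mutual_information(p, y) / hy for p in predictors])
    s_pair = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            v = _cmi(predictors[i], predictors[j], y) / hy
            s_pair[i, j] = s_pair[j, i] = v
    return s, s_pair
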
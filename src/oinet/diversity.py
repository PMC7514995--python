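"""Macroecological diversity indicators over RSA time series.

Order-zero indicators built from species presence (RSA above a presence
floor, 0 by default):

* alpha(t): species richness at time t,
* beta(t): temporal turnover, 1 - Jaccard similarity between the
  presence sets at t and t+1 (with the convention that a shared-species
  count of 0 is replaced by 1, implemented literally; a strict-Jaccard
  switch is available),
* gamma(t): cumulative distinct-species count up to t,
* M(t): cumulative number of speciation events, i.e. (species, time)
  presence occurrences — every time a species is present at a time point
  counts as one introduction event.

Entropic (order-one) counterparts obey H_gamma >= H_alpha, the diversity
balance H_beta = H_gamma - H_alpha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DiversityTrack, GroupEnsemble

__all__ = [
    "alpha_diversity",
    "beta_turnover",
    "gamma_diversity",
    "speciation_events",
    "diversity_track",
    "rsa_rank_profile",
    "richness_vs_rsa",
    "diversity_entropies",
]


def _presence(group: GroupEnsemble, presence_eps: float = 0.0) -> np.ndarray:
    return group.values > presence_eps


def alpha_diversity(group: GroupEnsemble, t: int, presence_eps: float = 0.0) -> int:
    """Number of species present (RSA > presence_eps) at time t."""
    return int(_presence(group, presence_eps)[:, t].sum())


def beta_turnover(group: GroupEnsemble, t: int, presence_eps: float = 0.0,
                  strict_jaccard: bool = False) -> float:
    """Turnover between times t and t+1: 1 - Jaccard similarity.

    When the two presence sets share no species the shared count is set
    to 1 (the literal fallback); ``strict_jaccard=True`` keeps 0 instead
    (beta = 1 for disjoint nonempty sets).
    """
    pres = _presence(group, presence_eps)
    if t + 1 >= pres.shape[1]:
        raise ValueError(f"time {t + 1} out of range")
    a = pres[:, t]
    b = pres[:, t + 1]
    shared = int((a & b).sum())
    if shared == 0 and not strict_jaccard and (a.sum() or b.sum()):
        shared = 1
    union = int(a.sum()) + int(b.sum()) - shared
    if union <= 0:
        return 0.0
    return 1.0 - shared / union


def gamma_diversity(group: GroupEnsemble, up_to_t: int | None = None,
                    presence_eps: float = 0.0) -> int:
    """Distinct species present at any time up to ``up_to_t`` (inclusive)."""
    pres = _presence(group, presence_eps)
    if up_to_t is None:
        up_to_t = pres.shape[1] - 1
    return int(pres[:, : up_to_t + 1].any(axis=1).sum())


def speciation_events(group: GroupEnsemble, up_to_t: int | None = None,
                      presence_eps: float = 0.0) -> int:
    """Total count of (species, time) presence occurrences up to ``up_to_t``."""
    pres = _presence(group, presence_eps)
    if up_to_t is None:
        up_to_t = pres.shape[1] - 1
    return int(pres[:, : up_to_t + 1].sum())


def diversity_track(group: GroupEnsemble, presence_eps: float = 0.0,
                    strict_jaccard: bool = False) -> DiversityTrack:
    """Assemble the full alpha/beta/gamma/M track for a group."""
    pres = _presence(group, presence_eps)
    t = pres.shape[1]
    alpha = pres.sum(axis=0).astype(int)
    gamma = np.array([pres[:, : k + 1].any(axis=1).sum() for k in range(t)])
    m = np.cumsum(alpha)
    beta = np.array([beta_turnover(group, k, presence_eps, strict_jaccard)
                     for k in range(t - 1)])
    return DiversityTrack(group_id=group.group_id, times=np.arange(t),
                          alpha=alpha, beta=beta, gamma=gamma, m_events=m)


def rsa_rank_profile(group: GroupEnsemble) -> pd.DataFrame:
    """Species mean RSA sorted descending with ranks 1..S (ties lexical)."""
    means = group.pooled.mean(axis=1)
    order = sorted(means.index, key=lambda s: (-means[s], s))
    out = pd.DataFrame({"species": order,
                        "mean_rsa": [means[s] for s in order]})
    out["rank"] = np.arange(1, len(order) + 1)
    return out.set_index("rank")


def richness_vs_rsa(group: GroupEnsemble, bins: int = 10) -> pd.DataFrame:
    """Preston-style histogram: species counts per logarithmic RSA class."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    means = group.pooled.mean(axis=1).to_numpy()
    means = means[means > 0]
    logm = np.log10(means)
    lo, hi = logm.min(), logm.max()
    if hi - lo < 1e-12:
        edges = np.linspace(lo - 0.5, lo + 0.5, bins + 1)
    else:
        edges = np.linspace(lo, hi, bins + 1)
    counts, _ = np.histogram(logm, bins=edges)
    return pd.DataFrame({
        "log10_rsa_lo": edges[:-1],
        "log10_rsa_hi": edges[1:],
        "n_species": counts,
    })


def diversity_entropies(group: GroupEnsemble) -> tuple[float, float, float]:
    """(H_alpha, H_gamma, H_beta) in bits from RSA compositions.

    H_alpha is the time-averaged entropy of the per-time species
    composition, H_gamma the entropy of the time-averaged (pooled)
    composition; concavity of entropy gives H_beta = H_gamma - H_alpha
    >= 0.
    """
    v = group.values
    def _h(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())
    h_alpha = float(np.mean([_h(v[:, t] / v[:, t].sum()) for t in range(v.shape[1])]))
    pooled = v.mean(axis=1)
    h_gamma = _h(pooled / pooled.sum())
    return h_alpha, h_gamma, h_gamma - h_alpha
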
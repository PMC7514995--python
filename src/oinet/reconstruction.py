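"""Least-common-multiple time-series reconstruction and group assembly.

Individuals in a group are sampled for different numbers of days.  To pool
them, every member series is extended to the least common multiple of the
member lengths by whole-series cyclic tiling, which preserves each
species' empirical value distribution exactly.  Species shared by several
members are then averaged pointwise; species unique to one member pass
through verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd

from .containers import GroupEnsemble, RsaSeries

__all__ = ["LcmPlan", "lcm_target", "extend_series", "build_group"]


@dataclass
class LcmPlan:
    member_lengths: list[int]
    target_length: int

    @property
    def repeats(self) -> list[float]:
        return [self.target_length / n for n in self.member_lengths]


def lcm_target(lengths: list[int]) -> int:
    """Least common multiple of the member series lengths."""
    if not lengths:
        raise ValueError("empty length list")
    if any(int(n) != n or n < 1 for n in lengths):
        raise ValueError(f"lengths must be positive integers, got {lengths}")
    return reduce(math.lcm, (int(n) for n in lengths))


def extend_series(series: RsaSeries, target_length: int) -> RsaSeries:
    """Extend a series to ``target_length`` days by cyclic tiling.

    The input columns are repeated end-to-end until the target length is
    reached; when the target is an integer multiple of the input length,
    the per-species value multiset is exactly preserved.
    """
    t = series.n_time
    if target_length < t:
        raise ValueError(f"target length {target_length} < series length {t}")
    if target_length == t:
        return series
    reps = -(-target_length // t)  # ceil
    tiled = np.tile(series.values, reps)[:, :target_length]
    frame = pd.DataFrame(tiled, index=series.data.index, columns=range(target_length))
    return RsaSeries(individual_id=series.individual_id, data=frame)


def build_group(members: list[RsaSeries], group_id: str) -> GroupEnsemble:
    """Assemble a :class:`GroupEnsemble` from raw member series.

    All members are extended to the group LCM.  The pooled table holds,
    for every species in the union, the pointwise mean over the members
    that contain it (species found in a single member are kept as they
    are).  Pooled columns are renormalized to sum to 1 afterwards; the
    mean of compositions is compositional already, so this is a no-op
    guard against rounding.
    """
    if not members:
        raise ValueError("empty member list")
    target = lcm_target([m.n_time for m in members])
    extended = [extend_series(m, target) for m in members]

    species: list[str] = []
    for m in extended:
        for s in m.species_ids:
            if s not in species:
                species.append(s)

    pooled = pd.DataFrame(0.0, index=species, columns=range(target))
    counts = pd.Series(0, index=species, dtype=int)
    for m in extended:
        pooled.loc[m.species_ids] += m.data.to_numpy()
        counts.loc[m.species_ids] += 1
    pooled = pooled.div(counts, axis=0)
    pooled = pooled / pooled.to_numpy().sum(axis=0)
    return GroupEnsemble(group_id=group_id, members=extended, pooled=pooled)
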
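"""Tree-shape metrics describing how a binary trait is distributed over a phylogeny.

Four statistics summarise the "tippiness" of the derived state (state 1):

* ``n1`` — number of state-1 tips;
* ``tpo`` — state-1 tips per independent origin (origins counted by minimum-
  change parsimony);
* ``sscd`` — sum of sister-clade differences, a branch-length-free measure of
  phylogenetic signal;
* ``tars`` — tip age rank sum: ranks of terminal branch lengths (ascending,
  average ties) summed over state-1 tips, so small values mean young
  state-1 tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .treeio import CharacterData, Phylogeny

__all__ = [
    "MetricSet",
    "count_state1",
    "origins_parsimony",
    "tips_per_origin",
    "sum_sister_clade_differences",
    "tip_age_rank_sum",
    "compute_metrics",
]


@dataclass(frozen=True)
class MetricSet:
    """The four adequacy statistics of one (tree, states) dataset.

    ``tpo`` and ``tars`` are NaN when undefined (no state-1 tips, or a
    monomorphic dataset).
    """

    n1: int
    tpo: float
    sscd: float
    tars: float

    def as_dict(self) -> dict[str, float]:
        return {"n1": self.n1, "tpo": self.tpo, "sscd": self.sscd, "tars": self.tars}


def count_state1(states: CharacterData) -> int:
    """Number of tips in the derived state."""
    return sum(states.states.values())


def origins_parsimony(
    tree: Phylogeny, states: CharacterData, irreversible: bool = False
) -> int:
    """Minimum number of 0→1 changes over most-parsimonious reconstructions.

    Minimum-change (Fitch-style) parsimony with reversals allowed by default;
    the root is held in state 0 (the derived state is, by definition, derived),
    and among root-0 reconstructions achieving the minimum total change count,
    the one with fewest 0→1 changes is reported.  With ``irreversible=True``
    the 1→0 change is forbidden instead.
    """
    x = states.as_array(tree)
    if x.sum() == 0:
        return 0
    INF = 10 ** 9
    # cost[v][s] = (total changes, 0->1 changes), lexicographic minimum
    cost = np.zeros((tree.n_nodes, 2, 2), dtype=np.int64)
    for v in tree.postorder():
        if v < tree.n_tips:
            for s in (0, 1):
                if s == x[v]:
                    cost[v, s] = (0, 0)
                else:
                    cost[v, s] = (INF, INF)
        else:
            for s in (0, 1):
                tot = np.zeros(2, dtype=np.int64)
                for c in tree.children[v]:
                    best = (INF, INF)
                    for sc in (0, 1):
                        ch = 0 if sc == s else 1
                        if ch and irreversible and s == 1 and sc == 0:
                            continue
                        orig = 1 if (s == 0 and sc == 1) else 0
                        cand = (cost[c, sc, 0] + ch, cost[c, sc, 1] + orig)
                        if cand < best:
                            best = cand
                    tot += np.array(best)
                cost[v, s] = tot
    return int(cost[tree.root, 0, 1])


def tips_per_origin(tree: Phylogeny, states: CharacterData) -> float:
    """State-1 tips per parsimony origin; NaN when there are no state-1 tips."""
    n1 = count_state1(states)
    if n1 == 0:
        return math.nan
    return n1 / origins_parsimony(tree, states)


def sum_sister_clade_differences(tree: Phylogeny, states: CharacterData) -> float:
    """Sum over internal nodes of |left − right| child values.

    Node values are built bottom-up as the mean of the two child values, with
    tips valued by their 0/1 state; branch lengths play no role.
    """
    x = states.as_array(tree)
    val = np.zeros(tree.n_nodes)
    sscd = 0.0
    for v in tree.postorder():
        if v < tree.n_tips:
            val[v] = x[v]
        else:
            a, b = val[tree.children[v, 0]], val[tree.children[v, 1]]
            sscd += abs(a - b)
            val[v] = 0.5 * (a + b)
    return sscd


def tip_age_rank_sum(tree: Phylogeny, states: CharacterData) -> float:
    """Rank-sum of terminal branch lengths of state-1 tips (ascending, average ties).

    NaN for monomorphic data (the rank sum carries no contrast).
    """
    x = states.as_array(tree)
    n1 = int(x.sum())
    if n1 == 0 or n1 == tree.n_tips:
        return math.nan
    ranks = rankdata(tree.terminal_lengths(), method="average")
    return float(ranks[x == 1].sum())


def compute_metrics(tree: Phylogeny, states: CharacterData) -> MetricSet:
    """All four metrics of one dataset; undefined entries are NaN."""
    n1 = count_state1(states)
    return MetricSet(
        n1=n1,
        tpo=tips_per_origin(tree, states),
        sscd=sum_sister_clade_differences(tree, states),
        tars=tip_age_rank_sum(tree, states),
    )
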
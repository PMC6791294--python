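"""Forward simulation under state-dependent birth–death with character transitions.

Trees are grown event by event from a crown split (two lineages in the root
state at time 0): total event rate summed over extant lineages sets an
exponential waiting time; the event type (speciation, extinction, transition)
and the lineage it hits are chosen proportionally to their rates.  Growth
stops at the instant the requested number of extant lineages is created;
extinct lineages are then pruned, so accepted trees are extant-only and
ultrametric.  Whole-clade extinction triggers a restart on the same random
stream, up to a retry cap, which conditions the accepted-tree distribution
on survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sse_core import SSEParameters
from .treeio import CharacterData, Phylogeny

__all__ = ["SimulatedDataset", "simulate_sse_tree", "simulate_mk_character"]


@dataclass
class SimulatedDataset:
    """A simulated extant tree with its character data and true history."""

    tree: Phylogeny
    states: CharacterData
    params: SSEParameters
    seed: int | None
    retries: int
    #: transition counts (from, to) -> events over the whole (unpruned) history
    transitions_total: dict[tuple[int, int], int] = field(default_factory=dict)
    #: transition counts restricted to lineages with surviving descendants
    transitions_surviving: dict[tuple[int, int], int] = field(default_factory=dict)
    #: true state of the crown ancestor (the extant MRCA) at its split
    mrca_state: int = 0

    @property
    def true_origins(self) -> int:
        """0→1 transition events on lineages ancestral to the extant tips."""
        return self.transitions_surviving.get((0, 1), 0)


class _Lineage:
    __slots__ = ("parent", "birth", "death", "state0", "events", "children", "extinct")

    def __init__(self, parent: int, birth: float, state: int):
        self.parent = parent
        self.birth = birth
        self.death = -1.0
        self.state0 = state          # state at birth
        self.events: list[tuple[float, int, int]] = []   # (time, from, to)
        self.children: tuple[int, int] | None = None
        self.extinct = False

    def state_at_end(self) -> int:
        return self.events[-1][2] if self.events else self.state0


def _grow(params: SSEParameters, n_tips: int, root_state: int, rng: np.random.Generator,
          max_events: int = 2_000_000):
    k = params.n_states
    lam, mu, q = params.lam, params.mu, params.q
    qrow = q.sum(axis=1)
    tot = lam + mu + qrow
    # grow from a single stem lineage; the pruned tree's root is the first
    # surviving split, so accepted trees are crown trees of exactly n_tips
    lineages: list[_Lineage] = [_Lineage(-1, 0.0, root_state)]
    alive: list[set[int]] = [set() for _ in range(k)]
    alive[root_state].add(0)
    cur_state = {0: root_state}
    t = 0.0
    n_alive = 1
    for _ in range(max_events):
        if n_alive >= n_tips:
            break
        rates = np.array([len(alive[s]) * tot[s] for s in range(k)])
        R = rates.sum()
        if R <= 0:
            # no events possible; with pure stasis the clade can never reach n_tips
            return None, t, lineages
        t += rng.exponential(1.0 / R)
        s = rng.choice(k, p=rates / R)
        lid = list(alive[s])[rng.integers(len(alive[s]))]
        u = rng.random() * tot[s]
        ln = lineages[lid]
        if u < lam[s]:
            # speciation: lineage ends, two children born in state s
            ln.death = t
            c1, c2 = len(lineages), len(lineages) + 1
            lineages.append(_Lineage(lid, t, s))
            lineages.append(_Lineage(lid, t, s))
            ln.children = (c1, c2)
            alive[s].discard(lid)
            del cur_state[lid]
            alive[s].update((c1, c2))
            cur_state[c1] = cur_state[c2] = s
            n_alive += 1
        elif u < lam[s] + mu[s]:
            ln.death = t
            ln.extinct = True
            alive[s].discard(lid)
            del cur_state[lid]
            n_alive -= 1
            if n_alive == 0:
                return None, t, lineages
        else:
            # transition to state j, chosen proportional to q[s, :]
            w = u - lam[s] - mu[s]
            targets = [jj for jj in range(k) if jj != s and q[s, jj] > 0]
            j = targets[-1]
            acc = 0.0
            for jj in targets:
                acc += q[s, jj]
                if w < acc:
                    j = jj
                    break
            ln.events.append((t, s, j))
            alive[s].discard(lid)
            alive[j].add(lid)
            cur_state[lid] = j
    else:
        raise RuntimeError("simulation exceeded the event cap")
    # extend the stopping time by a uniform fraction of the waiting time to the
    # next event, so terminal branches (incl. the final twin pair) are positive
    rates = np.array([len(alive[s]) * tot[s] for s in range(k)])
    R = rates.sum()
    if R > 0:
        t += rng.random() * rng.exponential(1.0 / R)
    for lid in cur_state:
        lineages[lid].death = t
    return sorted(cur_state), t, lineages


def _prune_build(lineages: list[_Lineage], extant: list[int], t_end: float,
                 obs_map: np.ndarray | None):
    """Prune extinct lineages, suppress unifurcations, return arrays + histories."""
    surviving = set(extant)
    order = sorted(range(len(lineages)), key=lambda i: -lineages[i].birth)
    for lid in order:
        ln = lineages[lid]
        if ln.children is not None and any(c in surviving for c in ln.children):
            surviving.add(lid)
    # merged branches: walk from each surviving split/tip up to the nearest
    # surviving ancestor that is itself a split in the pruned tree
    def pruned_children(lid: int):
        ch = [c for c in lineages[lid].children if c in surviving] \
            if lineages[lid].children else []
        return ch

    n_tips = len(extant)
    labels = [f"t{i + 1}" for i in range(n_tips)]
    tip_of = {lid: i for i, lid in enumerate(extant)}
    node_id: dict[int, int] = dict(tip_of)
    next_id = n_tips
    # identify pruned-tree nodes: extant tips and surviving bifurcations
    splits = [lid for lid in surviving
              if lineages[lid].children and len(pruned_children(lid)) == 2]
    for lid in sorted(splits, key=lambda i: lineages[i].birth):
        node_id[lid] = next_id
        next_id += 1
    n_nodes = next_id
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    blen = np.zeros(n_nodes)

    def nearest_pruned_ancestor(lid: int) -> int:
        p = lineages[lid].parent
        while p >= 0:
            if p in node_id:
                return p
            p = lineages[p].parent
        return -1

    for lid, v in node_id.items():
        ln = lineages[lid]
        p = nearest_pruned_ancestor(lid)
        end = ln.death if ln.children is not None or ln.extinct else t_end
        if lid in tip_of:
            end = t_end
        start = lineages[p].death if p >= 0 else 0.0
        blen[v] = end - start
        if p >= 0:
            pv = node_id[p]
            parent[v] = pv
            slot = 0 if children[pv, 0] < 0 else 1
            children[pv, slot] = v
    # the single top node is the extant MRCA; drop the stem above it
    top = [v for v in range(n_nodes) if parent[v] < 0]
    blen[top[0]] = 0.0
    root_lid = next(lid for lid, v in node_id.items() if v == top[0])
    tree = Phylogeny(parent, children, blen, labels)
    tip_states = {}
    for lid, i in tip_of.items():
        s = lineages[lid].state_at_end()
        tip_states[labels[i]] = int(obs_map[s]) if obs_map is not None else int(s)
    return tree, tip_states, surviving, root_lid


def simulate_sse_tree(
    params: SSEParameters,
    n_tips: int,
    root_state: int = 0,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 1000,
    obs_map: np.ndarray | None = None,
) -> SimulatedDataset:
    """Simulate an extant-only tree of exactly ``n_tips`` under an SSE process.

    ``root_state`` indexes the expanded states of ``params``; for hidden-state
    simulations pass ``obs_map`` (observed 0/1 state per expanded state) so tip
    characters are projected to the observed binary trait.

    Raises ``RuntimeError`` if ``max_retries`` whole-clade extinctions occur.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if params.lam.sum() + params.mu.sum() + params.q.sum() <= 0:
        raise ValueError("all rates are zero; nothing can ever happen")
    if params.lam.sum() <= 0:
        raise ValueError("no positive speciation rate; target tip count unreachable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else seed
    retries = 0
    while True:
        extant, t_end, lineages = _grow(params, n_tips, root_state, rng)
        if extant is not None:
            break
        retries += 1
        if retries >= max_retries:
            raise RuntimeError(
                f"whole-clade extinction in {max_retries} consecutive attempts "
                f"(lam={params.lam}, mu={params.mu}, q01-like rates may be too low)")
    tree, tip_states, surviving, root_lid = _prune_build(lineages, extant, t_end, obs_map)
    mrca_state = lineages[root_lid].state_at_end()
    if obs_map is not None:
        mrca_state = int(obs_map[mrca_state])
    tot: dict[tuple[int, int], int] = {}
    surv: dict[tuple[int, int], int] = {}
    for lid, ln in enumerate(lineages):
        for (_, a, b) in ln.events:
            key = (int(a), int(b))
            if obs_map is not None:
                key = (int(obs_map[a]), int(obs_map[b]))
            tot[key] = tot.get(key, 0) + 1
            if lid in surviving:
                surv[key] = surv.get(key, 0) + 1
    return SimulatedDataset(
        tree=tree, states=CharacterData(tip_states), params=params,
        seed=seed_val, retries=retries,
        transitions_total=tot, transitions_surviving=surv,
        mrca_state=int(mrca_state),
    )


def simulate_mk_character(
    tree: Phylogeny,
    q01: float,
    q10: float,
    root_state: int = 0,
    seed: int | np.random.Generator | None = None,
) -> CharacterData:
    """Evolve a binary character along a fixed tree under a 2-state Markov model."""
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = (q01, q10)
    state = np.empty(tree.n_nodes, dtype=np.int64)
    for v in tree.postorder()[::-1]:     # preorder: root first
        p = tree.parent[v]
        s = root_state if p < 0 else int(state[p])
        remaining = float(tree.blen[v])
        while True:
            rate = q[s]
            if rate <= 0:
                break
            w = rng.exponential(1.0 / rate)
            if w >= remaining:
                break
            remaining -= w
            s = 1 - s
        state[v] = s
    return CharacterData({lb: int(state[i]) for i, lb in enumerate(tree.tip_labels)})
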
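"""Shared fixtures: small hand trees, random ultrametric trees, and an
independent fixed-step BiSSE likelihood oracle."""

from __future__ import annotations

import numpy as np
import pytest
from numba import njit

from syndive.treeio import CharacterData, Phylogeny, read_newick


@pytest.fixture(scope="session")
def crownlike():
    """One study-like synthetic dataset shared across tests (fixed seed)."""
    from syndive.synthetic_data import generate_crownlike
    return generate_crownlike(seed=20260927)


@pytest.fixture
def two_tip():
    return read_newick("(a:1,b:1):0;")


@pytest.fixture
def three_tip():
    return read_newick("((a:1,b:1):1,c:2):0;")


@pytest.fixture
def four_tip_balanced():
    return read_newick("((a:1,b:1):1,(c:1,d:1):1):0;")


def random_ultrametric(n_tips: int, rng: np.random.Generator,
                       height: float = 1.0) -> Phylogeny:
    """Random ultrametric tree: random pair merges at decreasing depths."""
    merge_depths = np.sort(rng.uniform(0, height, n_tips - 1))[::-1]
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    depth = np.empty(n_nodes)
    depth[:n_tips] = height
    active = list(range(n_tips))
    nxt = n_tips
    for d in merge_depths:
        i = active.pop(int(rng.integers(len(active))))
        j = active.pop(int(rng.integers(len(active))))
        children[nxt] = (i, j)
        parent[i] = parent[j] = nxt
        depth[nxt] = d
        active.append(nxt)
        nxt += 1
    depth[n_nodes - 1] = 0.0 if n_tips > 1 else height
    blen = np.zeros(n_nodes)
    for v in range(n_nodes - 1):
        blen[v] = depth[v] - depth[parent[v]]
    labels = [f"t{i}" for i in range(n_tips)]
    return Phylogeny(parent, children, blen, labels)


def random_states(tree: Phylogeny, rng: np.random.Generator,
                  p1: float = 0.5) -> CharacterData:
    x = (rng.random(tree.n_tips) < p1).astype(int)
    if x.sum() == 0:
        x[int(rng.integers(tree.n_tips))] = 1
    if x.sum() == tree.n_tips:
        x[int(rng.integers(tree.n_tips))] = 0
    return CharacterData({lb: int(x[i]) for i, lb in enumerate(tree.tip_labels)})


# ---------------------------------------------------------------------------
# Independent BiSSE oracle: classic fixed-step RK4, coded separately from the
# package's adaptive Cash-Karp kernel.

@njit(cache=True)
def _oracle_rk4(post, parent, children, blen, n_tips, tipD, E0, lam, mu, q,
                h_step, cond_surv):
    k = lam.shape[0]
    qrow = np.zeros(k)
    for i in range(k):
        for j in range(k):
            if j != i:
                qrow[i] += q[i, j]
    n_nodes = post.shape[0]
    E = np.zeros((n_nodes, k))
    D = np.zeros((n_nodes, k))
    logsc = 0.0
    root = -1
    for idx in range(n_nodes):
        v = post[idx]
        if v < n_tips:
            E[v] = E0.copy()
            D[v] = tipD[v].copy()
        else:
            c1, c2 = children[v, 0], children[v, 1]
            for i in range(k):
                E[v, i] = E[c1, i]
                D[v, i] = lam[i] * D[c1, i] * D[c2, i]
        s = D[v].sum()
        D[v] /= s
        logsc += np.log(s)
        if parent[v] >= 0:
            t_total = blen[v]
            n_steps = max(1, int(np.ceil(t_total / h_step)))
            h = t_total / n_steps
            e = E[v].copy()
            d = D[v].copy()
            for _ in range(n_steps):
                ke = np.empty((4, k))
                kd = np.empty((4, k))
                for stage in range(4):
                    if stage == 0:
                        ee, dd = e, d
                    elif stage == 1:
                        ee, dd = e + 0.5 * h * ke[0], d + 0.5 * h * kd[0]
                    elif stage == 2:
                        ee, dd = e + 0.5 * h * ke[1], d + 0.5 * h * kd[1]
                    else:
                        ee, dd = e + h * ke[2], d + h * kd[2]
                    for i in range(k):
                        ae = 0.0
                        ad = 0.0
                        for j in range(k):
                            ae += q[i, j] * ee[j]
                            ad += q[i, j] * dd[j]
                        tot = lam[i] + mu[i] + qrow[i]
                        ke[stage, i] = mu[i] - tot * ee[i] + lam[i] * ee[i] ** 2 + ae
                        kd[stage, i] = -tot * dd[i] + ad + 2.0 * lam[i] * ee[i] * dd[i]
                e = e + h / 6.0 * (ke[0] + 2 * ke[1] + 2 * ke[2] + ke[3])
                d = d + h / 6.0 * (kd[0] + 2 * kd[1] + 2 * kd[2] + kd[3])
            E[v] = e
            D[v] = d
        else:
            root = v
    d = D[root].copy()
    if cond_surv:
        for i in range(k):
            d[i] /= lam[i] * (1.0 - E[root, i]) ** 2
    tot = d.sum()
    acc = 0.0
    for i in range(k):
        acc += (d[i] / tot) * d[i]
    return np.log(acc) + logsc


def oracle_loglik(tree: Phylogeny, states: CharacterData, lam, mu, q,
                  f0=1.0, f1=1.0, h_step=1e-5, cond_surv=True) -> float:
    """Fixed-step RK4 BiSSE log-likelihood (FitzJohn root weighting)."""
    lam = np.asarray(lam, float)
    mu = np.asarray(mu, float)
    q = np.asarray(q, float)
    x = states.as_array(tree)
    fvec = np.array([f0, f1])
    tipD = np.zeros((tree.n_tips, 2))
    for t in range(tree.n_tips):
        tipD[t, x[t]] = fvec[x[t]]
    E0 = 1.0 - fvec
    return float(_oracle_rk4(tree.postorder(), tree.parent, tree.children,
                             tree.blen, tree.n_tips, tipD, E0, lam, mu, q,
                             h_step, cond_surv))
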
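"""Nonparametric tip-rate test for state-associated diversification.

Each tip's speciation rate is proxied by the inverse of its equal-splits
measure, ES = sum over the path to the root of branch length l_j halved at
each successive rootward node (l_1 + l_2/2 + l_3/4 + ...).  The test statistic
is the difference between the state means Λ0 − Λ1 of 1/ES; its null
distribution is built by refitting a symmetric one-rate Markov model to the
observed states and re-simulating characters on the same tree, so tree shape
is held fixed and only the character is randomised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .simulate import simulate_mk_character
from .treeio import CharacterData, Phylogeny

__all__ = ["FisseResult", "equal_splits", "fisse_test"]


@dataclass(frozen=True)
class FisseResult:
    """Inverse equal-splits statistics per state and simulation p-value."""

    lambda0: float       # mean 1/ES over state-0 tips
    lambda1: float       # mean 1/ES over state-1 tips
    diff: float          # lambda0 - lambda1
    pval: float
    n_sim: int

    def to_csv_row(self) -> str:
        return (f"{self.lambda0:.6g},{self.lambda1:.6g},{self.diff:.6g},"
                f"{self.pval:.6g},{self.n_sim}")


def _es_all(tree: Phylogeny) -> np.ndarray:
    """Equal-splits value of every tip, in tip order."""
    es = np.zeros(tree.n_tips)  # weight halves at each rootward node
    for i in range(tree.n_tips):
        w = 1.0
        v = i
        total = 0.0
        while tree.parent[v] >= 0:
            total += w * tree.blen[v]
            w *= 0.5
            v = tree.parent[v]
        es[i] = total
    return es


def equal_splits(tree: Phylogeny, tip: str) -> float:
    """ES of one tip: Σ_j l_j (1/2)^{j-1}, edges indexed from the tip rootward."""
    i = tree.tip_index(tip)
    return float(_es_all(tree)[i])


def _mk_symmetric_loglik(tree: Phylogeny, x: np.ndarray, q: float) -> float:
    """Pruning likelihood of a symmetric 2-state Markov model, stationary root."""
    L = np.zeros((tree.n_nodes, 2))
    logsc = 0.0
    for v in tree.postorder():
        if v < tree.n_tips:
            L[v, x[v]] = 1.0
            L[v, 1 - x[v]] = 0.0
        else:
            L[v] = L[tree.children[v, 0]] * L[tree.children[v, 1]]
        p = tree.parent[v]
        if p >= 0:
            t = tree.blen[v]
            same = 0.5 * (1.0 + np.exp(-2.0 * q * t))
            L[v] = np.array([
                same * L[v, 0] + (1 - same) * L[v, 1],
                (1 - same) * L[v, 0] + same * L[v, 1],
            ])
        s = L[v].sum()
        if s <= 0:
            return -np.inf
        L[v] /= s
        logsc += np.log(s)
    return float(np.log(0.5 * L[tree.root].sum()) + logsc)


def fit_mk_symmetric(tree: Phylogeny, states: CharacterData) -> float:
    """Maximum-likelihood symmetric transition rate of the observed character."""
    x = states.as_array(tree)
    if x.sum() in (0, tree.n_tips):
        raise ValueError("monomorphic character: Mk rate not identifiable")
    h = tree.height()
    res = minimize_scalar(
        lambda lq: -_mk_symmetric_loglik(tree, x, np.exp(lq)),
        bounds=(np.log(1e-4 / h), np.log(1e3 / h)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not np.isfinite(res.fun):
        raise ValueError("Mk fit failed")
    return float(np.exp(res.x))


def _lambda_stats(inv_es: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    return float(inv_es[x == 0].mean()), float(inv_es[x == 1].mean())


def fisse_test(
    tree: Phylogeny,
    states: CharacterData,
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
    redraw_cap: int = 100,
) -> FisseResult:
    """Two-tailed simulation test of Λ0 − Λ1 against a state-neutral null.

    The null holds the tree fixed, fits a one-rate symmetric Markov model to
    the observed states, and simulates ``n_sim`` replicate characters (root
    state drawn from the 0.5/0.5 stationary distribution).  Monomorphic
    replicates are redrawn up to ``redraw_cap`` times each.  The p-value is
    twice the smaller tail proportion with the (m+1)/(n+1) correction,
    capped at 1.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    x = states.as_array(tree)
    if x.sum() in (0, tree.n_tips):
        raise ValueError("both states must be present among the tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inv_es = 1.0 / _es_all(tree)
    lam0, lam1 = _lambda_stats(inv_es, x)
    obs = lam0 - lam1
    q = fit_mk_symmetric(tree, states)
    null = np.empty(n_sim)
    for i in range(n_sim):
        for _ in range(redraw_cap):
            root = int(rng.random() < 0.5)
            sim = simulate_mk_character(tree, q, q, root, rng)
            xs = sim.as_array(tree)
            if 0 < xs.sum() < tree.n_tips:
                break
        else:
            raise RuntimeError("could not draw a polymorphic null replicate")
        a, b = _lambda_stats(inv_es, xs)
        null[i] = a - b
    ge = int(np.sum(null >= obs))
    le = int(np.sum(null <= obs))
    p = 2.0 * (min(ge, le) + 1) / (n_sim + 1)
    return FisseResult(lam0, lam1, obs, min(p, 1.0), n_sim)
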
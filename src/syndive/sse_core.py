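"""State-dependent speciation–extinction (SSE) likelihoods.

Implements the coupled character-extinction ODE pruning algorithm for binary
traits with optional hidden states: BiSSE on two expanded states, HiSSE on
four, and character-independent (CID) nulls on four or eight.  Seven named
model structures are provided:

======  =========================================================
B1      full BiSSE, all six rates free
B2      BiSSE with symmetric transitions (q01 = q10)
B3      BiSSE with irreversible gains (q10 = 0)
B4      BiSSE with state-independent diversification (λ0=λ1, μ0=μ1)
H1      full HiSSE, hidden states A/B, 8 diversification + 4 q
CID2    hidden-state-only diversification, 2 hidden classes
CID4    hidden-state-only diversification, 4 hidden classes,
        14 transition rates (8 observed flips + 6 hidden-chain moves)
======  =========================================================

Along each branch the pair (E_i, D_i) is integrated with an adaptive
Cash–Karp Runge–Kutta scheme (rtol 1e-8, atol 1e-10), with per-branch
renormalisation of D and log-scaler accumulation to avoid underflow on
trees of ~100 tips.  State-specific sampling fractions enter through the
tip initial conditions (skeleton-tree correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .treeio import CharacterData, Phylogeny, SamplingFractions

__all__ = [
    "SSEParameters",
    "ModelSpec",
    "MODEL_NAMES",
    "make_model",
    "sse_loglik",
    "net_diversification",
    "SSELikelihood",
]

MODEL_NAMES = ("B1", "B2", "B3", "B4", "H1", "CID2", "CID4")


@dataclass
class SSEParameters:
    """Per-expanded-state speciation (λ), extinction (μ) and transition (q) rates."""

    lam: np.ndarray           # (k,)
    mu: np.ndarray            # (k,)
    q: np.ndarray             # (k, k), diagonal ignored
    state_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=np.float64)
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.q = np.asarray(self.q, dtype=np.float64)
        k = self.lam.shape[0]
        if self.mu.shape != (k,) or self.q.shape != (k, k):
            raise ValueError("inconsistent parameter shapes")
        if np.any(self.lam < 0) or np.any(self.mu < 0) or np.any(self.q < 0):
            raise ValueError("rates must be non-negative")
        if not np.all(np.isfinite(self.lam)) or not np.all(np.isfinite(self.mu)) \
                or not np.all(np.isfinite(self.q)):
            raise ValueError("rates must be finite")
        np.fill_diagonal(self.q, 0.0)

    @property
    def n_states(self) -> int:
        return self.lam.shape[0]

    @property
    def r(self) -> np.ndarray:
        """Net diversification per expanded state, r_i = λ_i − μ_i."""
        return self.lam - self.mu


def net_diversification(params: SSEParameters) -> np.ndarray:
    """Net diversification rates r_i = λ_i − μ_i."""
    return params.r


@dataclass
class ModelSpec:
    """Constraint structure mapping a free-parameter vector to SSEParameters.

    ``lam_map[i]``/``mu_map[i]`` index the free vector for expanded state i;
    ``q_map[i, j]`` indexes it for the i→j transition, or -1 for a structural
    zero.  ``obs[i]`` is the observed (0/1) state an expanded state projects
    to, defining which expanded states a tip observation is compatible with.
    """

    name: str
    state_names: tuple[str, ...]
    obs: np.ndarray
    param_names: tuple[str, ...]
    param_kinds: tuple[str, ...]      # "lambda" | "mu" | "q" per free parameter
    lam_map: np.ndarray
    mu_map: np.ndarray
    q_map: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    def build_params(self, theta: np.ndarray) -> SSEParameters:
        theta = np.asarray(theta, dtype=np.float64)
        if theta.shape != (self.n_free,):
            raise ValueError(
                f"model {self.name} expects {self.n_free} parameters, got {theta.shape}")
        lam = theta[self.lam_map]
        mu = theta[self.mu_map]
        k = self.n_states
        q = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                if self.q_map[i, j] >= 0:
                    q[i, j] = theta[self.q_map[i, j]]
        return SSEParameters(lam, mu, q, self.state_names)

    def params_to_dict(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.param_names, np.asarray(theta, dtype=float)))

    def compat(self, obs_state: int) -> np.ndarray:
        """Boolean mask of expanded states compatible with an observed tip state."""
        return self.obs == obs_state


def _bisse_spec(name: str) -> ModelSpec:
    obs = np.array([0, 1])
    if name == "B1":
        names = ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10")
        lam_map, mu_map = np.array([0, 1]), np.array([2, 3])
        q_map = np.array([[-1, 4], [5, -1]])
    elif name == "B2":
        names = ("lambda0", "lambda1", "mu0", "mu1", "q")
        lam_map, mu_map = np.array([0, 1]), np.array([2, 3])
        q_map = np.array([[-1, 4], [4, -1]])
    elif name == "B3":
        names = ("lambda0", "lambda1", "mu0", "mu1", "q01")
        lam_map, mu_map = np.array([0, 1]), np.array([2, 3])
        q_map = np.array([[-1, 4], [-1, -1]])
    else:  # B4
        names = ("lambda", "mu", "q01", "q10")
        lam_map, mu_map = np.array([0, 0]), np.array([1, 1])
        q_map = np.array([[-1, 2], [3, -1]])
    kinds = tuple("lambda" if n.startswith("lambda") else
                  ("mu" if n.startswith("mu") else "q") for n in names)
    return ModelSpec(name, ("0", "1"), obs, names, kinds, lam_map, mu_map, q_map)


def _hidden2_spec(name: str) -> ModelSpec:
    # expanded states 0A, 1A, 0B, 1B
    states = ("0A", "1A", "0B", "1B")
    obs = np.array([0, 1, 0, 1])
    if name == "H1":
        names = ("lambda0A", "lambda1A", "lambda0B", "lambda1B",
                 "mu0A", "mu1A", "mu0B", "mu1B",
                 "q01", "q10", "qAB", "qBA")
        lam_map = np.array([0, 1, 2, 3])
        mu_map = np.array([4, 5, 6, 7])
        i01, i10, iAB, iBA = 8, 9, 10, 11
    else:  # CID2: diversification tied within hidden class across observed states
        names = ("lambdaA", "lambdaB", "muA", "muB", "q01", "q10", "qAB", "qBA")
        lam_map = np.array([0, 0, 1, 1])
        mu_map = np.array([2, 2, 3, 3])
        i01, i10, iAB, iBA = 4, 5, 6, 7
    # no simultaneous observed+hidden changes
    q_map = np.array([
        [-1, i01, iAB, -1],
        [i10, -1, -1, iAB],
        [iBA, -1, -1, i01],
        [-1, iBA, i10, -1],
    ])
    kinds = tuple("lambda" if n.startswith("lambda") else
                  ("mu" if n.startswith("mu") else "q") for n in names)
    return ModelSpec(name, states, obs, names, kinds, lam_map, mu_map, q_map)


def _cid4_spec() -> ModelSpec:
    # expanded states 0A, 1A, 0B, 1B, 0C, 1C, 0D, 1D
    classes = "ABCD"
    states = tuple(f"{o}{h}" for h in classes for o in "01")
    obs = np.array([0, 1] * 4)
    names = [f"lambda{h}" for h in classes] + [f"mu{h}" for h in classes]
    lam_map = np.array([0, 0, 1, 1, 2, 2, 3, 3])
    mu_map = lam_map + 4
    # 8 observed-flip rates, one pair per hidden class
    for h in classes:
        names += [f"q01{h}", f"q10{h}"]
    # 6 hidden chain rates A<->B<->C<->D, shared across observed states
    names += ["qAB", "qBA", "qBC", "qCB", "qCD", "qDC"]
    names = tuple(names)
    q_map = np.full((8, 8), -1, dtype=np.int64)
    for hi, h in enumerate(classes):
        s0, s1 = 2 * hi, 2 * hi + 1
        q_map[s0, s1] = 8 + 2 * hi       # q01 within class
        q_map[s1, s0] = 8 + 2 * hi + 1   # q10 within class
    chain = [16, 17, 18, 19, 20, 21]     # qAB qBA qBC qCB qCD qDC
    pairs = [(0, 1), (1, 2), (2, 3)]
    for (a, b), (fwd, bwd) in zip(pairs, [chain[0:2], chain[2:4], chain[4:6]]):
        for o in (0, 1):
            q_map[2 * a + o, 2 * b + o] = fwd
            q_map[2 * b + o, 2 * a + o] = bwd
    kinds = tuple("lambda" if n.startswith("lambda") else
                  ("mu" if n.startswith("mu") else "q") for n in names)
    return ModelSpec("CID4", states, obs, names, kinds, lam_map, mu_map, q_map)


def make_model(name: str) -> ModelSpec:
    """Return the constraint structure of a named model (see module docstring)."""
    if name in ("B1", "B2", "B3", "B4"):
        return _bisse_spec(name)
    if name in ("H1", "CID2"):
        return _hidden2_spec(name)
    if name == "CID4":
        return _cid4_spec()
    raise ValueError(f"unknown model name {name!r}; known: {MODEL_NAMES}")


# ---------------------------------------------------------------------------
# ODE pruning kernel (numba)

_CK_B = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0],
    [1 / 5, 0.0, 0.0, 0.0, 0.0],
    [3 / 40, 9 / 40, 0.0, 0.0, 0.0],
    [3 / 10, -9 / 10, 6 / 5, 0.0, 0.0],
    [-11 / 54, 5 / 2, -70 / 27, 35 / 27, 0.0],
    [1631 / 55296, 175 / 512, 575 / 13824, 44275 / 110592, 253 / 4096],
])
_CK_C5 = np.array([37 / 378, 0.0, 250 / 621, 125 / 594, 0.0, 512 / 1771])
_CK_C4 = np.array([2825 / 27648, 0.0, 18575 / 48384, 13525 / 55296,
                   277 / 14336, 1 / 4])


@njit(cache=True)
def _rhs(y, lam, mu, q, qrow, k, out):
    # y[:k] = E, y[k:] = D
    for i in range(k):
        E = y[i]
        acc_e = 0.0
        acc_d = 0.0
        for j in range(k):
            acc_e += q[i, j] * y[j]
            acc_d += q[i, j] * y[k + j]
        tot = lam[i] + mu[i] + qrow[i]
        out[i] = mu[i] - tot * E + lam[i] * E * E + acc_e
        out[k + i] = -tot * y[k + i] + acc_d + 2.0 * lam[i] * E * y[k + i]


@njit(cache=True)
def _integrate_branch(y, t_total, lam, mu, q, qrow, k, rtol, atol):
    """Adaptive Cash-Karp RK45 over one branch, in place.  Returns 0 on success."""
    n = 2 * k
    ks = np.empty((6, n))
    ytmp = np.empty(n)
    yerr = np.empty(n)
    y5 = np.empty(n)
    t = 0.0
    h = t_total
    max_steps = 100000
    for _ in range(max_steps):
        if t >= t_total:
            return 0
        if t + h > t_total:
            h = t_total - t
        # six stages
        _rhs(y, lam, mu, q, qrow, k, ks[0])
        for s in range(1, 6):
            for i in range(n):
                acc = 0.0
                for m in range(s):
                    acc += _CK_B[s, m] * ks[m, i]
                ytmp[i] = y[i] + h * acc
            _rhs(ytmp, lam, mu, q, qrow, k, ks[s])
        errmax = 0.0
        for i in range(n):
            acc5 = 0.0
            acc4 = 0.0
            for s in range(6):
                acc5 += _CK_C5[s] * ks[s, i]
                acc4 += _CK_C4[s] * ks[s, i]
            y5[i] = y[i] + h * acc5
            yerr[i] = h * (acc5 - acc4)
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = abs(yerr[i]) / sc
            if e > errmax:
                errmax = e
        if not np.isfinite(errmax):
            return 1
        if errmax <= 1.0:
            t += h
            for i in range(n):
                y[i] = y5[i]
            # clamp E to [0, 1] against roundoff
            for i in range(k):
                if y[i] < 0.0:
                    y[i] = 0.0
                elif y[i] > 1.0:
                    y[i] = 1.0
            fac = 5.0 if errmax == 0.0 else min(5.0, 0.9 * errmax ** -0.2)
            h *= fac
        else:
            h *= max(0.1, 0.9 * errmax ** -0.25)
            if h <= 1e-14 * t_total:
                return 1
    return 1


@njit(cache=True)
def _prune_loglik(post, parent, children, blen, n_tips, tipD, E0,
                  lam, mu, q, cond_surv, root_mode, root_fixed, rtol, atol):
    """Postorder pruning.  Returns (loglik, failed_branch_id)."""
    k = lam.shape[0]
    n_nodes = post.shape[0]
    E = np.zeros((n_nodes, k))
    D = np.zeros((n_nodes, k))
    qrow = np.zeros(k)
    for i in range(k):
        s = 0.0
        for j in range(k):
            if j != i:
                s += q[i, j]
        qrow[i] = s
    logsc = 0.0
    y = np.empty(2 * k)
    root = -1
    for idx in range(n_nodes):
        v = post[idx]
        if v < n_tips:
            for i in range(k):
                E[v, i] = E0[i]
                D[v, i] = tipD[v, i]
        else:
            c1 = children[v, 0]
            c2 = children[v, 1]
            for i in range(k):
                E[v, i] = E[c1, i]
                D[v, i] = lam[i] * D[c1, i] * D[c2, i]
        s = 0.0
        for i in range(k):
            s += D[v, i]
        if not np.isfinite(s) or s <= 0.0:
            return -np.inf, v
        for i in range(k):
            D[v, i] /= s
        logsc += np.log(s)
        if parent[v] >= 0:
            if blen[v] > 0.0:
                for i in range(k):
                    y[i] = E[v, i]
                    y[k + i] = D[v, i]
                status = _integrate_branch(y, blen[v], lam, mu, q, qrow, k, rtol, atol)
                if status != 0:
                    return -np.inf, v
                for i in range(k):
                    E[v, i] = y[i]
                    D[v, i] = y[k + i]
        else:
            root = v
    # root assembly
    d = np.empty(k)
    for i in range(k):
        d[i] = D[root, i]
    if cond_surv:
        for i in range(k):
            denom = lam[i] * (1.0 - E[root, i]) ** 2
            if denom <= 0.0:
                d[i] = 0.0
            else:
                d[i] /= denom
    tot = 0.0
    for i in range(k):
        tot += d[i]
    if not np.isfinite(tot) or tot <= 0.0:
        return -np.inf, root
    lnl = 0.0
    if root_mode == 0:      # FitzJohn weighting
        acc = 0.0
        for i in range(k):
            acc += (d[i] / tot) * d[i]
        lnl = np.log(acc)
    elif root_mode == 1:    # equal
        lnl = np.log(tot / k)
    else:                   # fixed state
        if d[root_fixed] <= 0.0:
            return -np.inf, root
        lnl = np.log(d[root_fixed])
    return lnl + logsc, -1


class SSELikelihood:
    """Reusable likelihood evaluator binding one (tree, states, model, f) tuple.

    Precomputes the flat tree arrays and tip initial conditions once, so MCMC
    can call :meth:`loglik` with just a free-parameter vector.
    """

    def __init__(
        self,
        tree: Phylogeny,
        states: CharacterData,
        spec: ModelSpec,
        f: SamplingFractions = SamplingFractions(),
        root_mode: str = "weighted",
        condition_on_survival: bool = True,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> None:
        if not tree.is_ultrametric():
            raise ValueError("SSE fitting requires an ultrametric tree")
        self.tree = tree
        self.spec = spec
        self.f = f
        self.rtol, self.atol = rtol, atol
        self.condition_on_survival = condition_on_survival
        self.root_fixed = 0
        if root_mode == "weighted":
            self.root_mode = 0
        elif root_mode == "equal":
            self.root_mode = 1
        elif root_mode.startswith("fixed"):
            self.root_mode = 2
            inside = root_mode[root_mode.find("(") + 1:root_mode.find(")")]
            self.root_fixed = list(spec.state_names).index(inside) \
                if inside in spec.state_names else int(inside)
        else:
            raise ValueError(f"unknown root_mode {root_mode!r}")
        tip_states = states.as_array(tree)
        k = spec.n_states
        fvec = np.where(spec.obs == 0, f.f0, f.f1)      # sampling fraction per expanded state
        self._E0 = 1.0 - fvec
        tipD = np.zeros((tree.n_tips, k))
        for t in range(tree.n_tips):
            mask = spec.compat(int(tip_states[t]))
            tipD[t, mask] = fvec[mask]
        self._tipD = tipD
        self._post = tree.postorder()
        self._parent = tree.parent
        self._children = tree.children
        self._blen = tree.blen

    def loglik(self, theta: np.ndarray) -> float:
        params = self.spec.build_params(theta)
        return self.loglik_params(params)

    def loglik_params(self, params: SSEParameters) -> float:
        lnl, bad = _prune_loglik(
            self._post, self._parent, self._children, self._blen,
            self.tree.n_tips, self._tipD, self._E0,
            params.lam, params.mu, params.q,
            self.condition_on_survival, self.root_mode, self.root_fixed,
            self.rtol, self.atol,
        )
        return float(lnl)  # -inf carries integration failure (branch id in `bad`)


def sse_loglik(
    tree: Phylogeny,
    states: CharacterData,
    spec: ModelSpec,
    params: SSEParameters | np.ndarray,
    f: SamplingFractions = SamplingFractions(),
    root_mode: str = "weighted",
    condition_on_survival: bool = True,
) -> float:
    """Log-likelihood of the tree and tip states under an SSE model.

    ``params`` may be an :class:`SSEParameters` on the model's expanded states
    or a free-parameter vector in ``spec.param_names`` order.
    """
    ev = SSELikelihood(tree, states, spec, f, root_mode, condition_on_survival)
    if isinstance(params, SSEParameters):
        if params.n_states != spec.n_states:
            raise ValueError("parameter/state dimension mismatch")
        return ev.loglik_params(params)
    return ev.loglik(np.asarray(params, dtype=float))
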
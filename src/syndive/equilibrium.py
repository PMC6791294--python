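"""Deterministic dynamics of expected state proportions under a two-state SSE process.

With net diversification rates r0, r1 and transition rates q01, q10 held
constant, the expected lineage counts obey

    dn0/dt = r0 n0 - q01 n0 + q10 n1
    dn1/dt = r1 n1 + q01 n0 - q10 n1

so the expected state-1 proportion p = n1/(n0+n1) follows the scalar flow

    dp/dt = (r1 - r0) p (1 - p) + q01 (1 - p) - q10 p.

The equilibrium proportion is the stable root of this quadratic in [0, 1]
(equivalently the dominant-eigenvector proportion of the 2x2 rate matrix).
Time is measured in root-height units (root height normalised to 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "EquilibriumResult",
    "proportion_dynamics",
    "equilibrium_proportion",
    "time_to_fraction",
    "posterior_equilibrium",
]


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium proportion and the time to reach a stated fraction of it."""

    p1_star: float
    t90: float
    trajectory: tuple[np.ndarray, np.ndarray] | None = None   # (t, p1)


def _rates(params) -> tuple[float, float, float, float]:
    """Extract (r0, r1, q01, q10) from SSEParameters or a 4-tuple."""
    if hasattr(params, "lam"):
        if params.n_states != 2:
            raise ValueError("equilibrium dynamics require a 2-state parameterisation")
        r = params.r
        return float(r[0]), float(r[1]), float(params.q[0, 1]), float(params.q[1, 0])
    r0, r1, q01, q10 = params
    return float(r0), float(r1), float(q01), float(q10)


def _flow(p: float, r0: float, r1: float, q01: float, q10: float) -> float:
    return (r1 - r0) * p * (1.0 - p) + q01 * (1.0 - p) - q10 * p


def proportion_dynamics(params, p1_0: float, t_grid: np.ndarray) -> np.ndarray:
    """Integrate p1(t) on a time grid from initial proportion ``p1_0``."""
    r0, r1, q01, q10 = _rates(params)
    if not (0.0 <= p1_0 <= 1.0):
        raise ValueError("p1_0 must be in [0, 1]")
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        lambda t, y: _flow(y[0], r0, r1, q01, q10),
        (0.0, float(t_grid[-1])), [p1_0],
        t_eval=t_grid, rtol=1e-10, atol=1e-12, method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"proportion integration failed: {sol.message}")
    return np.clip(sol.y[0], 0.0, 1.0)


def equilibrium_proportion(params) -> float:
    """Stable root in [0, 1] of the proportion flow.

    Degenerate when r0 = r1 and both transition rates are zero (every p is a
    fixed point).
    """
    r0, r1, q01, q10 = _rates(params)
    dlt = r1 - r0
    if abs(dlt) < 1e-14:
        if q01 + q10 <= 0:
            raise ValueError(
                "degenerate dynamics: r0 = r1 with q01 = q10 = 0 has no unique equilibrium")
        return q01 / (q01 + q10)
    # dlt*p^2 + (q01 + q10 - dlt)*p - q01 = 0
    a, b, c = dlt, (q01 + q10 - dlt), -q01
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("no real equilibrium (should not happen for non-negative q)")
    roots = [(-b - math.sqrt(disc)) / (2 * a), (-b + math.sqrt(disc)) / (2 * a)]
    stable = [p for p in roots if -1e-12 <= p <= 1 + 1e-12
              and (dlt * (1.0 - 2.0 * p) - (q01 + q10)) < 0]
    if not stable:
        raise ValueError("no stable equilibrium in [0, 1]")
    return float(min(max(stable[0], 0.0), 1.0))


def time_to_fraction(
    params, fraction: float = 0.9, p1_0: float = 0.0, t_max: float = 1000.0
) -> float:
    """First time p1(t) reaches ``fraction`` x p1_star, approaching from below.

    Returns 0 when the initial proportion is already at or beyond the target.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    r0, r1, q01, q10 = _rates(params)
    p_star = equilibrium_proportion(params)
    target = fraction * p_star
    if p1_0 >= target:
        return 0.0

    def event(t, y):
        return y[0] - target

    event.terminal = True
    event.direction = 1
    sol = solve_ivp(
        lambda t, y: _flow(y[0], r0, r1, q01, q10),
        (0.0, t_max), [p1_0], events=event,
        rtol=1e-10, atol=1e-12, method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    if len(sol.t_events[0]) == 0:
        raise RuntimeError(f"target fraction not reached within t_max={t_max}")
    return float(sol.t_events[0][0])


def posterior_equilibrium(
    posterior, fraction: float = 0.9, p1_0: float = 0.0
):
    """Per-draw equilibrium results over a posterior sample.

    ``posterior`` is a :class:`syndive.inference.PosteriorSet` whose model has
    two observed states (BiSSE-type).  Draws hitting the degenerate condition
    are dropped and counted.  Returns a dict with arrays ``p1_star``, ``t90``,
    summary percentiles, and ``n_degenerate``.
    """
    draws = posterior.parameter_draws()
    p1s, t90s = [], []
    n_deg = 0
    for params in draws:
        try:
            p1 = equilibrium_proportion(params)
            t9 = time_to_fraction(params, fraction, p1_0)
        except ValueError:
            n_deg += 1
            continue
        p1s.append(p1)
        t90s.append(t9)
    p1s, t90s = np.asarray(p1s), np.asarray(t90s)
    if p1s.size == 0:
        raise ValueError("all posterior draws were degenerate")

    def summ(x):
        return {
            "median": float(np.median(x)),
            "q2.5": float(np.percentile(x, 2.5)),
            "q97.5": float(np.percentile(x, 97.5)),
        }

    return {
        "p1_star": p1s,
        "t90": t90s,
        "summary_p1_star": summ(p1s),
        "summary_t90": summ(t90s),
        "n_degenerate": n_deg,
    }
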
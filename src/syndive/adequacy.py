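"""Posterior-predictive model adequacy.

Trees are simulated from parameters drawn (with replacement) out of a
posterior sample, each scored with the four tippiness metrics, and the
empirical dataset's metrics are located within the simulated distributions:
a model is inadequate for a metric when the empirical value falls outside
the central 95% interval of its posterior-predictive distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylometrics import MetricSet, compute_metrics
from .simulate import simulate_sse_tree

__all__ = ["AdequacyReport", "posterior_predictive", "compare_empirical"]

METRICS = ("n1", "tpo", "sscd", "tars")


@dataclass
class AdequacyReport:
    """Per-metric simulated distributions and the empirical value's position."""

    table: pd.DataFrame          # rows: metric; cols: lo, hi, empirical, percentile, inside, n_valid
    samples: dict[str, np.ndarray]
    n_reps: int
    n_failed: int                # replicates lost to the simulator retry cap
    n_monomorphic: int           # replicates with no state-1 tips

    def outside(self) -> list[str]:
        return [m for m in self.table.index if self.table.loc[m, "inside"] is False]

    def to_text(self) -> str:
        lines = [f"posterior predictive adequacy ({self.n_reps} replicates, "
                 f"{self.n_monomorphic} monomorphic, {self.n_failed} failed)"]
        for m, row in self.table.iterrows():
            flag = "inside" if row["inside"] else "OUTSIDE"
            lines.append(
                f"  {m:>5}: 95% interval [{row['lo']:.4g}, {row['hi']:.4g}]  "
                f"empirical {row['empirical']:.4g}  percentile {row['percentile']:.1f}  {flag}")
        return "\n".join(lines)


def posterior_predictive(
    posterior,
    n_tips: int,
    n_reps: int = 1000,
    seed: int | None = None,
    root_state: int = 0,
    max_failure_fraction: float = 0.2,
) -> tuple[list[MetricSet], int, int]:
    """Simulate ``n_reps`` trees from posterior draws and score the four metrics.

    Each replicate resamples one posterior draw (with replacement), simulates a
    tree of ``n_tips``, and computes the MetricSet.  Monomorphic replicates are
    kept with n1 = 0 and NaN tpo/tars.  Returns (metric sets, n_failed,
    n_monomorphic); aborts if more than ``max_failure_fraction`` of replicates
    exhaust the simulator retry cap.
    """
    if len(posterior) < 1:
        raise ValueError("posterior must be nonempty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    spec = posterior.spec
    obs_map = spec.obs
    out: list[MetricSet] = []
    n_failed = 0
    n_mono = 0
    for _ in range(n_reps):
        theta = posterior.draws[rng.integers(len(posterior))]
        params = spec.build_params(theta)
        try:
            ds = simulate_sse_tree(params, n_tips, root_state, rng,
                                   max_retries=100, obs_map=obs_map)
        except RuntimeError:
            n_failed += 1
            if n_failed > max_failure_fraction * n_reps:
                raise RuntimeError(
                    f"more than {max_failure_fraction:.0%} of replicates failed to simulate")
            continue
        ms = compute_metrics(ds.tree, ds.states)
        if ms.n1 == 0:
            n_mono += 1
        out.append(ms)
    return out, n_failed, n_mono


def _midrank_percentile(sample: np.ndarray, value: float) -> float:
    below = np.sum(sample < value)
    equal = np.sum(sample == value)
    return 100.0 * (below + 0.5 * equal) / sample.size


def compare_empirical(
    replicates: list[MetricSet],
    empirical: MetricSet,
    n_failed: int = 0,
    n_monomorphic: int = 0,
    min_valid: int = 100,
) -> AdequacyReport:
    """Locate the empirical metrics within the posterior-predictive distributions.

    Percentiles use the midrank convention; the 95% interval is the 2.5/97.5
    empirical percentile pair.  A metric with fewer than ``min_valid``
    non-missing replicates is flagged unusable (NaN row, inside = None).
    """
    rows = {}
    samples = {}
    emp = empirical.as_dict()
    for m in METRICS:
        vals = np.array([getattr(r, m) for r in replicates], dtype=float)
        vals = vals[np.isfinite(vals)]
        samples[m] = vals
        if vals.size < min_valid or not np.isfinite(emp[m]):
            rows[m] = dict(lo=np.nan, hi=np.nan, empirical=emp[m],
                           percentile=np.nan, inside=None, n_valid=vals.size)
            continue
        lo, hi = np.percentile(vals, [2.5, 97.5])
        pct = _midrank_percentile(vals, emp[m])
        rows[m] = dict(lo=lo, hi=hi, empirical=emp[m], percentile=pct,
                       inside=bool(lo <= emp[m] <= hi), n_valid=vals.size)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["inside"] = pd.Series({m: rows[m]["inside"] for m in rows}, dtype=object)
    return AdequacyReport(table=table, samples=samples,
                          n_reps=len(replicates) + n_failed,
                          n_failed=n_failed, n_monomorphic=n_monomorphic)
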
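"""Sample-representativeness simulation for flawed-tree fractions.

Field permits in protected areas fix the number of increment cores in
advance, and some cored trees always turn out unusable (rot, fungus,
increment anomalies).  How badly does a small random sample misestimate
the population fraction of such "flawed" trees?  This module repeats the
experiment in silico: draw without replacement from a pool of N virtual
trees of which K carry the flawed attribute, record the flawed fraction
per draw, and summarize over replications for each sample size.  The
number of flawed trees in a draw of size n is hypergeometric, so the
closed-form moments serve as an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


@dataclass(frozen=True)
class SamplingPool:
    """N virtual objects, K of which carry the flawed attribute."""

    n_total: int
    n_flawed: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("pool must contain at least one object")
        if not 0 <= self.n_flawed <= self.n_total:
            raise ValueError("need 0 <= n_flawed <= n_total")

    @property
    def true_fraction(self) -> float:
        return self.n_flawed / self.n_total


@dataclass(frozen=True)
class RepresentativenessResult:
    """Per-size summaries of the flawed fraction over replications.

    ``table`` columns: size, mean_frac, sd_frac, se_frac (SD/sqrt(reps)),
    and the percentage-scale duplicates mean_pct/sd_pct/se_pct.
    """

    table: pd.DataFrame
    reps: int
    seed: int
    pool: SamplingPool


def default_size_grid(pool: SamplingPool, step: int = 5) -> list[int]:
    """Sample sizes step, 2*step, ... up to N (N always included)."""
    sizes = list(range(step, pool.n_total + 1, step))
    if sizes[-1] != pool.n_total:
        sizes.append(pool.n_total)
    return sizes


def _draw_counts(
    rng: np.random.Generator, pool: SamplingPool, size: int, reps: int
) -> np.ndarray:
    """Flawed counts in ``reps`` independent without-replacement draws.

    Each draw is an explicit random subset of the N object indices
    (first ``size`` positions of an independent random permutation), so
    no index can repeat within a draw; indices < K are the flawed ones.
    """
    order = np.argsort(rng.random((reps, pool.n_total)), axis=1)
    return np.sum(order[:, :size] < pool.n_flawed, axis=1)


def simulate_sampling(
    pool: SamplingPool,
    sizes: list[int] | None = None,
    reps: int = 5000,
    seed: int = 0,
) -> RepresentativenessResult:
    """Monte-Carlo estimate of the flawed fraction for each sample size.

    For every size, ``reps`` independent draws without replacement are
    taken from the pool and the per-draw flawed fraction recorded.
    Fully reproducible given ``seed``.
    """
    if sizes is None:
        sizes = default_size_grid(pool)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for n in sizes:
        if not 1 <= n <= pool.n_total:
            raise ValueError(f"sample size {n} outside [1, {pool.n_total}]")
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        frac = _draw_counts(rng, pool, n, reps) / n
        sd = float(np.std(frac, ddof=1)) if reps > 1 else np.nan
        rows.append(
            {
                "size": n,
                "mean_frac": float(np.mean(frac)),
                "sd_frac": sd,
                "se_frac": sd / np.sqrt(reps) if reps > 1 else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    for col in ("mean", "sd", "se"):
        table[f"{col}_pct"] = table[f"{col}_frac"] * 100.0
    return RepresentativenessResult(table=table, reps=reps, seed=seed, pool=pool)


def analytic_moments(pool: SamplingPool, size: int) -> tuple[float, float]:
    """Exact mean and SD of the flawed fraction in one draw of ``size``.

    The flawed count is Hypergeometric(N, K, size): E = K/N and
    Var = (K/N)(1-K/N)/size * (N-size)/(N-1), the binomial variance
    shrunk by the finite-population correction (0 at size = N).
    """
    if not 1 <= size <= pool.n_total:
        raise ValueError(f"size {size} outside [1, {pool.n_total}]")
    p = pool.true_fraction
    if pool.n_total == 1:
        return p, 0.0
    fpc = (pool.n_total - size) / (pool.n_total - 1)
    return p, float(np.sqrt(p * (1.0 - p) / size * fpc))


def convergence_report(
    result: RepresentativenessResult, pool: SamplingPool | None = None
) -> pd.DataFrame:
    """Per-size deviation from the population fraction and SE trend.

    Adds |mean - K/N| and the analytic SD; the frame's ``attrs`` carry
    the Spearman correlation of SE vs size (strongly negative when the
    estimate tightens with sample size, the expected behaviour).
    """
    pool = pool or result.pool
    t = result.table.copy()
    t["abs_dev_frac"] = (t["mean_frac"] - pool.true_fraction).abs()
    t["analytic_sd_frac"] = [analytic_moments(pool, n)[1] for n in t["size"]]
    if result.reps > 1 and len(t) > 1:
        rho, p = spearmanr(t["size"], t["se_frac"])
        t.attrs["spearman_se_vs_size"] = float(rho)
        t.attrs["spearman_p"] = float(p)
    else:
        t.attrs["spearman_se_vs_size"] = None
        t.attrs["spearman_p"] = None
    return t
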
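"""Descriptive and chronology statistics for grouped ring-width series.

Implements the standard dendro quality statistics: pooled descriptive
stats of TRW per plot/zone group, Douglass mean sensitivity,
Gleichläufigkeit (GLK, sign-agreement of year-to-year changes), mean
inter-series correlation r-bar, and the Wigley expressed population
signal EPS = n*rbar / (n*rbar + (1 - rbar)).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import RingDataError, RingDataset, RingSeries, exclude_flawed, mean_annual_increment


@dataclass(frozen=True)
class SeriesGroupStats:
    plot: str
    zone: str
    studied_period: tuple[int, int]
    n_bored: int
    n_flawed: int
    min_trw: float
    max_trw: float
    mean_trw: float
    sd_trw: float


@dataclass(frozen=True)
class ChronologyStats:
    mean_sensitivity: float
    glk: float
    rbar: float
    eps: float | None
    n_series: int


def descriptive_stats(
    dataset: RingDataset, group_by: Sequence[str] = ("plot", "zone")
) -> pd.DataFrame:
    """Min/max/mean/SD of TRW pooled over all rings within each group,
    plus bored/flawed counts and the studied period."""
    group_by = tuple(group_by)
    keys = sorted(
        {
            (s.plot_id if "plot" in group_by else "", s.zone if "zone" in group_by else "")
            for s in dataset.series
        }
    )
    rows = []
    for plot, zone in keys:
        members = [
            s
            for s in dataset.series
            if ("plot" not in group_by or s.plot_id == plot)
            and ("zone" not in group_by or s.zone == zone)
        ]
        kept = [s for s in members if not s.flawed]
        if not kept:
            raise RingDataError(f"group ({plot!r}, {zone!r}) empty after flaw exclusion")
        pooled = np.concatenate([s.widths for s in kept])
        rows.append(
            {
                "plot": plot,
                "zone": zone,
                "period_start": min(s.first_year for s in kept),
                "period_end": max(s.last_year for s in kept),
                "n_bored": len(members),
                "n_flawed": sum(s.flawed for s in members),
                "min_trw": float(pooled.min()),
                "max_trw": float(pooled.max()),
                "mean_trw": float(pooled.mean()),
                "sd_trw": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def mean_sensitivity(series: RingSeries | np.ndarray) -> float:
    """Douglass mean sensitivity: average of |2(w_t - w_{t-1}) / (w_t + w_{t-1})|
    over the n-1 year-to-year intervals.  Scale-invariant, in [0, 2]."""
    w = series.widths if isinstance(series, RingSeries) else np.asarray(series, float)
    if w.size < 2:
        raise RingDataError("mean sensitivity needs >= 2 rings")
    if not np.all(w > 0):
        raise RingDataError("mean sensitivity needs positive widths")
    return float(np.mean(np.abs(2.0 * np.diff(w) / (w[1:] + w[:-1]))))


def group_mean_sensitivity(dataset: RingDataset) -> float:
    """Unweighted mean of per-series sensitivities (not MS of the mean)."""
    data = exclude_flawed(dataset)
    vals = [mean_sensitivity(s) for s in data.series if len(s) >= 2]
    if not vals:
        raise RingDataError("no series long enough for mean sensitivity")
    return float(np.mean(vals))


def _sign(x: np.ndarray) -> np.ndarray:
    return np.sign(x)


def glk(a: RingSeries | pd.Series, b: RingSeries | pd.Series) -> float:
    """Gleichläufigkeit of two dated series over their common overlap.

    Per year-to-year interval the score is 1 - |s_a - s_b| / 2 with
    s = sign of the first difference: both-zero scores 1, one-zero 0.5,
    opposite signs 0.  GLK is the mean interval score.
    """
    sa = a.to_pandas() if isinstance(a, RingSeries) else a
    sb = b.to_pandas() if isinstance(b, RingSeries) else b
    common = sa.index.intersection(sb.index)
    if len(common) < 2:
        raise RingDataError("GLK needs an overlap of >= 2 years")
    da = _sign(np.diff(sa.loc[common].to_numpy()))
    db = _sign(np.diff(sb.loc[common].to_numpy()))
    return float(np.mean(1.0 - 0.5 * np.abs(da - db)))


def dataset_glk(dataset: RingDataset, min_overlap: int = 2) -> float:
    """Unweighted mean GLK over all series pairs with sufficient overlap."""
    data = exclude_flawed(dataset)
    vals = []
    for a, b in itertools.combinations(data.series, 2):
        overlap = len(
            range(max(a.first_year, b.first_year), min(a.last_year, b.last_year) + 1)
        )
        if overlap < max(min_overlap, 2):
            warnings.warn(f"GLK pair ({a.tree_id}, {b.tree_id}) skipped: overlap {overlap}")
            continue
        vals.append(glk(a, b))
    if not vals:
        raise RingDataError("no series pairs with sufficient overlap")
    return float(np.mean(vals))


def _negexp_detrend(widths: np.ndarray) -> np.ndarray:
    """Ratio indices from a modified negative exponential age curve.

    Fits w = a * exp(-b*t) + k (a, b > 0, k >= 0) over cambial age t and
    returns w / fit; falls back to the horizontal mean when the fit
    fails, is non-decreasing, or the curve is not strictly positive.
    """
    t = np.arange(widths.size, dtype=float)
    fallback = np.full_like(widths, widths.mean())
    if widths.size < 4 or np.all(widths == widths[0]):
        return widths / fallback

    def resid(p):
        a, b, k = p
        return a * np.exp(-b * t) + k - widths

    rng_span = widths.max() - widths.min()
    p0 = [max(rng_span, 1e-3), 1.0 / max(widths.size, 2), max(widths.min(), 1e-3)]
    try:
        sol = least_squares(
            resid, p0, bounds=([1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf])
        )
        a, b, k = sol.x
        curve = a * np.exp(-b * t) + k
        if sol.success and np.all(curve > 0):
            return widths / curve
    except Exception:
        pass
    return widths / fallback


def rbar_eps(
    dataset: RingDataset, detrend: str = "negexp_per_series", min_overlap: int = 10
) -> tuple[float, float | None]:
    """Mean pairwise inter-series correlation and the expressed
    population signal EPS = n*rbar / (n*rbar + (1 - rbar)).

    ``detrend='negexp_per_series'`` correlates ratio indices after a
    per-series modified negative exponential fit (the usual chronology
    practice); ``'none'`` correlates raw widths.  EPS is None (undefined)
    when rbar <= 0.
    """
    data = exclude_flawed(dataset)
    if len(data) < 2:
        raise RingDataError("rbar/EPS needs >= 2 series")
    if detrend not in ("none", "negexp_per_series"):
        raise RingDataError(f"unknown detrend option {detrend!r}")
    indexed = {}
    for s in data.series:
        w = s.widths if detrend == "none" else _negexp_detrend(s.widths)
        indexed[s.tree_id] = pd.Series(w, index=s.years)
    cors = []
    for (ida, sa), (idb, sb) in itertools.combinations(indexed.items(), 2):
        common = sa.index.intersection(sb.index)
        if len(common) < min_overlap:
            continue
        va, vb = sa.loc[common].to_numpy(), sb.loc[common].to_numpy()
        if np.std(va) == 0 or np.std(vb) == 0:
            continue
        cors.append(float(np.corrcoef(va, vb)[0, 1]))
    if not cors:
        raise RingDataError(f"no series pairs overlap >= {min_overlap} years")
    rbar = float(np.mean(cors))
    n = len(data)
    if rbar <= 0:
        return rbar, None
    eps = n * rbar / (n * rbar + (1.0 - rbar))
    return rbar, float(eps)


def eps_from_rbar(rbar: float, n: int) -> float:
    """Wigley EPS closed form for a chronology of n series."""
    if rbar <= 0:
        raise RingDataError("EPS undefined for rbar <= 0")
    return n * rbar / (n * rbar + (1.0 - rbar))


def chronology_stats(
    dataset: RingDataset, detrend: str = "negexp_per_series", min_overlap: int = 10
) -> ChronologyStats:
    rbar, eps = rbar_eps(dataset, detrend=detrend, min_overlap=min_overlap)
    return ChronologyStats(
        mean_sensitivity=group_mean_sensitivity(dataset),
        glk=dataset_glk(dataset),
        rbar=rbar,
        eps=eps,
        n_series=len(exclude_flawed(dataset)),
    )


def build_chronology(
    dataset: RingDataset,
    group_by: Sequence[str] = ("plot", "zone"),
    reference_zone: str = "control",
) -> pd.DataFrame:
    """Per-group year-indexed mean normalized increment.

    Expects z-units (apply :func:`dendrotramp.io.normalize_global`
    first).  Control-zone columns are the reference trends the trampled
    track-zone chronologies are compared against; the frame carries a
    ``reference_columns`` attribute listing them.
    """
    if dataset.units != "z":
        raise RingDataError("build_chronology expects a normalized (z-units) dataset")
    means, counts = mean_annual_increment(dataset, group_by=group_by)
    means.attrs["reference_columns"] = [
        c for c in means.columns if c.split("/")[-1] == reference_zone
    ]
    means.attrs["counts"] = counts
    return means
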
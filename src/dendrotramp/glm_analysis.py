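"""Joint model of ring size against calendar year, study plot and zone.

Tree-level ring observations are modelled with a Gaussian GLM and
identity link (equivalent to OLS on the same design):

    width ~ intercept + plot + zone + year

The categorical terms are dummy-coded against configurable reference
levels, so the reported contrasts are the non-reference plot and zone
effects; with no interactions the model has three non-intercept terms.
Per-term Wald chi-square statistics ((estimate/SE)^2, 1 df) and an
overall likelihood-ratio chi-square against the intercept-only model
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import RingDataError, RingDataset, exclude_flawed


@dataclass(frozen=True)
class GLMResult:
    """Term table plus overall fit of the year/plot/zone ring model."""

    table: pd.DataFrame  # index: term; columns: estimate, se, wald_chi2, p
    model_chi2: float
    df: int
    model_p: float
    n_obs: int
    response: str

    def estimate(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])


def rings_long(dataset: RingDataset) -> pd.DataFrame:
    """Tree x year long table of ring observations (flawed excluded)."""
    data = exclude_flawed(dataset)
    if not len(data):
        raise RingDataError("no series remain after flaw exclusion")
    rows = []
    for s in data.series:
        rows.append(
            pd.DataFrame(
                {
                    "tree": s.tree_id,
                    "plot": s.plot_id,
                    "zone": s.zone,
                    "year": s.years,
                    "width": s.widths,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def fit_glm(
    dataset: RingDataset,
    response: str = "raw_mm",
    ref_plot: str | None = None,
    ref_zone: str = "track",
    per_year_means: bool = False,
) -> GLMResult:
    """Fit the Gaussian identity-link GLM of ring size on year, plot, zone.

    ``response='raw_mm'`` expects a mm dataset; ``'normalized'`` a
    z-units one.  ``ref_plot`` (default: first plot in sorted order)
    and ``ref_zone`` choose the dummy-coding baselines, so the reported
    contrasts are the other plot and the other zone.
    ``per_year_means=True`` collapses rings to per plot/zone/year means
    before fitting (the default keeps tree-level rings).
    """
    if response not in ("raw_mm", "normalized"):
        raise RingDataError(f"unknown response {response!r}")
    expected_units = "mm" if response == "raw_mm" else "z"
    if dataset.units != expected_units:
        raise RingDataError(
            f"response {response!r} expects a {expected_units!r}-units dataset, got {dataset.units!r}"
        )
    df = rings_long(dataset)
    if per_year_means:
        df = (
            df.groupby(["plot", "zone", "year"], as_index=False)["width"].mean()
        )
    plots = sorted(df["plot"].unique())
    zones = sorted(df["zone"].unique())
    if len(plots) < 2:
        raise RingDataError("factor 'plot' has a single level")
    if len(zones) < 2:
        raise RingDataError("factor 'zone' has a single level")
    if ref_plot is None:
        ref_plot = plots[0]
    if ref_plot not in plots or ref_zone not in zones:
        raise RingDataError("reference level not present in the data")
    if not np.all(np.isfinite(df["width"])):
        raise RingDataError("response contains non-finite values")

    terms = ["Intercept"]
    cols = [np.ones(len(df))]
    for p in plots:
        if p != ref_plot:
            terms.append(f"plot[{p}]")
            cols.append((df["plot"] == p).to_numpy(float))
    for z in zones:
        if z != ref_zone:
            terms.append(f"zone[{z}]")
            cols.append((df["zone"] == z).to_numpy(float))
    terms.append("year")
    cols.append(df["year"].to_numpy(float))
    X = np.column_stack(cols)
    y = df["width"].to_numpy(float)

    model = sm.GLM(y, X, family=sm.families.Gaussian(sm.families.links.Identity()))
    res = model.fit()
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Gaussian()).fit()
    lr = 2.0 * (res.llf - null.llf)
    k = X.shape[1] - 1
    table = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "wald_chi2": (res.params / res.bse) ** 2,
            "p": stats.chi2.sf((res.params / res.bse) ** 2, 1),
        },
        index=terms,
    )
    return GLMResult(
        table=table,
        model_chi2=float(lr),
        df=k,
        model_p=float(stats.chi2.sf(lr, k)),
        n_obs=int(len(y)),
        response=response,
    )
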
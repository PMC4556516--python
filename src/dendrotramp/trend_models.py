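"""Growth-trend fitting, model selection and curve comparison.

Five candidate families describe how (normalized) ring increments change
with calendar year x (u = x - x0 + 1 counts years from the series start):

* linear     y = b0 + b1*x
* negexp     y = a*exp(-b*(x - x0)) + k          (a, b > 0) — the classic
  age-trend form for long-term increment decline
* log        y = b0 + b1*ln(u)
* poly3      cubic in (x - mean(x))
* weibull    y = a*(u/c)^(b-1)*exp(-(u/c)^b)     (a, b, c > 0) — a scaled
  Weibull-density shape for rise-then-decline ontogeny

Selection is by maximum R²; the conservative alternative keeps the line
unless another family's absolute residuals are significantly smaller.
Same-family curves fitted to two groups are compared with an
extra-sum-of-squares F test of "parallelism" (shared shape, free
vertical offsets vs fully separate curves), and group differences under
one pooled fit with a Welch t test on the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

FAMILIES = ("linear", "negexp", "log", "poly3", "weibull")

#: parameter count per family (including any intercept-like term)
N_PARAMS = {"linear": 2, "negexp": 3, "log": 2, "poly3": 4, "weibull": 3}

_HAS_INTERCEPT = {"linear", "log", "poly3"}


class FitError(RuntimeError):
    """Raised when a trend fit cannot be computed or does not converge."""


@dataclass(frozen=True)
class TrendFit:
    """A fitted growth-trend model.

    ``f_stat``/``p_value`` come from the regression F test with
    (n_params - 1, n - n_params) degrees of freedom; for the nonlinear
    families the same R²-based F is reported as a descriptive analogue.
    """

    family: str
    params: np.ndarray
    param_names: tuple[str, ...]
    r_squared: float
    f_stat: float
    p_value: float
    residuals: np.ndarray
    fitted: np.ndarray
    x: np.ndarray
    y: np.ndarray
    n_points: int
    n_params: int
    x0: float
    x_center: float
    selection: dict | None = None

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    @property
    def slope(self) -> float:
        """Linear-family slope coefficient (b1)."""
        if self.family != "linear":
            raise FitError("slope defined only for the linear family")
        return float(self.params[1])

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _predict(self.family, self.params, np.asarray(x, float), self.x0, self.x_center)


# ---------------------------------------------------------------------------
# model functions


def _design(family: str, x: np.ndarray, x0: float, x_center: float) -> np.ndarray:
    """Design matrix for the linear-in-parameters families."""
    if family == "linear":
        return np.column_stack([np.ones_like(x), x])
    if family == "log":
        return np.column_stack([np.ones_like(x), np.log(x - x0 + 1.0)])
    if family == "poly3":
        xc = x - x_center
        return np.column_stack([np.ones_like(x), xc, xc**2, xc**3])
    raise FitError(f"{family} is not linear-in-parameters")


def _predict(family: str, params: np.ndarray, x: np.ndarray, x0: float, x_center: float) -> np.ndarray:
    if family in ("linear", "log", "poly3"):
        return _design(family, x, x0, x_center) @ params
    if family == "negexp":
        a, b, k = params
        return a * np.exp(-b * (x - x0)) + k
    if family == "weibull":
        a, b, c = params
        u = x - x0 + 1.0
        z = u / c
        return a * z ** (b - 1.0) * np.exp(-(z**b))
    raise FitError(f"unknown family {family!r}")


def _r2_f_p(y: np.ndarray, resid: np.ndarray, n_params: int) -> tuple[float, float, float]:
    n = y.size
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(resid**2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)
    df1, df2 = n_params - 1, n - n_params
    if df2 <= 0:
        raise FitError("not enough points for the requested family")
    if rss <= 1e-14 * max(tss, 1.0):
        return r2, np.inf, 0.0
    f = (r2 / df1) / ((1.0 - r2) / df2) if r2 < 1.0 else np.inf
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return r2, float(f), p


def _negexp_starts(x, y, x0, rng):
    span = float(y.max() - y.min())
    span = span if span > 0 else 1.0
    xr = float(x.max() - x0) or 1.0
    base = [
        (span, 2.0 / xr, float(y.min())),
        (span, 0.5 / xr, float(y.min())),
        (2 * span, 5.0 / xr, float(y.mean())),
    ]
    # log-linear pre-fit of (y - k0) where positive
    k0 = float(y.min()) - 0.05 * span
    pos = y - k0 > 0
    if pos.sum() > 2:
        sl, ic = np.polyfit(x[pos] - x0, np.log(y[pos] - k0), 1)
        if sl < 0:
            base.append((float(np.exp(ic)), float(-sl), k0))
    while len(base) < 5:
        base.append(
            (span * rng.uniform(0.3, 3.0), rng.uniform(0.1, 10.0) / xr, float(y.min()) + span * rng.uniform(-0.5, 0.5))
        )
    return base


def _weibull_starts(x, y, x0, rng):
    u = x - x0 + 1.0
    umax = float(u.max())
    apk = float(y.max()) if y.max() > 0 else 1.0
    base = [
        (apk * np.e, 2.0, max(umax / 3.0, 1.0)),
        (apk * np.e, 1.5, max(umax / 2.0, 1.0)),
        (apk, 1.01, umax),
    ]
    while len(base) < 5:
        base.append(
            (apk * rng.uniform(0.5, 5.0), rng.uniform(1.0, 4.0), umax * rng.uniform(0.2, 1.5))
        )
    return base


def fit_trend(
    x: np.ndarray, y: np.ndarray, family: str, seed: int = 0
) -> TrendFit:
    """Least-squares fit of one family to a year-indexed series.

    The nonlinear families (negexp, weibull) use bounded multi-start
    least squares: five seeded starts from data-driven heuristics, best
    RSS wins; non-convergence of every start raises :class:`FitError`.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if family not in FAMILIES:
        raise FitError(f"unknown family {family!r}; choose from {FAMILIES}")
    if x.size != y.size:
        raise FitError("x and y must have equal length")
    if np.any(np.diff(x) < 0):
        # ties are allowed so pooled two-group fits can share years
        raise FitError("x must be sorted in non-decreasing order")
    p = N_PARAMS[family]
    if x.size <= p + 1:
        raise FitError(f"{family} needs more than {p + 1} points, got {x.size}")
    x0 = float(x[0])
    x_center = float(x.mean())

    if family in _HAS_INTERCEPT:
        X = _design(family, x, x0, x_center)
        params, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ params
    else:
        rng = np.random.default_rng(seed)
        starts = (_negexp_starts if family == "negexp" else _weibull_starts)(x, y, x0, rng)
        lo = np.full(3, 1e-12)
        hi = np.full(3, np.inf)
        if family == "negexp":
            lo[2], hi[2] = -np.inf, np.inf  # level k is unconstrained

        def resid_fn(params):
            return _predict(family, params, x, x0, x_center) - y

        best = None
        for p0 in starts:
            p0 = np.clip(np.asarray(p0, float), lo + 1e-12, None)
            try:
                sol = least_squares(
                    resid_fn, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-10, max_nfev=5000
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success:
            best_msg = "no start converged" if best is None else best.message
            raise FitError(f"{family} fit failed after multi-start: {best_msg}")
        params = best.x
        fitted = _predict(family, params, x, x0, x_center)

    resid = y - fitted
    r2, f, pval = _r2_f_p(y, resid, p)
    names = {
        "linear": ("b0", "b1"),
        "log": ("b0", "b1"),
        "poly3": ("b0", "b1", "b2", "b3"),
        "negexp": ("a", "b", "k"),
        "weibull": ("a", "b", "c"),
    }[family]
    return TrendFit(
        family=family,
        params=np.asarray(params, float),
        param_names=names,
        r_squared=r2,
        f_stat=f,
        p_value=pval,
        residuals=resid,
        fitted=fitted,
        x=x,
        y=y,
        n_points=int(x.size),
        n_params=p,
        x0=x0,
        x_center=x_center,
    )


def fit_all(
    x: np.ndarray, y: np.ndarray, families: Sequence[str] = FAMILIES, seed: int = 0
) -> dict[str, TrendFit]:
    """Fit every requested family, silently dropping failures."""
    fits: dict[str, TrendFit] = {}
    errors: dict[str, str] = {}
    for fam in families:
        try:
            fits[fam] = fit_trend(x, y, fam, seed=seed)
        except FitError as e:
            errors[fam] = str(e)
    if not fits:
        raise FitError(f"all families failed: {errors}")
    return fits


def best_fit(
    x: np.ndarray, y: np.ndarray, families: Sequence[str] = FAMILIES, seed: int = 0
) -> TrendFit:
    """Maximum-R² fit; R² ties (within 1e-8) go to the fewest parameters."""
    fits = fit_all(x, y, families, seed=seed)
    if len(fits) < 2 and len(families) > 1:
        # a single surviving family is still returned, but selection was vacuous
        pass
    top = max(f.r_squared for f in fits.values())
    tied = [f for f in fits.values() if f.r_squared >= top - 1e-8]
    return min(tied, key=lambda f: (f.n_params, FAMILIES.index(f.family)))


@dataclass(frozen=True)
class FitComparison:
    """Paired comparison of two fits' absolute residuals on shared data."""

    family_a: str
    family_b: str
    t_stat: float
    p_value: float
    mean_abs_resid_a: float
    mean_abs_resid_b: float


def compare_fits(fit_a: TrendFit, fit_b: TrendFit) -> FitComparison:
    """Two-sided paired t test on the absolute residuals of two fits.

    Both fits must be on the identical point set; identical residual
    magnitudes give p = 1 (no evidence either curve fits better).
    """
    if fit_a.n_points != fit_b.n_points or not (
        np.allclose(fit_a.x, fit_b.x) and np.allclose(fit_a.y, fit_b.y)
    ):
        raise FitError("compare_fits requires fits on the identical (x, y) data")
    da = np.abs(fit_a.residuals)
    db = np.abs(fit_b.residuals)
    diff = da - db
    if np.allclose(diff, 0.0, atol=1e-12):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(da, db)
    return FitComparison(
        family_a=fit_a.family,
        family_b=fit_b.family,
        t_stat=float(t),
        p_value=float(p),
        mean_abs_resid_a=float(da.mean()),
        mean_abs_resid_b=float(db.mean()),
    )


def conservative_select(
    x: np.ndarray,
    y: np.ndarray,
    families: Sequence[str] = FAMILIES,
    alpha: float = 0.05,
    seed: int = 0,
) -> TrendFit:
    """Line-first model selection.

    The straight line is the starting-point model; another family
    replaces it only when its absolute residuals are significantly
    smaller (paired t, p < alpha) AND its mean absolute residual is
    lower.  Among qualifying families the maximum-R² one wins.  The
    returned fit's ``selection`` dict records the justification
    p-values.
    """
    linear = fit_trend(x, y, "linear", seed=seed)
    fits = fit_all(x, y, [f for f in families if f != "linear"], seed=seed)
    pvals: dict[str, float] = {}
    qualifying: list[TrendFit] = []
    for fam, f in fits.items():
        cmp = compare_fits(linear, f)
        pvals[fam] = cmp.p_value
        if cmp.p_value < alpha and cmp.mean_abs_resid_b < cmp.mean_abs_resid_a:
            qualifying.append(f)
    if not qualifying:
        chosen = linear
    else:
        chosen = max(qualifying, key=lambda f: f.r_squared)
    return replace(
        chosen, selection={"alpha": alpha, "p_vs_linear": pvals, "chosen": chosen.family}
    )


# ---------------------------------------------------------------------------
# parallelism and group comparisons


@dataclass(frozen=True)
class ParallelismResult:
    family: str
    f_stat: float
    p_value: float
    df: tuple[int, int]
    rss_full: float
    rss_reduced: float


def _stacked_lstsq(X: np.ndarray, y: np.ndarray) -> float:
    params, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ params) ** 2))


def parallelism_test(
    x: np.ndarray,
    y_a: np.ndarray,
    y_b: np.ndarray,
    family: str = "linear",
    seed: int = 0,
    shared: str = "shape",
) -> ParallelismResult:
    """Extra-sum-of-squares F test of curve parallelism for two groups.

    Full model: separate parameter vectors per group.  Reduced model
    (``shared='shape'``): one shared set of shape parameters with a free
    vertical offset per group — i.e. the curves may only differ by a
    shift; ``shared='all'`` forces one fully common curve.
    F = ((RSS_r - RSS_f)/ddf) / (RSS_f/df_f) with the usual F reference
    distribution.
    """
    x = np.asarray(x, float)
    y_a = np.asarray(y_a, float)
    y_b = np.asarray(y_b, float)
    if shared not in ("shape", "all"):
        raise FitError("shared must be 'shape' or 'all'")
    fa = fit_trend(x, y_a, family, seed=seed)
    fb = fit_trend(x, y_b, family, seed=seed)
    rss_full = fa.rss + fb.rss
    n = 2 * x.size
    p = N_PARAMS[family]
    df_full = n - 2 * p

    x2 = np.concatenate([x, x])
    y2 = np.concatenate([y_a, y_b])
    gb = np.concatenate([np.zeros(x.size), np.ones(x.size)])  # group indicator
    x0, x_center = fa.x0, float(x.mean())

    if family in _HAS_INTERCEPT:
        D = _design(family, x2, x0, x_center)
        if shared == "shape":
            # free intercept per group, shared non-intercept columns
            X = np.column_stack([1.0 - gb, gb, D[:, 1:]])
            p_red = p + 1
        else:
            X = D
            p_red = p
        rss_red = _stacked_lstsq(X, y2)
    else:
        if shared == "shape":
            # shared curve parameters + additive per-group offsets
            lo = [1e-12] * 3 + [-np.inf, -np.inf]
            hi = [np.inf] * 5
            if family == "negexp":
                lo[2] = -np.inf

            def resid(q):
                curve = _predict(family, q[:3], x2, x0, x_center)
                return curve + np.where(gb == 0, q[3], q[4]) - y2

            p0 = np.concatenate([(fa.params + fb.params) / 2.0, [0.0, 0.0]])
            p_red = p + 2
        else:
            lo = [1e-12] * 3
            hi = [np.inf] * 3
            if family == "negexp":
                lo[2] = -np.inf

            def resid(q):
                return _predict(family, q, x2, x0, x_center) - y2

            p0 = (fa.params + fb.params) / 2.0
            p_red = p
        p0 = np.clip(np.asarray(p0, float), np.asarray(lo) + 1e-12, None)
        sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-10, max_nfev=5000)
        if not sol.success:
            raise FitError(f"reduced parallelism model failed to converge: {sol.message}")
        rss_red = float(2.0 * sol.cost)

    ddf = 2 * p - p_red
    if df_full <= 0 or ddf <= 0:
        raise FitError("not enough points for the parallelism test")
    num = max(rss_red - rss_full, 0.0)
    if rss_full <= 1e-14 * max(float(np.sum(y2**2)), 1.0):
        f = 0.0 if num <= 1e-12 else np.inf
    else:
        f = (num / ddf) / (rss_full / df_full)
    pval = float(stats.f.sf(f, ddf, df_full)) if np.isfinite(f) else 0.0
    return ParallelismResult(
        family=family,
        f_stat=float(f),
        p_value=pval if np.isfinite(f) else 0.0,
        df=(ddf, df_full),
        rss_full=rss_full,
        rss_reduced=rss_red,
    )


def between_group_residuals(
    fit_on_pooled: TrendFit, group_labels: Sequence
) -> tuple[float, float]:
    """Welch two-sample t test comparing the pooled fit's residuals
    between the two groups (detects a group shift the single curve
    cannot absorb).  Returns (t, p)."""
    labels = np.asarray(group_labels)
    if labels.size != fit_on_pooled.n_points:
        raise FitError("group_labels length must match the fitted data")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise FitError(f"need exactly 2 groups, got {uniq.size}")
    ra = fit_on_pooled.residuals[labels == uniq[0]]
    rb = fit_on_pooled.residuals[labels == uniq[1]]
    if ra.size < 2 or rb.size < 2:
        raise FitError("each group needs >= 2 points")
    if np.allclose(ra.mean() - rb.mean(), 0.0, atol=1e-14) and np.allclose(
        np.concatenate([ra, rb]).std(), 0.0, atol=1e-14
    ):
        return 0.0, 1.0
    t, p = stats.ttest_ind(ra, rb, equal_var=False)
    return float(t), float(p)
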
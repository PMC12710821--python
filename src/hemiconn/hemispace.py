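"""Hemisphere-space statistics: LD1 scores, LD1_dist, and EHI regressions.

The first linear discriminant (LD1) of a hemisphere-chirality LDA places
every hemisphere sample on a one-dimensional "hemisphere space" axis:
strongly left-organised hemispheres sit at negative values, strongly
right-organised ones at positive values (the sign convention fixes the LH
class mean to be negative).  How distinct a subject's two hemispheres are
is summarised by

    LD1_dist = |LD1_LH| + |LD1_RH|

which is symmetric in the hemispheres and invariant to the global LDA
sign flip.  LD1_dist is then modelled as a function of the continuous
Edinburgh Handedness Inventory (EHI) score with four competing forms:
simple linear, one- and two-breakpoint continuous segmented regression,
and quadratic; nested forms are compared by F-test and all by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
import statsmodels.api as sm

__all__ = [
    "HemisphereScores",
    "DistanceModelFit",
    "SegmentedRegression",
    "ld1_scores",
    "ld1_dist",
    "z_within_group",
    "ld1_correlation",
    "fit_distance_models",
    "compare_nested",
    "group_distance_test",
]


@dataclass(frozen=True)
class HemisphereScores:
    """Per-subject hemisphere-space quantities."""

    subject_id: str
    ld1_lh: float
    ld1_rh: float
    z_ld1_lh: float
    z_ld1_rh: float

    @property
    def ld1_dist(self) -> float:
        return ld1_dist(self.ld1_lh, self.ld1_rh)


def ld1_scores(
    lda, X: np.ndarray, sign: float = 1.0, component: int = 0
) -> np.ndarray:
    """Oriented discriminant scores of feature vectors under a fitted LDA.

    ``sign`` is the orientation returned by
    :func:`hemiconn.classify.fit_oriented_lda` (LH class mean negative).
    """
    X = np.asarray(X)
    if X.shape[1] != lda.scalings_.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the fitted model "
            f"({lda.scalings_.shape[0]})"
        )
    return sign * lda.transform(X)[:, component]


def ld1_dist(ld1_lh: float | np.ndarray, ld1_rh: float | np.ndarray):
    """Hemisphere separation: |LD1_LH| + |LD1_RH|."""
    lh = np.asarray(ld1_lh, dtype=float)
    rh = np.asarray(ld1_rh, dtype=float)
    if not (np.all(np.isfinite(lh)) and np.all(np.isfinite(rh))):
        raise ValueError("LD1 scores must be finite")
    out = np.abs(lh) + np.abs(rh)
    return float(out) if out.ndim == 0 else out


def z_within_group(values: Sequence[float], groups: Sequence) -> np.ndarray:
    """Standardize values to mean 0, SD 1 within each group (sample SD, n-1)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for g in np.unique(groups):
        rows = groups == g
        if rows.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        sd = values[rows].std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {g!r} has zero variance")
        out[rows] = (values[rows] - values[rows].mean()) / sd
    return out


def ld1_correlation(ld1_lh: Sequence[float], ld1_rh: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation between per-subject LH and RH LD1 scores."""
    lh = np.asarray(ld1_lh, dtype=float)
    rh = np.asarray(ld1_rh, dtype=float)
    if len(lh) < 3:
        raise ValueError("need at least 3 subjects")
    if lh.std() == 0 or rh.std() == 0:
        raise ValueError("constant LD1 scores have no defined correlation")
    r, p = stats.pearsonr(lh, rh)
    return float(r), float(p)


def _hinge_design(x: np.ndarray, breakpoints: Sequence[float]) -> np.ndarray:
    cols = [np.ones_like(x), x]
    cols += [np.maximum(x - b, 0.0) for b in breakpoints]
    return np.column_stack(cols)


def _ols_sse(x: np.ndarray, y: np.ndarray, breakpoints: Sequence[float]) -> float:
    design = _hinge_design(x, breakpoints)
    _, res, _, _ = np.linalg.lstsq(design, y, rcond=None)
    if res.size:
        return float(res[0])
    fit = design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(((y - fit) ** 2).sum())


def _gaussian_aic(n: int, sse: float, k_params: int) -> float:
    """AIC under Gaussian errors, statsmodels OLS convention for the constant."""
    llf = -0.5 * n * (np.log(2 * np.pi * sse / n) + 1.0)
    return float(-2 * llf + 2 * k_params)


class SegmentedRegression(BaseEstimator, RegressorMixin):
    """Continuous piecewise-linear (broken-stick) regression on one predictor.

    Breakpoints are estimated by a profiled grid search over interior
    predictor values, refined by golden-section search; continuity at each
    breakpoint is structural (hinge basis ``max(x - b, 0)``).  Standard
    errors of the breakpoints come from a nonparametric bootstrap.

    Parameters
    ----------
    n_breakpoints : 1 or 2
    grid_size : number of grid candidates per breakpoint
    margin : fraction of the sorted sample excluded at each boundary

    Attributes (after fit)
    ----------------------
    breakpoints_ : estimated breakpoint locations (ascending)
    coef_ : [intercept, slope, hinge coefficients...]
    sse_, r2_, aic_, df_resid_ : fit summaries (breakpoints counted as
        estimated parameters)
    boundary_flag_ : True when a breakpoint landed at the search boundary
    """

    def __init__(self, n_breakpoints: int = 1, grid_size: int = 50, margin: float = 0.05):
        self.n_breakpoints = n_breakpoints
        self.grid_size = grid_size
        self.margin = margin

    @property
    def n_params(self) -> int:
        return 2 + 2 * self.n_breakpoints  # intercept, slope, hinges + breakpoints

    def _search_bounds(self, x: np.ndarray) -> tuple[float, float]:
        lo = float(np.quantile(x, self.margin))
        hi = float(np.quantile(x, 1 - self.margin))
        if lo >= hi:
            raise ValueError("predictor has no interior span for breakpoints")
        return lo, hi

    def _golden(self, x, y, lo, hi, other: Sequence[float]) -> float:
        inv_phi = (np.sqrt(5.0) - 1) / 2
        a, b = lo, hi
        c = b - inv_phi * (b - a)
        d = a + inv_phi * (b - a)
        fc = _ols_sse(x, y, sorted([*other, c]))
        fd = _ols_sse(x, y, sorted([*other, d]))
        for _ in range(60):
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - inv_phi * (b - a)
                fc = _ols_sse(x, y, sorted([*other, c]))
            else:
                a, c, fc = c, d, fd
                d = a + inv_phi * (b - a)
                fd = _ols_sse(x, y, sorted([*other, d]))
            if b - a < 1e-9 * (hi - lo + 1e-12):
                break
        return (a + b) / 2

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(x) != len(y) or len(x) < self.n_params + 2:
            raise ValueError("too few observations for a segmented fit")
        if self.n_breakpoints not in (1, 2):
            raise ValueError("n_breakpoints must be 1 or 2")
        lo, hi = self._search_bounds(x)
        grid = np.linspace(lo, hi, self.grid_size)
        if self.n_breakpoints == 1:
            sses = [_ols_sse(x, y, [b]) for b in grid]
            best = grid[int(np.argmin(sses))]
            span = grid[1] - grid[0]
            bp = [self._golden(x, y, max(lo, best - span), min(hi, best + span), [])]
        else:
            best_pair, best_sse = None, np.inf
            for i, b1 in enumerate(grid[:-1]):
                for b2 in grid[i + 1 :]:
                    sse = _ols_sse(x, y, [b1, b2])
                    if sse < best_sse:
                        best_sse, best_pair = sse, (b1, b2)
            span = grid[1] - grid[0]
            b1, b2 = best_pair
            b1 = self._golden(x, y, max(lo, b1 - span), min(hi, b1 + span), [b2])
            b2 = self._golden(x, y, max(b1 + 1e-9, b2 - span), min(hi, b2 + span), [b1])
            bp = sorted([b1, b2])
        design = _hinge_design(x, bp)
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ coef
        sse = float(((y - fitted) ** 2).sum())
        tss = float(((y - y.mean()) ** 2).sum())
        self.breakpoints_ = np.asarray(bp)
        self.coef_ = coef
        self.sse_ = sse
        self.r2_ = 1.0 - sse / tss if tss > 0 else 0.0
        self.aic_ = _gaussian_aic(len(y), max(sse, 1e-300), self.n_params)
        self.df_resid_ = len(y) - self.n_params
        tol = 1e-6 * (hi - lo)
        self.boundary_flag_ = bool(
            np.any(self.breakpoints_ <= lo + tol) or np.any(self.breakpoints_ >= hi - tol)
        )
        if self.boundary_flag_:
            warnings.warn("breakpoint estimate at the search boundary", stacklevel=2)
        self._x_fit = x
        self._y_fit = y
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        x = np.asarray(X, dtype=float).ravel()
        return _hinge_design(x, self.breakpoints_) @ self.coef_

    def bootstrap_se(self, n_boot: int = 500, seed: int = 0) -> np.ndarray:
        """Nonparametric bootstrap SE of the breakpoint location(s)."""
        check_is_fitted(self, "coef_")
        rng = np.random.default_rng(seed)
        n = len(self._x_fit)
        estimates = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = SegmentedRegression(
                        self.n_breakpoints, self.grid_size, self.margin
                    ).fit(self._x_fit[idx], self._y_fit[idx])
                estimates.append(model.breakpoints_)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if len(estimates) < 2:
            return np.full(self.n_breakpoints, np.nan)
        return np.asarray(estimates).std(axis=0, ddof=1)


@dataclass
class DistanceModelFit:
    """Summary of one EHI -> LD1_dist model fit."""

    kind: str
    coef: np.ndarray
    sse: float
    r2: float
    aic: float
    n_params: int
    df_resid: int
    breakpoints: np.ndarray | None = None
    breakpoint_se: np.ndarray | None = None
    boundary_flag: bool = False
    vertex: tuple[float, float] | None = None
    opens_downward: bool | None = None
    extras: dict = field(default_factory=dict)


def _fit_ols(x: np.ndarray, y: np.ndarray, kind: str) -> DistanceModelFit:
    if kind == "linear":
        design = sm.add_constant(x)
    elif kind == "quadratic":
        design = sm.add_constant(np.column_stack([x, x**2]))
    else:
        raise ValueError(kind)
    res = sm.OLS(y, design).fit()
    fit = DistanceModelFit(
        kind=kind,
        coef=np.asarray(res.params),
        sse=float(res.ssr),
        r2=float(res.rsquared),
        aic=float(res.aic),
        n_params=design.shape[1],
        df_resid=int(res.df_resid),
    )
    if kind == "quadratic":
        c0, c1, c2 = res.params
        if c2 != 0:
            vx = -c1 / (2 * c2)
            fit.vertex = (float(vx), float(c0 + c1 * vx + c2 * vx**2))
            fit.opens_downward = bool(c2 < 0)
    return fit


def fit_distance_models(
    ehi: Sequence[float],
    dist: Sequence[float],
    kinds: Sequence[str] = ("linear", "segmented1", "segmented2", "quadratic"),
    n_boot: int = 0,
    seed: int = 0,
) -> dict[str, DistanceModelFit]:
    """Fit the competing EHI -> LD1_dist models.

    ``n_boot > 0`` additionally bootstraps breakpoint standard errors for
    the segmented fits.
    """
    x = np.asarray(ehi, dtype=float)
    y = np.asarray(dist, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    fits: dict[str, DistanceModelFit] = {}
    for kind in kinds:
        if kind in ("linear", "quadratic"):
            fits[kind] = _fit_ols(x, y, kind)
        elif kind in ("segmented1", "segmented2"):
            nb = 1 if kind == "segmented1" else 2
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = SegmentedRegression(n_breakpoints=nb).fit(x, y)
            se = model.bootstrap_se(n_boot, seed=seed) if n_boot else None
            fits[kind] = DistanceModelFit(
                kind=kind,
                coef=model.coef_,
                sse=model.sse_,
                r2=model.r2_,
                aic=model.aic_,
                n_params=model.n_params,
                df_resid=model.df_resid_,
                breakpoints=model.breakpoints_,
                breakpoint_se=se,
                boundary_flag=model.boundary_flag_,
            )
        else:
            raise ValueError(f"unknown model kind {kind!r}")
    return fits


def compare_nested(
    restricted: DistanceModelFit, full: DistanceModelFit
) -> dict[str, float]:
    """F-test of a restricted model against a nesting full model."""
    df_num = restricted.df_resid - full.df_resid
    if df_num <= 0:
        raise ValueError("models are not nested in the stated order")
    if full.sse <= 0:
        return {"F": np.inf, "df_num": df_num, "df_den": full.df_resid, "p": 0.0}
    f_stat = ((restricted.sse - full.sse) / df_num) / (full.sse / full.df_resid)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, df_num, full.df_resid))
    return {"F": float(f_stat), "df_num": df_num, "df_den": full.df_resid, "p": p}


def group_distance_test(
    values: Sequence[float], labels: Sequence[str]
) -> dict[str, object]:
    """One-way ANOVA comparing a hemisphere-space quantity across groups.

    For the two-group case this is equivalent to the squared two-sample
    t-test (F = t^2).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    f_stat, p = stats.f_oneway(*groups)
    return {
        "group_means": {str(g): float(values[labels == g].mean()) for g in np.unique(labels)},
        "F": float(f_stat),
        "p": float(p),
        "df_between": len(groups) - 1,
        "df_within": len(values) - len(groups),
    }
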
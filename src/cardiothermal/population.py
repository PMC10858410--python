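"""Population-level inference on cardiac thermal indices.

Given a table of per-individual indices (T_AB, T_peak, T_Arr, heart-rate
metrics) tagged with clutch and incubation temperature, this module fits:

* random-intercept linear mixed models (incubation fixed effect, clutch
  random effect) with marginal/conditional R-squared and a boundary-corrected
  likelihood-ratio test for the random effect;
* Tukey-adjusted pairwise contrasts between incubation groups;
* logistic "proportion of individuals that have reached T_peak / T_Arr"
  curves over temperature, with 10/50/95% inverse prediction (delta-method
  standard errors);
* kernel density estimates of the proportion of individuals at T_AB;
* the overlay statistic dN(T) = density of individuals at T_AB minus the
  fitted proportion having reached the endpoint, whose maximum locates the
  group-level optimal temperature range;
* penalized-spline smooths of dN sampled at the ramp steps, whose first
  derivative turning negative marks the decline breakpoint.

Note on units: dN literally subtracts a density (per degC) from a
cumulative proportion (dimensionless). The subtraction is kept literal
because the overlay statistic is defined that way; the resulting maxima are
on the 0.03-0.12 scale of the assay.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline

__all__ = [
    "LMMFit",
    "ReachedCurve",
    "ThresholdEstimate",
    "DensityCurve",
    "DeltaNCurve",
    "SmoothCurve",
    "fit_random_intercept_lmm",
    "pairwise_contrasts",
    "reached_indicators",
    "fit_reached_curve",
    "inverse_predict",
    "kde_tab",
    "delta_n_curve",
    "smooth_decline_breakpoint",
]

ENDPOINT_COLUMNS = {"t_peak": "t_peak_C", "t_arr": "t_arr_C"}


# --------------------------------------------------------------------------
# linear mixed models


@dataclass(frozen=True)
class LMMFit:
    """Random-intercept mixed-model fit of one metric on incubation."""

    beta: np.ndarray  # (intercept, incubation slope)
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    sigma2_clutch: float
    sigma2_resid: float
    r2_marginal: float
    r2_conditional: float
    lrt_p_random: float
    n_obs: int
    n_clutches: int
    fallback_ols: bool = False

    @property
    def incubation_slope(self) -> float:
        return float(self.beta[1])

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return (self.beta[1] - z * self.se[1], self.beta[1] + z * self.se[1])


def fit_random_intercept_lmm(
    values, incubation_c, clutch_id
) -> LMMFit:
    """REML fit of ``value ~ incubation`` with a clutch random intercept.

    Marginal R2 is var(fixed predictor)/(var(fixed) + clutch variance +
    residual variance); conditional R2 adds the clutch variance to the
    numerator. The random-effect likelihood-ratio test compares maximum
    likelihoods of the mixed and plain-OLS models on chi-square(1) with the
    boundary correction (p halved).

    With a single clutch the random intercept is unidentifiable; the fit
    falls back to OLS and is flagged ``fallback_ols``.
    """
    y = np.asarray(values, dtype=float)
    inc = np.asarray(incubation_c, dtype=float)
    groups = np.asarray(clutch_id)
    keep = np.isfinite(y)
    y, inc, groups = y[keep], inc[keep], groups[keep]
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    X = sm.add_constant(inc)
    uniq = np.unique(groups)

    if len(uniq) < 2:
        ols = sm.OLS(y, X).fit()
        var_f = float(np.var(X @ ols.params))
        s2r = float(ols.scale)
        r2m = var_f / (var_f + s2r)
        return LMMFit(
            beta=np.asarray(ols.params),
            se=np.asarray(ols.bse),
            tvalues=np.asarray(ols.tvalues),
            pvalues=np.asarray(ols.pvalues),
            sigma2_clutch=0.0,
            sigma2_resid=s2r,
            r2_marginal=r2m,
            r2_conditional=r2m,
            lrt_p_random=math.nan,
            n_obs=len(y),
            n_clutches=1,
            fallback_ols=True,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits warn on sigma2_clutch ~ 0
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)
        res_ml = sm.MixedLM(y, X, groups=groups).fit(reml=False)
    beta = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    s2c = float(np.asarray(res.cov_re)[0, 0])
    s2r = float(res.scale)
    if s2c <= 1e-8 * max(1.0, s2r):
        # REML landed on the boundary sigma2_clutch = 0, where the GLS step
        # is singular and the fixed effects unreliable; the model reduces to
        # OLS there, so use it
        ols = sm.OLS(y, X).fit()
        beta = np.asarray(ols.params, dtype=float)
        se = np.asarray(ols.bse, dtype=float)
        s2c, s2r = 0.0, float(ols.scale)

    var_f = float(np.var(X @ beta))
    denom = var_f + s2c + s2r
    r2m = var_f / denom
    r2c = (var_f + s2c) / denom

    ll_null = sm.OLS(y, X).fit().llf
    lrt = max(0.0, 2.0 * (res_ml.llf - ll_null))
    lrt_p = 0.5 * stats.chi2.sf(lrt, df=1)

    return LMMFit(
        beta=beta,
        se=se,
        tvalues=beta / se,
        pvalues=2 * stats.norm.sf(np.abs(beta / se)),
        sigma2_clutch=s2c,
        sigma2_resid=s2r,
        r2_marginal=r2m,
        r2_conditional=r2c,
        lrt_p_random=float(lrt_p),
        n_obs=len(y),
        n_clutches=len(uniq),
    )


def pairwise_contrasts(values, group) -> pd.DataFrame:
    """All pairwise group-mean differences with Tukey (studentized-range)
    adjustment at the pooled residual degrees of freedom.

    Returns a frame with one row per unordered pair: the mean difference,
    its standard error, the unadjusted two-sided t-test p-value, and the
    Tukey-Kramer adjusted p-value.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group)
    keep = np.isfinite(y)
    y, g = y[keep], g[keep]
    levels = np.unique(g)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    means = {lv: y[g == lv].mean() for lv in levels}
    ns = {lv: int((g == lv).sum()) for lv in levels}
    df_resid = len(y) - k
    sse = sum(float(np.sum((y[g == lv] - means[lv]) ** 2)) for lv in levels)
    mse = sse / df_resid

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = means[b] - means[a]
            se = math.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0:
                p_raw = p_adj = 1.0 if diff == 0 else 0.0
            else:
                tstat = diff / se
                p_raw = 2 * stats.t.sf(abs(tstat), df_resid)
                q = abs(diff) / math.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
                p_adj = float(stats.studentized_range.sf(q, k, df_resid))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "estimate": diff,
                    "se": se,
                    "p_unadjusted": min(1.0, p_raw),
                    "p_tukey": min(1.0, p_adj),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# logistic "proportion reached" curves


def reached_indicators(
    dataset: pd.DataFrame, metrics: pd.DataFrame, endpoint: str
) -> pd.DataFrame:
    """Long 0/1 table: has each individual reached its endpoint by each step?

    ``reached`` is 1 iff the step temperature is at or above the
    individual's endpoint temperature. Individuals with censored T_Arr
    (never arrhythmic on the ramp) contribute 0 at every observed step.
    """
    if endpoint not in ENDPOINT_COLUMNS:
        raise ValueError(f"endpoint must be one of {sorted(ENDPOINT_COLUMNS)}")
    col = ENDPOINT_COLUMNS[endpoint]
    cols = ["individual_id", col]
    if endpoint == "t_arr" and "t_arr_censored" in metrics:
        cols.append("t_arr_censored")
    merged = dataset.merge(metrics[cols], on="individual_id", how="inner")
    if merged[col].isna().all():
        raise ValueError(f"endpoint {endpoint} missing for every individual")
    reached = (merged["step_temp_C"] >= merged[col]).astype(int)
    if "t_arr_censored" in merged:
        reached[merged["t_arr_censored"].astype(bool)] = 0
    out = merged[["individual_id", "clutch_id", "incubation_C", "step_temp_C"]].copy()
    out["reached"] = reached
    return out


@dataclass(frozen=True)
class ReachedCurve:
    """Fitted logistic curve of the proportion reached vs temperature.

    Coefficients are ordered (intercept, temperature[, incubation,
    temperature x incubation]); ``cov`` is their covariance matrix
    (cluster-robust by clutch when clutch identifiers were supplied).
    """

    endpoint: str
    params: np.ndarray
    cov: np.ndarray
    param_names: tuple[str, ...]
    has_incubation: bool
    separation: bool = False

    def linear_predictor(self, temp_c, incubation_c: float | None = None):
        t = np.asarray(temp_c, dtype=float)
        if self.has_incubation:
            if incubation_c is None:
                raise ValueError("incubation_c required for an interaction model")
            b0, bt, bi, bti = self.params
            return b0 + bt * t + bi * incubation_c + bti * t * incubation_c
        b0, bt = self.params
        return b0 + bt * t

    def predict(self, temp_c, incubation_c: float | None = None):
        """Fitted proportion of individuals having reached the endpoint."""
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(temp_c, incubation_c)))

    def effective_coefficients(self, incubation_c: float | None = None):
        """(intercept, slope) of the logit-linear predictor in temperature."""
        if self.has_incubation:
            if incubation_c is None:
                raise ValueError("incubation_c required for an interaction model")
            b0, bt, bi, bti = self.params
            return b0 + bi * incubation_c, bt + bti * incubation_c
        return tuple(self.params)


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = 1e-3):
    """Ridge-penalized logistic IRLS fallback for separated data."""
    beta = np.zeros(X.shape[1])
    pen = alpha * np.eye(X.shape[1])
    for _ in range(200):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-10, None)
        H = (X * w[:, None]).T @ X + 2 * pen
        grad = X.T @ (y - p) - 2 * alpha * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1 - p), 1e-10, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X + 2 * pen)
    return beta, cov


def fit_reached_curve(
    indicators: pd.DataFrame,
    endpoint: str = "t_peak",
    include_incubation: bool = True,
) -> ReachedCurve:
    """Logistic regression of reached on temperature (and incubation).

    With ``include_incubation`` the model is
    ``reached ~ temp + incubation + temp:incubation``; otherwise temperature
    only (the per-group mode). Clutch structure is handled by a
    cluster-robust covariance correction on a fixed-effects fit rather than
    a random intercept; with tiny between-clutch variance the two are
    practically identical, and the robust fit is deterministic.

    Complete separation is flagged and handled with a small-ridge refit.
    """
    y = indicators["reached"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("need both 0 and 1 outcomes to fit a logistic curve")
    t = indicators["step_temp_C"].to_numpy(dtype=float)
    if include_incubation:
        inc = indicators["incubation_C"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(t), t, inc, t * inc])
        names = ("intercept", "temp", "incubation", "temp_x_incubation")
    else:
        X = np.column_stack([np.ones_like(t), t])
        names = ("intercept", "temp")

    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial())
            if "clutch_id" in indicators:
                codes = pd.factorize(indicators["clutch_id"])[0]
                res = model.fit(cov_type="cluster", cov_kwds={"groups": codes})
            else:
                res = model.fit()
        params = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        se_fit = np.sqrt(np.diag(cov))
        if (
            not (np.all(np.isfinite(params)) and np.all(np.isfinite(cov)))
            or np.max(np.abs(params)) > 100.0
            or np.max(se_fit) > 1e3
        ):
            raise np.linalg.LinAlgError("diverged fit")
    except Exception:
        separation = True
        params, cov = _ridge_logit(X, y)

    return ReachedCurve(
        endpoint=endpoint,
        params=params,
        cov=cov,
        param_names=names,
        has_incubation=include_incubation,
        separation=separation,
    )


@dataclass(frozen=True)
class ThresholdEstimate:
    """Inverse-predicted temperature at which a given proportion of
    individuals has reached the endpoint, with delta-method SE."""

    endpoint: str
    p_level: float
    temperature_c: float
    se_c: float
    incubation_c: float | None = None


def inverse_predict(
    curve: ReachedCurve, p_level: float, incubation_c: float | None = None
) -> ThresholdEstimate:
    """Temperature solving ``logit(p_level) = linear predictor``.

    The standard error comes from the delta method on the coefficient
    covariance. Requires a positive effective temperature slope at the
    requested incubation.
    """
    if not (0.0 < p_level < 1.0):
        raise ValueError("p_level must lie in (0, 1)")
    a, b = curve.effective_coefficients(incubation_c)
    if b <= 0:
        raise ValueError("effective temperature slope must be positive")
    logit_p = math.log(p_level / (1.0 - p_level))
    temp = (logit_p - a) / b
    # gradient of temp wrt (b0, bt[, bi, bti])
    if curve.has_incubation:
        grad = np.array([-1.0 / b, -temp / b, -incubation_c / b, -incubation_c * temp / b])
    else:
        grad = np.array([-1.0 / b, -temp / b])
    se = float(math.sqrt(grad @ curve.cov @ grad))
    return ThresholdEstimate(
        endpoint=curve.endpoint,
        p_level=p_level,
        temperature_c=float(temp),
        se_c=se,
        incubation_c=incubation_c,
    )


# --------------------------------------------------------------------------
# kernel density of T_AB and the dN overlay


@dataclass(frozen=True)
class DensityCurve:
    """Gaussian kernel density of T_AB on a uniform temperature grid."""

    grid: np.ndarray  # degC
    density: np.ndarray  # per degC
    bandwidth: float
    n: int

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    @property
    def mode_c(self) -> float:
        return float(self.grid[np.argmax(self.density)])


def nrd0_bandwidth(values: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5), the
    default of the density smoother the assay's plots use."""
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    spread = min(sd, iqr / 1.34)
    if spread == 0:
        spread = sd
    if spread == 0:
        raise ValueError("all values identical: zero bandwidth")
    return 0.9 * spread * len(v) ** (-0.2)


def kde_tab(
    values,
    bandwidth: float | None = None,
    grid_spacing: float = 0.05,
    cut: float = 3.0,
) -> DensityCurve:
    """Gaussian KDE of per-individual T_AB on a uniform grid.

    The grid spans the data range extended by ``cut`` bandwidths each side
    at ``grid_spacing`` (degC) resolution, so the trapezoid integral is ~1.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise ValueError("need at least 3 finite values")
    if bandwidth is None:
        bandwidth = nrd0_bandwidth(v)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    kde = stats.gaussian_kde(v, bw_method=bandwidth / np.std(v, ddof=1))
    lo = v.min() - cut * bandwidth
    hi = v.max() + cut * bandwidth
    grid = np.arange(lo, hi + grid_spacing / 2, grid_spacing)
    return DensityCurve(grid=grid, density=kde(grid), bandwidth=float(bandwidth), n=len(v))


def _contiguous_intervals(grid: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    """Closed temperature intervals covering each contiguous True run."""
    intervals = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return intervals
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    for s, e in zip(starts, ends):
        intervals.append((float(grid[s]), float(grid[e])))
    return intervals


@dataclass(frozen=True)
class DeltaNCurve:
    """Overlay statistic dN(T): T_AB density minus fitted proportion reached.

    ``max_range`` is the span of grid temperatures where dN is within
    ``tol`` of its maximum (it always contains the argmax); ``max_intervals``
    lists each contiguous piece separately, since bimodal T_AB densities can
    split the near-maximal region. ``density_peak_intervals`` is the
    analogous 90%-of-maximum range of the density alone.
    """

    endpoint: str
    incubation_c: float | None
    grid: np.ndarray
    delta_n: np.ndarray
    max_value: float
    argmax_c: float
    max_range: tuple[float, float]
    max_intervals: list[tuple[float, float]] = field(default_factory=list)
    density_peak_intervals: list[tuple[float, float]] = field(default_factory=list)


def delta_n_curve(
    density: DensityCurve,
    curve: ReachedCurve,
    incubation_c: float | None = None,
    tol: float = 0.10,
) -> DeltaNCurve:
    """Compute dN(T) = density(T) - fitted reached proportion(T) on the
    density's grid, with its maximum, near-maximal range and the
    density-only 90%-of-maximum range."""
    grid = density.grid
    if len(grid) == 0:
        raise ValueError("empty density grid")
    reached = np.asarray(curve.predict(grid, incubation_c), dtype=float)
    delta = density.density - reached
    i_max = int(np.argmax(delta))
    max_value = float(delta[i_max])
    if max_value > 0:
        thresh = (1.0 - tol) * max_value
    else:  # degenerate: density everywhere below the logistic curve
        thresh = max_value - tol * abs(max_value)
    mask = delta >= thresh
    intervals = _contiguous_intervals(grid, mask)
    dens_mask = density.density >= 0.9 * density.density.max()
    return DeltaNCurve(
        endpoint=curve.endpoint,
        incubation_c=incubation_c,
        grid=grid,
        delta_n=delta,
        max_value=max_value,
        argmax_c=float(grid[i_max]),
        max_range=(float(grid[mask].min()), float(grid[mask].max())),
        max_intervals=intervals,
        density_peak_intervals=_contiguous_intervals(grid, dens_mask),
    )


# --------------------------------------------------------------------------
# penalized-spline smooth of dN and its decline breakpoint


@dataclass(frozen=True)
class SmoothCurve:
    """Penalized cubic B-spline smooth evaluated on a fine grid."""

    grid: np.ndarray
    fitted: np.ndarray
    derivative: np.ndarray
    k: int
    lam: float
    edf: float


def _bspline_basis(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis of dimension k with equally spaced knots."""
    degree = 3
    if k < degree + 1:
        raise ValueError("basis dimension k must be at least 4 for cubic splines")
    n_interior = k - degree - 1
    lo, hi = float(x.min()), float(x.max())
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()
    return B, knots


def smooth_decline_breakpoint(
    temps,
    values,
    k: int = 4,
    grid_spacing: float = 0.05,
    persist_c: float = 0.5,
    lambdas: np.ndarray | None = None,
) -> tuple[SmoothCurve, float | None]:
    """Penalized-spline smooth of dN samples and its decline breakpoint.

    Fits a cubic B-spline of basis dimension ``k`` with a second-difference
    penalty on the coefficients, choosing the smoothing parameter by
    generalized cross-validation. The decline breakpoint is the lowest grid
    temperature, at or beyond the smooth's maximum, where the first
    derivative becomes negative and stays negative for at least
    ``persist_c`` degC. The persistence window and the restriction to the
    falling limb both guard against boundary wiggles of flexible bases
    triggering a spurious early "decline". Returns ``(smooth, None)`` when
    the derivative never turns persistently negative.
    """
    x = np.asarray(temps, dtype=float)
    y = np.asarray(values, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} points, got {n}")

    B, knots = _bspline_basis(x, k)
    D = np.diff(np.eye(k), n=2, axis=0)  # second-order difference penalty
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y
    if lambdas is None:
        lambdas = np.logspace(-8, 4, 49)

    best = None
    for lam in lambdas:
        A = BtB + lam * P
        try:
            coef = np.linalg.solve(A, Bty)
            edf = float(np.trace(np.linalg.solve(A, BtB)))
        except np.linalg.LinAlgError:
            continue
        rss = float(np.sum((B @ coef - y) ** 2))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, edf)
    if best is None:
        raise np.linalg.LinAlgError("penalized fit failed at every lambda")
    _, lam, coef, edf = best

    spline = BSpline(knots, coef, 3, extrapolate=False)
    grid = np.arange(x.min(), x.max() + grid_spacing / 2, grid_spacing)
    grid = np.clip(grid, x.min(), x.max())
    fitted = spline(grid)
    deriv = spline.derivative()(grid)
    smooth = SmoothCurve(grid=grid, fitted=fitted, derivative=deriv, k=k,
                         lam=float(lam), edf=edf)

    # negative means "really declining", not numerical jitter on flat data
    tol = 1e-8 * max(1.0, float(np.max(np.abs(y))))
    negative = deriv < -tol
    window = max(1, int(round(persist_c / grid_spacing)))
    start = int(np.argmax(fitted))  # decline can only begin at/after the peak
    for i in np.flatnonzero(negative):
        if i < start:
            continue
        j = min(i + window, len(grid) - 1)
        if negative[i : j + 1].all():
            return smooth, float(grid[i])
    return smooth, None
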
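"""End-to-end pipeline stages: extract per-individual metrics, then run the
population-level inference.

These functions back both the command-line interface and the analysis
drivers; tests and the acceptance script import them directly.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

from .metrics import (
    CardiacMetrics,
    HeartRateSeries,
    compute_metrics,
    fit_series_breakpoint,
)
from .population import (
    delta_n_curve,
    fit_random_intercept_lmm,
    fit_reached_curve,
    inverse_predict,
    kde_tab,
    pairwise_contrasts,
    reached_indicators,
    smooth_decline_breakpoint,
)

__all__ = [
    "series_from_dataset",
    "extract_metrics",
    "lmm_table",
    "tukey_table",
    "threshold_table",
    "overlay_analysis",
]

#: metric columns analysed by the mixed models, in report order
METRIC_COLUMNS = {
    "f_H0": "f_h0",
    "f_Hpeak": "f_hpeak",
    "delta_f_Hpeak_H0": "delta_f",
    "dfH_dT": "dfdt",
    "T_AB": "t_ab_C",
    "T_peak": "t_peak_C",
    "T_Arr": "t_arr_C",
}

#: penalized-spline basis dimension per endpoint for the dN smooths
SMOOTH_K = {"t_peak": 4, "t_arr": 9}


def series_from_dataset(dataset: pd.DataFrame) -> Iterator[HeartRateSeries]:
    """Yield one HeartRateSeries per individual, steps in temperature order."""
    for ind, grp in dataset.groupby("individual_id", sort=True):
        grp = grp.sort_values("step_temp_C")
        yield HeartRateSeries(
            individual_id=str(ind),
            clutch_id=str(grp["clutch_id"].iloc[0]),
            incubation_c=float(grp["incubation_C"].iloc[0]),
            step_temps_c=tuple(grp["step_temp_C"].astype(float)),
            f_h=tuple(grp["f_H_bpm"].astype(float)),
            arrhythmic=tuple(grp["arrhythmic"].astype(bool)),
        )


def _metrics_row(m: CardiacMetrics) -> dict:
    return {
        "individual_id": m.individual_id,
        "clutch_id": m.clutch_id,
        "incubation_C": m.incubation_c,
        "f_h0": m.f_h0,
        "f_hpeak": m.f_hpeak,
        "delta_f": m.delta_f,
        "dfdt": m.dfdt,
        "t_ab_C": m.t_ab_c,
        "t_peak_C": m.t_peak_c,
        "t_arr_C": m.t_arr_c,
        "t_arr_censored": m.t_arr_censored,
        "fit_status": m.fit_status,
    }


def extract_metrics(dataset: pd.DataFrame, **fit_kwargs) -> pd.DataFrame:
    """Per-individual thermal indices for every individual in a dataset.

    Individuals whose Arrhenius fit finds no breakpoint keep their other
    metrics but carry NaN T_AB and a ``fit_status`` flag, mirroring assay
    practice of excluding them from the T_AB analyses only.
    """
    rows = []
    for series in series_from_dataset(dataset):
        fit = fit_series_breakpoint(series, **fit_kwargs)
        rows.append(_metrics_row(compute_metrics(series, fit)))
    return pd.DataFrame(rows)


def lmm_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Random-intercept mixed-model estimates for every metric.

    One pair of rows (intercept, incubation slope) per metric, with the
    variance components, marginal/conditional R2 and the random-effect
    likelihood-ratio p-value.
    """
    rows = []
    for label, col in METRIC_COLUMNS.items():
        fit = fit_random_intercept_lmm(
            metrics[col], metrics["incubation_C"], metrics["clutch_id"]
        )
        for i, term in enumerate(("intercept", "incubation")):
            rows.append(
                {
                    "metric": label,
                    "term": term,
                    "estimate": fit.beta[i],
                    "se": fit.se[i],
                    "t": fit.tvalues[i],
                    "p": fit.pvalues[i],
                    "sigma2_clutch": fit.sigma2_clutch,
                    "sigma2_resid": fit.sigma2_resid,
                    "r2_marginal": fit.r2_marginal,
                    "r2_conditional": fit.r2_conditional,
                    "lrt_p_random": fit.lrt_p_random,
                    "n": fit.n_obs,
                }
            )
    return pd.DataFrame(rows)


def tukey_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Tukey-adjusted pairwise incubation-group contrasts for every metric."""
    frames = []
    for label, col in METRIC_COLUMNS.items():
        tab = pairwise_contrasts(metrics[col], metrics["incubation_C"])
        tab.insert(0, "metric", label)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def threshold_table(
    dataset: pd.DataFrame,
    metrics: pd.DataFrame,
    p_levels: tuple[float, ...] = (0.10, 0.50, 0.95),
    endpoints: tuple[str, ...] = ("t_peak", "t_arr"),
    mode: str = "joint",
) -> pd.DataFrame:
    """Inverse-predicted 10/50/95% threshold temperatures.

    ``mode="joint"`` fits one interaction model per endpoint and evaluates
    it at each incubation temperature; ``mode="per_group"`` fits a separate
    temperature-only logistic curve within each incubation group. Both are
    defensible readings of per-incubation dose-response thresholds, so both
    are exposed.
    """
    if mode not in {"joint", "per_group"}:
        raise ValueError("mode must be 'joint' or 'per_group'")
    incubations = sorted(metrics["incubation_C"].unique())
    rows = []
    for endpoint in endpoints:
        ind = reached_indicators(dataset, metrics, endpoint)
        if mode == "joint":
            curve = fit_reached_curve(ind, endpoint, include_incubation=True)
            curves = {inc: (curve, inc) for inc in incubations}
        else:
            curves = {}
            for inc in incubations:
                sub = ind[ind["incubation_C"] == inc]
                curves[inc] = (
                    fit_reached_curve(sub, endpoint, include_incubation=False),
                    None,
                )
        for inc in incubations:
            curve, inc_arg = curves[inc]
            for p in p_levels:
                est = inverse_predict(curve, p, inc_arg)
                rows.append(
                    {
                        "endpoint": endpoint,
                        "incubation_C": inc,
                        "p_level": p,
                        "temperature_C": est.temperature_c,
                        "se_C": est.se_c,
                        "mode": mode,
                    }
                )
    return pd.DataFrame(rows)


def overlay_analysis(
    dataset: pd.DataFrame,
    metrics: pd.DataFrame,
    endpoints: tuple[str, ...] = ("t_peak", "t_arr"),
    tol: float = 0.10,
) -> tuple[pd.DataFrame, dict]:
    """Per-group dN(T) overlays and their decline breakpoints.

    For each incubation group: a KDE of T_AB, the joint logistic curve for
    the endpoint evaluated at that incubation, their difference dN(T), its
    maximum and near-maximal range, and a penalized-spline smooth of dN
    sampled at the protocol steps whose first derivative turning negative
    marks the decline breakpoint (basis dimension 4 for T_peak, 9 for
    T_Arr).

    Returns a summary frame and a dict of the full curve objects keyed by
    ``(endpoint, incubation)``.
    """
    steps = np.sort(dataset["step_temp_C"].unique())
    incubations = sorted(metrics["incubation_C"].unique())
    rows = []
    curves: dict[tuple[str, float], dict] = {}
    for endpoint in endpoints:
        ind = reached_indicators(dataset, metrics, endpoint)
        curve = fit_reached_curve(ind, endpoint, include_incubation=True)
        for inc in incubations:
            grp = metrics[metrics["incubation_C"] == inc]
            t_ab = grp["t_ab_C"].dropna()
            density = kde_tab(t_ab)
            dn = delta_n_curve(density, curve, inc, tol=tol)
            # sample dN at the assay's own step temperatures for the smooth
            dens_at_steps = np.interp(steps, density.grid, density.density,
                                      left=0.0, right=0.0)
            dn_at_steps = dens_at_steps - np.asarray(curve.predict(steps, inc))
            smooth, bp = smooth_decline_breakpoint(steps, dn_at_steps,
                                                   k=SMOOTH_K[endpoint])
            curves[(endpoint, inc)] = {
                "density": density,
                "reached_curve": curve,
                "delta_n": dn,
                "smooth": smooth,
            }
            rows.append(
                {
                    "endpoint": endpoint,
                    "incubation_C": inc,
                    "n_t_ab": len(t_ab),
                    "kde_bandwidth_C": density.bandwidth,
                    "max_delta_n": dn.max_value,
                    "argmax_C": dn.argmax_c,
                    "max_range_lo_C": dn.max_range[0],
                    "max_range_hi_C": dn.max_range[1],
                    "n_max_intervals": len(dn.max_intervals),
                    "density_peak_lo_C": dn.density_peak_intervals[-1][0],
                    "density_peak_hi_C": dn.density_peak_intervals[-1][1],
                    "decline_breakpoint_C": bp if bp is not None else np.nan,
                }
            )
    return pd.DataFrame(rows), curves
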
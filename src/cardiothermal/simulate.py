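"""Synthetic cohorts of larval heart-rate-vs-temperature profiles.

Generates populations with the statistical structure the downstream analysis
assumes: a stepwise 9-25 degC assay ramp, clutch-level random intercepts,
incubation-temperature fixed effects on the thermal thresholds, individual
variation around them, additive observation noise on heart rate, and
right-censoring of arrhythmia at the top of the ramp.

Each individual's noise-free profile is piecewise in Arrhenius coordinates
(x = 1000/T_K, y = log10 f_H): linear with slope ``arr_slope1`` up to T_AB,
attenuated slope ``arr_slope1 * slope_atten`` between T_AB and T_peak
(continuous at T_AB), then a linear-in-degC decline after T_peak until the
latent arrhythmia temperature, beyond which heart rate is unmeasurable.

Default trait models are calibrated to a larval smelt assay: threshold
means rise ~0.5-0.6 degC per degC of incubation temperature, e.g. a T_AB
linear predictor of 9.13 + 0.63 * incubation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import HeartRateSeries, celsius_to_arrhenius

__all__ = [
    "TemperatureProtocol",
    "TraitModel",
    "IndividualParams",
    "PopulationConfig",
    "make_protocol",
    "sample_clutch_effects",
    "sample_individual_params",
    "heart_rate_curve",
    "simulate_individuals",
    "generate_dataset",
]

DATASET_COLUMNS = [
    "individual_id",
    "clutch_id",
    "incubation_C",
    "step_temp_C",
    "f_H_bpm",
    "arrhythmic",
]

# heart rate never generated below this floor (bpm); keeps log10 defined
FH_FLOOR = 5.0


@dataclass(frozen=True)
class TemperatureProtocol:
    """Ordered assay ramp: which temperatures are visited and for how long."""

    steps: tuple[float, ...]
    hold_min: float = 5.0
    film_min: float = 2.5
    ramp_rate: float = 0.6  # degC per minute between steps

    def __post_init__(self):
        steps = np.asarray(self.steps, dtype=float)
        if len(steps) == 0:
            raise ValueError("protocol needs at least one step")
        if np.any(np.diff(steps) <= 0):
            raise ValueError("protocol steps must be strictly increasing")
        if self.hold_min <= 0 or self.film_min <= 0 or self.ramp_rate <= 0:
            raise ValueError("hold_min, film_min and ramp_rate must be positive")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def residence_min(self) -> float:
        """Total minutes an individual spends at each step (hold + film)."""
        return self.hold_min + self.film_min


def make_protocol(
    start: float = 9.0,
    end: float = 25.0,
    coarse_step: float = 2.0,
    fine_step: float = 1.0,
    switch: float = 19.0,
    *,
    hold_min: float = 5.0,
    film_min: float = 2.5,
    ramp_rate: float = 0.6,
) -> TemperatureProtocol:
    """Build a two-resolution stepwise ramp.

    Steps run ``start -> switch`` in ``coarse_step`` increments and
    ``switch -> end`` in ``fine_step`` increments, without duplicating the
    switch temperature. The default is the assay's 12-step ramp:
    2-degC increments 9-19 degC then 1-degC increments to 25 degC.
    """
    if coarse_step <= 0 or fine_step <= 0:
        raise ValueError("step sizes must be positive")
    if not (start <= switch <= end):
        raise ValueError(f"switch {switch} outside [{start}, {end}]")
    eps = 1e-9
    coarse = list(np.arange(start, switch + eps, coarse_step))
    fine = list(np.arange(switch, end + eps, fine_step))
    steps: list[float] = []
    for t in coarse + fine:
        if not steps or t > steps[-1] + eps:
            steps.append(round(float(t), 10))
    return TemperatureProtocol(
        steps=tuple(steps), hold_min=hold_min, film_min=film_min, ramp_rate=ramp_rate
    )


@dataclass(frozen=True)
class TraitModel:
    """Linear model for one trait: intercept + slope * incubation + clutch + individual."""

    intercept: float
    incubation_slope: float
    clutch_sd: float = 0.0
    individual_sd: float = 0.0

    def __post_init__(self):
        if self.clutch_sd < 0 or self.individual_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    def mean(self, incubation_c: float) -> float:
        return self.intercept + self.incubation_slope * incubation_c


@dataclass(frozen=True)
class IndividualParams:
    """Ground-truth generative parameters for one larva."""

    individual_id: str
    clutch_id: str
    incubation_c: float
    f_h0: float  # bpm at the first ramp step
    arr_slope1: float  # d(log10 f_H)/d(1000/K) below T_AB (negative)
    slope_atten: float  # slope attenuation factor between T_AB and T_peak
    decline_rate: float  # bpm per degC decline after T_peak
    t_ab_c: float
    t_peak_c: float
    t_arr_c: float  # latent, continuous; observed at step resolution

    def __post_init__(self):
        if self.f_h0 <= 0:
            raise ValueError("f_h0 must be positive")
        if not (self.t_ab_c < self.t_peak_c < self.t_arr_c):
            raise ValueError("thresholds must satisfy T_AB < T_peak < T_Arr")
        if self.decline_rate < 0:
            raise ValueError("decline_rate must be non-negative")
        if not (0.0 < self.slope_atten < 1.0):
            raise ValueError("slope_atten must lie in (0, 1)")
        if self.arr_slope1 >= 0:
            raise ValueError("arr_slope1 must be negative (f_H rises with temperature)")


@dataclass(frozen=True)
class PopulationConfig:
    """Study design and trait models for a simulated cohort.

    Defaults mirror the assay's design: three incubation groups
    (9/12/15 degC) of 121/152/134 larvae from 5 clutches, thresholds
    calibrated to the fitted mixed-model scale, 1.5 bpm observation noise,
    censoring at the 25 degC top step.
    """

    n_per_group: dict[float, int] = field(
        default_factory=lambda: {9.0: 121, 12.0: 152, 15.0: 134}
    )
    n_clutches: int = 5
    f_h0: TraitModel = TraitModel(48.87, 0.64, clutch_sd=3.0, individual_sd=2.5)
    t_ab: TraitModel = TraitModel(9.13, 0.63, clutch_sd=0.9, individual_sd=2.2)
    t_peak: TraitModel = TraitModel(12.20, 0.57, clutch_sd=0.8, individual_sd=2.0)
    t_arr: TraitModel = TraitModel(15.16, 0.51, clutch_sd=0.7, individual_sd=1.8)
    arr_slope1_mean: float = -2.8
    arr_slope1_sd: float = 0.15
    slope_atten: float = 0.45
    decline_rate_mean: float = 4.0
    decline_rate_sd: float = 1.0
    noise_sd: float = 1.5  # bpm; observation noise, user-set (no measured value exists)
    censor_temp_c: float = 25.0
    seed: int = 0
    max_resample: int = 1000

    def __post_init__(self):
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("n_per_group entries must be >= 1")
        if self.n_clutches < 1:
            raise ValueError("need at least one clutch")
        if self.noise_sd < 0 or self.arr_slope1_sd < 0 or self.decline_rate_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def n_individuals(self) -> int:
        return sum(self.n_per_group.values())

    @property
    def trait_models(self) -> dict[str, TraitModel]:
        return {
            "f_h0": self.f_h0,
            "t_ab": self.t_ab,
            "t_peak": self.t_peak,
            "t_arr": self.t_arr,
        }


def sample_clutch_effects(config: PopulationConfig, rng: np.random.Generator) -> dict:
    """Draw one random intercept per clutch per trait, shared by siblings."""
    return {
        clutch: {
            name: rng.normal(0.0, model.clutch_sd)
            for name, model in config.trait_models.items()
        }
        for clutch in range(1, config.n_clutches + 1)
    }


def sample_individual_params(
    config: PopulationConfig,
    clutch_id: int,
    incubation_c: float,
    rng: np.random.Generator,
    *,
    clutch_effects: dict[str, float] | None = None,
    individual_id: str = "ind",
) -> IndividualParams:
    """Draw one individual's generative parameters.

    Each threshold is intercept + slope * incubation + clutch effect +
    individual deviate. Draws violating T_AB < T_peak < T_Arr (or a
    non-positive f_H0) are resampled, redrawing only the individual
    deviates, so ordering is enforced without truncating clutch effects.

    Raises
    ------
    RuntimeError
        When ``config.max_resample`` draws never satisfy the ordering,
        which signals an incompatible configuration (e.g. overlapping
        threshold distributions with tiny separations).
    """
    if clutch_effects is None:
        clutch_effects = {
            name: rng.normal(0.0, m.clutch_sd) for name, m in config.trait_models.items()
        }
    mods = config.trait_models
    for _ in range(config.max_resample):
        draws = {
            name: mods[name].mean(incubation_c)
            + clutch_effects[name]
            + rng.normal(0.0, mods[name].individual_sd)
            for name in mods
        }
        if draws["t_ab"] < draws["t_peak"] < draws["t_arr"] and draws["f_h0"] > 0:
            break
    else:
        raise RuntimeError(
            "could not draw ordered thresholds T_AB < T_peak < T_Arr within "
            f"{config.max_resample} attempts; configuration looks incompatible"
        )
    slope = min(rng.normal(config.arr_slope1_mean, config.arr_slope1_sd), -0.5)
    decline = max(rng.normal(config.decline_rate_mean, config.decline_rate_sd), 0.0)
    return IndividualParams(
        individual_id=individual_id,
        clutch_id=f"C{clutch_id}",
        incubation_c=incubation_c,
        f_h0=draws["f_h0"],
        arr_slope1=slope,
        slope_atten=config.slope_atten,
        decline_rate=decline,
        t_ab_c=draws["t_ab"],
        t_peak_c=draws["t_peak"],
        t_arr_c=draws["t_arr"],
    )


def heart_rate_curve(
    params: IndividualParams, protocol: TemperatureProtocol
) -> HeartRateSeries:
    """Noise-free heart-rate profile of one individual over the ramp.

    In Arrhenius coordinates the profile is linear with slope
    ``arr_slope1`` for T <= T_AB (anchored so f_H at the first step equals
    f_H0), continues with slope ``arr_slope1 * slope_atten`` up to T_peak,
    then declines linearly in degC at ``decline_rate`` (floored at a small
    positive rate). Steps at or above the latent T_Arr are arrhythmic with
    missing heart rate.
    """
    temps = np.asarray(protocol.steps, dtype=float)
    x = celsius_to_arrhenius(temps)
    x0 = celsius_to_arrhenius(temps[0])
    x_ab = celsius_to_arrhenius(params.t_ab_c)
    x_peak = celsius_to_arrhenius(params.t_peak_c)

    y0 = math.log10(params.f_h0)
    y_ab = y0 + params.arr_slope1 * (x_ab - x0)
    s2 = params.arr_slope1 * params.slope_atten
    y_peak = y_ab + s2 * (x_peak - x_ab)
    f_peak = 10.0**y_peak

    fh = np.empty_like(temps)
    seg1 = temps <= params.t_ab_c
    seg2 = (temps > params.t_ab_c) & (temps <= params.t_peak_c)
    seg3 = temps > params.t_peak_c
    fh[seg1] = 10.0 ** (y0 + params.arr_slope1 * (x[seg1] - x0))
    fh[seg2] = 10.0 ** (y_ab + s2 * (x[seg2] - x_ab))
    fh[seg3] = np.maximum(
        f_peak - params.decline_rate * (temps[seg3] - params.t_peak_c), FH_FLOOR
    )

    arrhythmic = temps >= params.t_arr_c
    fh = np.where(arrhythmic, np.nan, fh)
    return HeartRateSeries(
        individual_id=params.individual_id,
        clutch_id=params.clutch_id,
        incubation_c=params.incubation_c,
        step_temps_c=tuple(temps),
        f_h=tuple(fh),
        arrhythmic=tuple(bool(a) for a in arrhythmic),
    )


def _add_noise(series: HeartRateSeries, noise_sd: float, rng) -> HeartRateSeries:
    if noise_sd == 0:
        return series
    fh = np.asarray(series.f_h, dtype=float)
    measured = ~np.isnan(fh)
    noisy = fh.copy()
    # truncated-positive additive noise: redraw the rare draws that would
    # push heart rate to or below zero
    vals = fh[measured] + rng.normal(0.0, noise_sd, size=int(measured.sum()))
    bad = vals <= 0
    while bad.any():
        vals[bad] = fh[measured][bad] + rng.normal(0.0, noise_sd, size=int(bad.sum()))
        bad = vals <= 0
    noisy[measured] = vals
    return replace(series, f_h=tuple(noisy))


def simulate_individuals(
    config: PopulationConfig,
    protocol: TemperatureProtocol | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[IndividualParams, HeartRateSeries]]:
    """Sample every individual in the design and evaluate its noisy profile.

    Censoring: the protocol simply ends at ``censor_temp_c``; individuals
    whose latent T_Arr exceeds it never show arrhythmia and are
    right-censored. Iteration order (group, clutch, individual) is fixed, so
    a fixed seed reproduces the cohort exactly.
    """
    if protocol is None:
        protocol = make_protocol(end=config.censor_temp_c)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    clutch_effects = sample_clutch_effects(config, rng)
    out = []
    counter = 0
    for incubation_c in sorted(config.n_per_group):
        n_group = config.n_per_group[incubation_c]
        # round-robin clutch assignment keeps clutches balanced across groups
        for i in range(n_group):
            clutch = (i % config.n_clutches) + 1
            counter += 1
            params = sample_individual_params(
                config,
                clutch,
                incubation_c,
                rng,
                clutch_effects=clutch_effects[clutch],
                individual_id=f"ind{counter:04d}",
            )
            series = _add_noise(heart_rate_curve(params, protocol), config.noise_sd, rng)
            out.append((params, series))
    return out


def generate_dataset(
    config: PopulationConfig, protocol: TemperatureProtocol | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and return (long-format dataset, ground-truth table).

    The dataset has one row per individual per protocol step with columns
    ``individual_id, clutch_id, incubation_C, step_temp_C, f_H_bpm,
    arrhythmic``; f_H_bpm is NaN exactly on arrhythmic rows. The truth table
    holds each individual's generative parameters for recovery tests.
    """
    if protocol is None:
        protocol = make_protocol(end=config.censor_temp_c)
    sims = simulate_individuals(config, protocol, np.random.default_rng(config.seed))
    n_steps = protocol.n_steps
    rows = {
        "individual_id": np.repeat([p.individual_id for p, _ in sims], n_steps),
        "clutch_id": np.repeat([p.clutch_id for p, _ in sims], n_steps),
        "incubation_C": np.repeat([p.incubation_c for p, _ in sims], n_steps),
        "step_temp_C": np.tile(np.asarray(protocol.steps), len(sims)),
        "f_H_bpm": np.concatenate([s.f_h for _, s in sims]),
        "arrhythmic": np.concatenate([s.arrhythmic for _, s in sims]).astype(bool),
    }
    dataset = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    truth = pd.DataFrame(
        [
            {
                "individual_id": p.individual_id,
                "clutch_id": p.clutch_id,
                "incubation_C": p.incubation_c,
                "f_h0": p.f_h0,
                "arr_slope1": p.arr_slope1,
                "slope_atten": p.slope_atten,
                "decline_rate": p.decline_rate,
                "t_ab_C": p.t_ab_c,
                "t_peak_C": p.t_peak_c,
                "t_arr_C": p.t_arr_c,
            }
            for p, _ in sims
        ]
    )
    return dataset, truth
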
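# Methods

## The assay and its data

One larva at a time is warmed through a fixed stepwise ramp while its
maximum heart rate *f*_H (beats·min⁻¹) is measured at each step. The default
protocol is 12 steps — {9, 11, 13, 15, 17, 19, 20, 21, 22, 23, 24, 25} °C —
with 5 min of holding plus 2.5 min of filming per step (7.5 min residence)
and a 0.6 °C·min⁻¹ ramp between steps. Once a heart becomes arrhythmic,
heart rate is no longer measurable, so within an individual the arrhythmia
flag is upward-closed in temperature and *f*_H is missing exactly on flagged
steps. Individuals still beating regularly at the top step carry a
right-censored T_Arr.

The population unit is a cohort of larvae from several full-sibling clutches,
incubated as embryos at different temperatures (9/12/15 °C in the default
design, with 121/152/134 individuals from 5 clutches).

## Generative model (synthetic cohorts)

The generator exists so that every downstream stage is testable without any
external dataset. Each trait y ∈ {f_H0, T_AB, T_peak, T_Arr} of an individual
is drawn from a linear mixed structure

    y = β0 + β1 · incubation + b_clutch + e_individual,
    b_clutch ~ N(0, σ_c²),  e_individual ~ N(0, σ_i²),

with clutch effects shared by siblings. Draws violating the physiological
ordering T_AB < T_peak < T_Arr are rejected and the *individual* deviates
redrawn (budget 1000), which enforces the ordering without truncating the
clutch effects; with the default separations, rejection is modest and the
marginal means shift by far less than a protocol step.

Default fixed effects are calibrated to the scale of a published larval
smelt assay of this design: intercept/slope pairs (48.87, 0.64) for f_H0,
(9.13, 0.63) for T_AB, (12.20, 0.57) for T_peak, (15.16, 0.51) for T_Arr
(units: bpm or °C, slope per °C of incubation). Individual SDs
(2.5 bpm, 2.2, 2.0, 1.8 °C) reproduce the reported within-group spreads;
clutch SDs (3.0 bpm, 0.9, 0.8, 0.7 °C) reproduce the pattern of large
clutch differences in heart rates but small clutch differences in the
threshold temperatures.

The noise-free profile is piecewise in Arrhenius coordinates
(x = 1000/(T + 273.15) K⁻¹, y = log₁₀ f_H):

1. slope `arr_slope1` (default −2.8 Δlog₁₀ per 1000 K⁻¹, i.e. roughly a
   doubling of f_H over 9→17 °C, matching the observed ~6 bpm·°C⁻¹ warming
   response) up to T_AB, anchored so f_H at the first step equals f_H0;
2. attenuated slope `arr_slope1 × slope_atten` (default attenuation 0.45)
   between T_AB and T_peak, continuous at T_AB;
3. a linear-in-°C decline after T_peak (default 4 bpm·°C⁻¹, floored at
   5 bpm);
4. missing (arrhythmic) from the first step at or above the latent
   continuous T_Arr — the *observed* T_Arr is therefore discretized to the
   step grid exactly as in the assay.

Pre-breakpoint linearity is imposed in Arrhenius space because that is the
space in which T_AB is estimated; the true generative form of cardiac
thermal performance is unknown, and the post-peak decline is linear in °C
purely for simplicity. Observation noise is additive Gaussian on f_H
(default SD 1.5 bpm, truncated positive by redraw) rather than on
log f_H, since beat-count error is approximately additive in bpm. **The
1.5 bpm default is a documented arbitrary choice** — no within-individual
measurement-error magnitude is available to calibrate it; it is exposed in
the configuration.

What the generator does *not* emulate: fluctuating temperature regimes,
survival/hatching differences between incubation groups, clutch-by-incubation
interactions, autocorrelated within-individual measurement error, or
individuals whose T_Arr precedes T_peak (possible in real data; the metric
extractor checks and warns rather than assuming it away). Passing tests
therefore demonstrate correctness of the estimators under the assumed
structure, not robustness to every pathology of real recordings.

## Measurement layer

Synthetic activity traces render beats at (k + ½)·60/f_H seconds as unit
Gaussian pulses (width 0.04 s) on a 30 frames·s⁻¹ grid plus amplitude noise;
arrhythmic traces drop a configurable fraction of beats and jitter the rest.
Beat detection is local-maxima-above-threshold with a refractory period of
0.15 s (≈ a 400 bpm ceiling — comfortably above larval heart rates).
Heart rate is estimated exactly as in assay practice: beats are counted in
seven consecutive 15-s clips starting at 0:30 and each count divided by
0.25 min, then averaged. Seven 15-s clips tile 0:30–2:15, leaving the final
15 s of the nominal 2-min window unused; seven-vs-eight is an
inconsistency inherited from assay practice and we follow the stated seven.
The quantization bound of this estimator is 4 bpm (one beat per clip).
Arrhythmia is operationalised as any inter-beat interval exceeding
`gap_factor` (default 2.0) times the median interval; trains with fewer than
three beats return an indeterminate status distinct from "regular".

## Breakpoint estimation

T_AB is fitted per individual by continuous two-segment least squares on the
Arrhenius-transformed measured steps. The model at candidate breakpoint c is
y = b₀ + b₁(x−c) + b₂·max(x−c, 0); the candidate grid is 200 equally spaced
x-values between the 2nd and (n−1)th sorted points (guaranteeing ≥ 2 points
per side), each candidate solved exactly by 3×3 normal equations, and the
global SSE minimum taken (ties to the lowest candidate). Exhaustive search
plus exact per-candidate least squares is cheap at n = 12 and removes
iterative-optimizer nondeterminism; a brute-force fitter using an
independent parametrization (value-at-break + two slopes, plain `lstsq`)
agrees exactly on random instances, which the test suite asserts on 1000
of them. Continuity at the breakpoint is imposed — standard for segmented
regression, though some breakpoint estimators leave it implicit.

A breakpoint is only accepted if the two-segment SSE is below 95 % of the
single-line SSE (configurable) and the segment slopes differ by at least
0.05 (configurable); otherwise the individual is flagged `no_breakpoint`
and excluded from T_AB analyses only — mirroring assay practice, where a
few individuals become arrhythmic before any breakpoint is expressed. Under
the default noise level the study-scale cohort yields a handful of such
individuals and a median |T_AB error| of about 1 °C (about half a coarse
protocol step).

Derived metrics: f_H0 is the heart rate at the first step; f_Hpeak/T_peak
are the maximum measured f_H and its temperature, ties broken toward the
*lower* temperature (conservative for an upper-limit proxy); df_H/dT is the
OLS slope of f_H on temperature over steps at or below the estimated T_AB —
"below the breakpoint" is ambiguous about inclusivity and we include the
boundary step, which stabilises the slope at coarse step spacing. T_Arr is
reported at step resolution, not interpolated, because the step is the
assay's observable.

## Population inference

**Mixed models.** `metric ~ incubation + (1 | clutch)` fitted by REML
(statsmodels `MixedLM`; cross-checked against lme4 in the test suite).
Marginal R² = var(Xβ)/(var(Xβ) + σ_c² + σ_e²); conditional R² adds σ_c² to
the numerator. The random-effect LRT compares ML fits of the mixed and OLS
models on χ²₁ with the usual boundary halving of the p-value. When REML
lands on the boundary σ_c² = 0 the GLS step is singular and the fixed
effects unreliable, so the fit is replaced by its OLS limit there. A
single-clutch dataset falls back to OLS with an explicit flag. Pairwise
incubation contrasts use the Tukey–Kramer studentized-range adjustment at
the pooled residual degrees of freedom; no family-wide correction is
applied across metrics.

**Threshold curves.** For each endpoint, a long 0/1 table marks whether each
individual has reached its endpoint by each step (censored T_Arr
individuals contribute zeros throughout). The logistic model
`reached ~ temperature × incubation` is fitted by IRLS with a
cluster-robust covariance by clutch instead of a clutch random intercept:
deterministic, dependency-light, and with near-zero between-clutch variance
in the threshold temperatures the two are practically identical. Complete
separation is detected (non-finite or exploding coefficients/SEs) and
handled by a small-ridge IRLS refit, flagged on the result. The 10/50/95 %
temperatures solve logit(p) = linear predictor; SEs come from the delta
method on the coefficient covariance. Whether per-group dose–response
thresholds should come from the joint interaction model evaluated at each
incubation or from independent per-group fits is genuinely ambiguous, so
both modes are exposed (`mode="joint"` / `"per_group"`); on the default
cohorts they differ by < 0.1 °C.

**ΔN overlays.** The T_AB density per group uses a Gaussian KDE with the
0.9·min(sd, IQR/1.34)·n^(−1/5) rule-of-thumb bandwidth (the default of the
density smoother used in standard plotting practice) on a 0.05 °C grid
spanning the data ± 3 bandwidths. ΔN(T) subtracts the fitted reached
proportion from the density *literally*, although the former is
dimensionless and the latter is per °C; the subtraction is kept literal
because the overlay statistic is defined that way, and the resulting maxima
land on the familiar 0.03–0.12 scale. The near-maximal range reports all
grid temperatures with ΔN ≥ (1−tol)·max (tol = 0.10), as contiguous
intervals — bimodal T_AB densities can split it — plus the density-only
90 %-of-maximum range.

**Decline breakpoints.** ΔN sampled at the 12 protocol steps is smoothed by
a penalized cubic B-spline of basis dimension k (4 for T_peak, 9 for T_Arr)
with a second-order difference penalty, the smoothing parameter chosen by
GCV over a log-spaced grid. The penalized GAM smoother is implemented
in-package (B-spline design matrix from scipy) because no installed Python
library exposes a basis-dimension-k penalized smooth; its decline behaviour
is cross-checked against an R mgcv thin-plate fit in the test suite. The
derivative is taken analytically from the fitted spline on the 0.05 °C grid.
The decline breakpoint is the lowest grid temperature **at or beyond the
smooth's maximum** where the derivative is negative and stays negative for
≥ 0.5 °C. Restricting the search to the falling limb matters: flexible
(k = 9) GCV smooths show tiny boundary wiggles (|derivative| ~ 1/30 of the
true falling limb) that would otherwise trigger a spurious "decline" at the
bottom of the ramp. On flat data the derivative is compared against a small
scale-relative tolerance so that numerical jitter never produces a
breakpoint. With the stiff k = 4 basis the smooth's own maximum sits well
below the sampled ΔN peak (a cubic fitted to a flat-then-cliff shape peaks
early), so T_peak decline breakpoints are systematically cooler than the
T_Arr ones — a known property of the k = 4 smooth, not of the data.

## Problem sizes and determinism

Default analyses run at the study scale (407 individuals × 12 steps);
statistical recovery tests use 200 mixed-model replicates at n = 407,
1000 random instances for the breakpoint-oracle equivalence, cohorts of 500
for threshold-quantile recovery, and 100 seeded end-to-end runs for the
ordering checks. Every random draw flows from a single `numpy` Generator
seeded from the configuration, and iteration order is fixed, so a seed
reproduces a cohort — and the full pipeline's output files — byte for byte.

## Known limitations

- T_Arr group means are biased upward relative to the latent arrhythmia
  temperature by step discretization (first step *at or above* the latent
  value) and by recording censored individuals at the top step; the same
  biases exist in the assay itself.
- The logistic threshold model treats per-individual step indicators as
  independent Bernoulli draws given temperature; within-individual
  dependence across steps is absorbed only by the cluster-robust variance.
- The k = 4 ΔN smooth is too stiff to track a sharp ΔN knee, as noted above.
- The arrhythmia gap rule is one operationalization of "discontinuous
  beating"; real assays verify flagged recordings visually.
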
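# cardiothermal

Analysis pipeline for **cardiac thermal-performance assays in larval fish**.
In this assay, anaesthetized larvae are warmed in a stepwise ramp
(9–25 °C: 2 °C steps to 19 °C, then 1 °C steps; 5 min hold + 2.5 min of
filming per step) while maximum heart rate *f*<sub>H</sub> (beats·min⁻¹) is
measured at every step. Three per-individual temperatures summarise thermal
performance:

- **T<sub>AB</sub>** — the *Arrhenius breakpoint temperature*: the
  temperature at which the slope of log₁₀ *f*<sub>H</sub> against inverse
  absolute temperature (1000/K) changes. A proxy for the thermal optimum
  T<sub>opt</sub>.
- **T<sub>peak</sub>** — the temperature eliciting the highest
  *f*<sub>H</sub>; a sublethal upper-limit proxy.
- **T<sub>Arr</sub>** — the lowest temperature at which cardiac arrhythmia
  (discontinuous beating) appears; a near-lethal upper-limit proxy,
  right-censored for individuals still beating regularly at the top step.

plus *f*<sub>H0</sub>, *f*<sub>Hpeak</sub>, the cardiac scope
Δ*f*<sub>Hpeak−H0</sub>, and d*f*<sub>H</sub>/dT (the warming response below
T<sub>AB</sub>). The package is aimed at thermal ecophysiologists who run
(or plan) such assays and want a tested, reproducible implementation of the
whole chain from raw activity traces to population-level thermal limits —
without needing access to any particular raw dataset: a calibrated
synthetic-cohort generator stands in for real data everywhere.

## What it computes

**Per individual** (`cardiothermal.metrics`): T<sub>AB</sub> by continuous
two-segment least squares in Arrhenius coordinates, with the breakpoint
located by exhaustive search over 200 candidate positions (deterministic,
globally optimal; individuals whose two-segment fit does not beat a single
line are flagged `no_breakpoint`); T<sub>peak</sub>, T<sub>Arr</sub> and the
heart-rate metrics by their assay definitions.

**Per population** (`cardiothermal.population`):

- random-intercept mixed models `metric ~ incubation + (1 | clutch)`
  (REML, via statsmodels), with marginal/conditional R², a
  boundary-corrected likelihood-ratio test of the clutch variance, and
  Tukey-adjusted pairwise incubation contrasts;
- logistic curves of the proportion of individuals that have reached
  T<sub>peak</sub> / T<sub>Arr</sub> by each temperature
  (`temperature × incubation`, cluster-robust by clutch), with the 10/50/95 %
  temperatures by inverse prediction and delta-method standard errors;
- Gaussian-kernel densities of T<sub>AB</sub> per group and the overlay
  statistic **ΔN(T) = density of individuals at T<sub>AB</sub> − fitted
  proportion having reached the endpoint**, whose maximum locates the
  group-level optimal temperature range;
- penalized-spline smooths of ΔN sampled at the ramp steps (basis dimension
  4 for T<sub>peak</sub>, 9 for T<sub>Arr</sub>, smoothing by GCV), whose
  first derivative turning persistently negative marks the temperature
  where ΔN begins to decline.

**Measurement layer** (`cardiothermal.traces`): beat detection on 1-D
cardiac activity traces, clip-averaged heart-rate estimation (seven 15-s
clips of the 0:30–2:15 window, counts divided by 0.25 min), and an
inter-beat-interval gap rule for arrhythmia.

## Worked example

Simulate the full study design (121/152/134 larvae incubated at 9/12/15 °C
from 5 clutches), extract metrics, and run the inference:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_extract_metrics.py
python analysis/03_mixed_models.py
python analysis/04_thresholds.py
python analysis/05_overlap.py
```

which prints (seed 1):

```
rows: 4884
individuals: 407
individuals per incubation group: 9.0C: 121, 12.0C: 152, 15.0C: 134
...
407 individuals; 2 without an Arrhenius breakpoint
T_AB recovery: median |error| 1.01 degC, 90th percentile 3.79 degC
              t_ab_C  t_peak_C  t_arr_C
incubation_C
9.0            15.43     17.00    20.80
12.0           17.09     18.80    22.22
15.0           18.55     20.53    23.57
...
10% thresholds (joint interaction model):
endpoint      t_arr  t_peak
incubation_C
9.0           18.16   13.86
12.0          19.78   15.99
15.0          21.29   17.95
```

Reading this: every individual profile yields 12 heart-rate measurements
(4884 rows in total); two individuals became arrhythmic before a breakpoint
was identifiable. The group means show the expected ordering
T<sub>AB</sub> < T<sub>peak</sub> < T<sub>Arr</sub> within every incubation
group, and all three indices shift upward with incubation temperature —
warmer-incubated embryos hatch into larvae with warmer thermal optima *and*
warmer upper limits. The 10 % thresholds are the temperatures at which one
in ten larvae has already peaked (or gone arrhythmic): conservative
upper-limit estimates for a *group*, which sit several degrees below the
group means of the same metrics.

The same pipeline is available as a console tool
(`cardiothermal all --out results/`, or the individual `simulate` /
`extract` / `analyze` / `report` / `validate` subcommands) for use on any
dataset in the documented long format.

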
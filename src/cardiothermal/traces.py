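"""Beat detection and heart-rate estimation from 1-D cardiac activity traces.

Replicates the measurement layer of the assay: a camera films the beating
heart and an activity signal is extracted; heart rate is the frequency of
activity spikes. The first 30 s of each 2.5-min recording are discarded
(camera settling) and beats are counted in seven 15-s clips, each count
divided by 0.25 min, then averaged — so the final 15 s of the 2-min
analysis window is unused by construction.

Arrhythmia is operationalised as "discontinuous spikes": any inter-beat
interval exceeding ``gap_factor`` times the median interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "ActivityTrace",
    "BeatTrain",
    "synth_trace",
    "detect_beats",
    "estimate_fh",
    "detect_arrhythmia",
]

#: default refractory period between detected beats: ~400 bpm ceiling
DEFAULT_REFRACTORY_S = 0.15


@dataclass(frozen=True)
class ActivityTrace:
    """Uniformly sampled cardiac activity signal."""

    sampling_rate: float  # frames per second
    samples: np.ndarray  # arbitrary amplitude units

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class BeatTrain:
    """Detected (or true) beat times in seconds, strictly increasing."""

    beat_times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.beat_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("beat times must be strictly increasing")
        object.__setattr__(self, "beat_times", t)

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    @property
    def inter_beat_intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)


def synth_trace(
    f_h: float,
    duration_s: float = 150.0,
    sampling_rate: float = 30.0,
    noise_sd: float = 0.0,
    arrhythmic: bool = False,
    rng: np.random.Generator | None = None,
    *,
    pulse_width_s: float = 0.04,
    drop_fraction: float = 0.3,
    jitter_frac: float = 0.25,
) -> tuple[ActivityTrace, np.ndarray]:
    """Render a synthetic activity trace for a given heart rate.

    Beats occur at ``(k + 1/2) * 60/f_h`` seconds while inside the trace, so
    a 60-bpm, 150-s trace carries exactly 150 beats. Each beat is a Gaussian
    pulse of unit amplitude; Gaussian amplitude noise is added on top. When
    ``arrhythmic``, a fraction of beats is dropped and the remaining beat
    times jittered, making the spike train discontinuous.

    Returns the trace together with the true beat times used to render it.
    """
    if f_h <= 0:
        raise ValueError("f_h must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    period = 60.0 / f_h
    beat_times = np.arange(0.5 * period, duration_s, period)
    if arrhythmic and len(beat_times) > 3:
        keep = rng.random(len(beat_times)) >= drop_fraction
        keep[0] = True
        beat_times = beat_times[keep]
        beat_times = beat_times + rng.normal(0.0, jitter_frac * period, len(beat_times))
        beat_times = np.sort(beat_times)
        beat_times = beat_times[(beat_times > 0) & (beat_times < duration_s)]
        # enforce strict increase after jitter
        beat_times = beat_times[np.concatenate([[True], np.diff(beat_times) > 1e-6])]

    t = np.arange(round(duration_s * sampling_rate)) / sampling_rate
    signal = np.zeros_like(t)
    for bt in beat_times:
        lo = np.searchsorted(t, bt - 5 * pulse_width_s)
        hi = np.searchsorted(t, bt + 5 * pulse_width_s)
        signal[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - bt) / pulse_width_s) ** 2)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, len(signal))
    return ActivityTrace(sampling_rate=sampling_rate, samples=signal), beat_times


def detect_beats(
    trace: ActivityTrace,
    threshold: float = 0.5,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> BeatTrain:
    """Detect beats as local maxima above ``threshold`` separated by at least
    the refractory period. Deterministic for fixed input."""
    if len(trace.samples) == 0:
        raise ValueError("empty trace")
    distance = max(1, int(round(refractory_s * trace.sampling_rate)))
    idx, _ = find_peaks(trace.samples, height=threshold, distance=distance)
    return BeatTrain(beat_times=idx / trace.sampling_rate)


def estimate_fh(
    train: BeatTrain,
    window_start_s: float = 30.0,
    clip_len_s: float = 15.0,
    n_clips: int = 7,
    trace_duration_s: float | None = None,
) -> float:
    """Clip-averaged heart rate in beats per minute.

    Beats are counted in ``n_clips`` consecutive clips of ``clip_len_s``
    seconds starting at ``window_start_s``; each count is divided by the
    clip length in minutes (0.25 min for 15-s clips) and the per-clip rates
    are averaged.
    """
    if n_clips < 1 or clip_len_s <= 0:
        raise ValueError("need n_clips >= 1 and positive clip length")
    window_end = window_start_s + n_clips * clip_len_s
    if trace_duration_s is not None and window_end > trace_duration_s + 1e-9:
        raise ValueError(
            f"analysis window [{window_start_s}, {window_end}) s extends past the "
            f"{trace_duration_s}-s trace"
        )
    edges = window_start_s + clip_len_s * np.arange(n_clips + 1)
    counts = np.histogram(train.beat_times, bins=edges)[0]
    return float(np.mean(counts / (clip_len_s / 60.0)))


def detect_arrhythmia(train: BeatTrain, gap_factor: float = 2.0) -> bool | None:
    """Flag discontinuous beating.

    True when any inter-beat interval exceeds ``gap_factor`` times the
    median interval; ``None`` (indeterminate, distinct from False) when the
    train has fewer than three beats and the rule cannot be evaluated.
    """
    if train.n_beats < 3:
        return None
    ibi = train.inter_beat_intervals
    return bool(np.any(ibi > gap_factor * np.median(ibi)))
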
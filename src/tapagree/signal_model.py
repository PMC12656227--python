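"""Synthetic finger-tapping cohorts with paired multi-rate sensor streams.

The Finger Tapping Test (FTT) asks a participant to tap a surface with the
index finger as fast as possible for 10 s.  Two instruments record the same
trial at their native rates: a high-speed camera tracking finger vertical
position (nominally 240 Hz) and a finger-mounted inertial sensor recording
linear acceleration (nominally 100 Hz).  This module generates ground-truth
tap times and renders both streams so the downstream detection, timing and
agreement machinery can be exercised end to end with a known answer key.

The default cohort mirrors the reference study design: 20 subjects (half
fibromyalgia, half matched controls), 2 hands, 6 trials per hand, 10 s per
trial — 240 trial pairs.  Tapping rate carries a subject-level random effect
so trials within a subject correlate, and the two clinical groups differ in
mean rate and inter-tap-interval variability.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHYSIO_RATE_RANGE_HZ",
    "MIN_PHYSIO_ITI_S",
    "MIN_ITI_S",
    "RAMP_S",
    "GROUP_PRESETS",
    "InvalidArgumentError",
    "DegenerateTrialError",
    "TrialKey",
    "CohortConfig",
    "TrialGroundTruth",
    "SampledSignal",
    "CohortTrial",
    "generate_tap_times",
    "render_position",
    "render_acceleration",
    "generate_cohort",
    "perfect_sensor_config",
    "cohort_signals_frame",
    "cohort_ground_truth_frame",
    "write_cohort_csv",
]

# Expected physiological tapping band in adults: roughly 4-8 Hz, i.e.
# inter-tap intervals (ITIs) of 0.125-0.250 s.
PHYSIO_RATE_RANGE_HZ: tuple[float, float] = (4.0, 8.0)
MIN_PHYSIO_ITI_S: float = 1.0 / PHYSIO_RATE_RANGE_HZ[1]  # 0.125 s

# Hard physiological floor for a generated ITI; the lognormal interval
# distribution is truncated (by redrawing) below this value.
MIN_ITI_S: float = 0.05

# Recording lead-in before the first contact.  A contact event is only
# observable if samples precede it, so every rendered stream starts at least
# this long before the first tap (on top of the drawn start offset).
LEAD_IN_S: float = 0.05

# Raised-cosine rise/fall ramp around each surface contact.  Fixed in time
# (not scaled by the cycle period) so the position valley at every contact is
# locally symmetric and its curvature does not depend on the neighbouring
# inter-tap intervals.  2 * RAMP_S never exceeds MIN_ITI_S.
RAMP_S: float = 0.025

# Acceleration template constants: a symmetric impact transient at each
# contact (raised-cosine pulse) riding on a smooth negative mid-cycle
# deceleration bowl.  Heights are expressed relative to the kinematic scale
# amplitude * pi^2 / (2 * RAMP_S^2) of the position ramps.
IMPACT_WIDTH_S: float = 0.010
IMPACT_HEIGHT_FRAC: float = 1.5
ARTIFACT_HEIGHT_RANGE: tuple[float, float] = (0.40, 0.70)
ARTIFACT_DELAY_RANGE_S: tuple[float, float] = (0.020, 0.050)

#: Group presets for tapping rate and timing variability.  The clinical
#: direction (slower, more variable tapping in fibromyalgia) follows the
#: motor-control literature; the magnitudes are this package's choice of
#: realistic values, not measured quantities.
GROUP_PRESETS: dict[str, dict[str, float]] = {
    "control": {"base_rate_mean": 6.0, "iti_jitter_cv": 0.08},
    "fibromyalgia": {"base_rate_mean": 5.0, "iti_jitter_cv": 0.15},
}

METHOD_VIDEO = "video_position"
METHOD_IMU = "imu_acceleration"
HANDS = ("preferred", "other")


class InvalidArgumentError(ValueError):
    """A generator argument is outside its valid domain."""


class DegenerateTrialError(ValueError):
    """A trial does not contain enough taps to be rendered."""


class TrialKey(NamedTuple):
    subject_id: str
    hand: str
    trial_index: int


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic FTT cohort.

    ``group_label=None`` (the default) assigns the first half of the subjects
    to the control group and the second half to the fibromyalgia group,
    matching the 10 + 10 design the defaults emulate.  Passing a label forces
    a single-group cohort.  ``base_rate_mean`` / ``iti_jitter_cv`` override
    the group presets when given.
    """

    n_subjects: int = 20
    n_hands: int = 2
    n_trials_per_hand: int = 6
    trial_duration: float = 10.0
    base_rate_mean: float | None = None
    base_rate_sd: float = 0.4
    iti_jitter_cv: float | None = None
    group_label: str | None = None
    position_rate: float = 240.0
    accel_rate: float = 100.0
    amplitude: float = 0.03
    noise_sd_frac: float = 0.02
    artifact_prob: float = 0.10
    start_offset_range: tuple[float, float] = (0.0, 0.5)
    min_iti: float = MIN_ITI_S
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_hands, self.n_trials_per_hand) < 1:
            raise InvalidArgumentError("all counts must be >= 1")
        if self.trial_duration <= 0:
            raise InvalidArgumentError("trial_duration must be > 0")
        if self.position_rate <= 0 or self.accel_rate <= 0:
            raise InvalidArgumentError("sampling rates must be > 0")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise InvalidArgumentError("artifact_prob must be in [0, 1]")
        if self.iti_jitter_cv is not None and self.iti_jitter_cv < 0:
            raise InvalidArgumentError("iti_jitter_cv must be >= 0")
        if self.noise_sd_frac < 0 or self.base_rate_sd < 0:
            raise InvalidArgumentError("noise and rate SDs must be >= 0")
        lo, hi = self.start_offset_range
        if lo < 0 or hi < lo:
            raise InvalidArgumentError("start_offset_range must be 0 <= lo <= hi")
        if self.group_label is not None and self.group_label not in GROUP_PRESETS:
            raise InvalidArgumentError(f"unknown group_label {self.group_label!r}")
        if self.amplitude <= 0 or self.min_iti <= 0:
            raise InvalidArgumentError("amplitude and min_iti must be > 0")


@dataclass(frozen=True)
class TrialGroundTruth:
    """True tap times for one trial, in task time (first tap at 0)."""

    subject_id: str
    hand: str
    trial_index: int
    true_tap_times: np.ndarray
    amplitude: float

    def __post_init__(self) -> None:
        t = np.asarray(self.true_tap_times, dtype=float)
        object.__setattr__(self, "true_tap_times", t)
        if t.ndim != 1 or t.size < 1:
            raise InvalidArgumentError("true_tap_times must be a non-empty vector")
        d = np.diff(t)
        if np.any(d < MIN_ITI_S - 1e-12):
            raise InvalidArgumentError(
                "successive tap times must be >= 0.05 s apart"
            )
        if self.amplitude <= 0:
            raise InvalidArgumentError("amplitude must be positive")

    @property
    def key(self) -> TrialKey:
        return TrialKey(self.subject_id, self.hand, self.trial_index)


@dataclass(frozen=True)
class SampledSignal:
    """One uniformly sampled stream for one trial and one method.

    ``events_offset`` records the shift between the trial's task clock (in
    which the ground-truth tap times are expressed) and this stream's own
    clock: a tap at task time ``t`` appears in the stream at
    ``t + events_offset``.  Each stream draws its offset independently, so
    event-based synchronization is non-trivial and testable.
    """

    key: TrialKey
    method: str
    sample_times: np.ndarray
    values: np.ndarray
    rate: float
    events_offset: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "values", v)
        if t.size < 2 or t.size != v.size:
            raise InvalidArgumentError("need >= 2 samples and matching lengths")
        dt = np.diff(t)
        if np.any(np.abs(dt - 1.0 / self.rate) > 1e-9):
            raise InvalidArgumentError("sample grid must be uniform at 1/rate")

    @property
    def n_samples(self) -> int:
        return int(self.sample_times.size)


@dataclass(frozen=True)
class CohortTrial:
    """Ground truth plus the two rendered streams for one trial."""

    ground_truth: TrialGroundTruth
    position: SampledSignal
    acceleration: SampledSignal
    group: str


# ---------------------------------------------------------------------------
# Ground-truth tap times
# ---------------------------------------------------------------------------

def generate_tap_times(
    rate_mean: float,
    jitter_cv: float,
    duration: float,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    start_offset: float = 0.0,
    min_iti: float = MIN_ITI_S,
) -> np.ndarray:
    """Draw a strictly increasing sequence of tap times.

    The first tap falls at ``start_offset``.  Subsequent inter-tap intervals
    are lognormal with mean ``1/rate_mean`` and coefficient of variation
    ``jitter_cv``, redrawn while below ``min_iti``; generation stops when the
    next tap would exceed ``start_offset + duration``.  ``jitter_cv == 0``
    degenerates to an exact arithmetic grid.
    """
    if rate_mean <= 0 or duration <= 0:
        raise InvalidArgumentError("rate_mean and duration must be > 0")
    if jitter_cv < 0:
        raise InvalidArgumentError("jitter_cv must be >= 0")
    if jitter_cv == 0.0:
        n_intervals = int(math.floor(duration * rate_mean + 1e-9))
        return start_offset + np.arange(n_intervals + 1) / rate_mean

    if rng is None:
        rng = np.random.default_rng(seed)
    mean_iti = 1.0 / rate_mean
    sigma2 = math.log1p(jitter_cv**2)
    mu = math.log(mean_iti) - sigma2 / 2.0
    sigma = math.sqrt(sigma2)

    taps = [start_offset]
    end = start_offset + duration
    while True:
        iti = rng.lognormal(mu, sigma)
        while iti < min_iti:
            iti = rng.lognormal(mu, sigma)
        t_next = taps[-1] + iti
        if t_next > end:
            break
        taps.append(t_next)
    return np.asarray(taps)


# ---------------------------------------------------------------------------
# Waveform templates
# ---------------------------------------------------------------------------

def _cycle_ramp_times(events: np.ndarray, ramp: float) -> np.ndarray:
    """Per-cycle ramp duration: ``min(ramp, T/2)`` for each inter-tap gap."""
    periods = np.diff(events)
    return np.minimum(ramp, periods / 2.0)


def _lift_waveform(
    t: np.ndarray, events: np.ndarray, amplitude: float, ramp: float = RAMP_S
) -> np.ndarray:
    """Continuous finger-lift trajectory: 0 at each contact, plateau between.

    Each cycle rises from the surface with a raised-cosine ramp, dwells at
    ``amplitude`` and falls back with a mirrored ramp, so every contact is a
    locally symmetric global-scale minimum.  Before the first and after the
    last contact the finger is held lifted.
    """
    e = np.asarray(events, dtype=float)
    if e.size < 2:
        raise DegenerateTrialError("need >= 2 taps to render a trial")
    taus = _cycle_ramp_times(e, ramp)
    periods = np.diff(e)
    y = np.empty_like(t, dtype=float)

    pre = t < e[0]
    v = e[0] - t[pre]
    y[pre] = np.where(
        v < taus[0],
        0.5 * (1.0 - np.cos(np.pi * v / taus[0])),
        1.0,
    )
    post = t >= e[-1]
    u = t[post] - e[-1]
    y[post] = np.where(
        u < taus[-1],
        0.5 * (1.0 - np.cos(np.pi * u / taus[-1])),
        1.0,
    )
    mid = ~pre & ~post
    tm = t[mid]
    i = np.searchsorted(e, tm, side="right") - 1
    i = np.clip(i, 0, e.size - 2)
    u = tm - e[i]
    T = periods[i]
    tau = taus[i]
    y[mid] = np.where(
        u < tau,
        0.5 * (1.0 - np.cos(np.pi * u / tau)),
        np.where(
            u > T - tau,
            0.5 * (1.0 - np.cos(np.pi * (T - u) / tau)),
            1.0,
        ),
    )
    return amplitude * y


def _cos_pulse(t: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Raised-cosine pulse of unit height supported on ``center +- half_width``."""
    x = (t - center) / half_width
    out = np.zeros_like(t, dtype=float)
    inside = np.abs(x) <= 1.0
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * x[inside]))
    return out


def _accel_waveform(
    t: np.ndarray,
    events: np.ndarray,
    amplitude: float,
    ramp: float = RAMP_S,
) -> tuple[np.ndarray, float]:
    """Noise-free acceleration template; returns (values, impact height).

    Each surface contact produces a symmetric impact transient (raised-cosine
    pulse of width ``2 * IMPACT_WIDTH_S``); between contacts the finger's
    smooth lift-and-lower produces a shallow negative deceleration bowl with
    no interior local maxima.  The bowl is supported strictly outside the
    impact-pulse windows, so the waveform within one pulse half-width of a
    contact is exactly symmetric about it and the sampled maximum is always
    the grid point nearest the true event.  The impact height is
    ``IMPACT_HEIGHT_FRAC * amplitude * pi^2 / (2 * ramp^2)``, i.e. 1.5x the
    peak kinematic acceleration of the position ramps, so every contact spike
    is the dominant feature of its cycle.
    """
    e = np.asarray(events, dtype=float)
    if e.size < 2:
        raise DegenerateTrialError("need >= 2 taps to render a trial")
    kinematic_peak = amplitude * np.pi**2 / (2.0 * ramp**2)
    impact = IMPACT_HEIGHT_FRAC * kinematic_peak
    w = IMPACT_WIDTH_S

    a = np.zeros_like(t, dtype=float)
    for center in e:
        a += impact * _cos_pulse(t, center, w)

    def _bowl(u: np.ndarray, T: np.ndarray | float) -> np.ndarray:
        # -C sin(pi (u-w)/(T-2w)) on [w, T-w], zero under the impact pulses;
        # depth scaled like the raised-cosine mid-flight acceleration.
        depth = 2.0 * np.pi**2 * amplitude / np.asarray(T, float) ** 2
        inner = (u >= w) & (u <= T - w)
        out = np.zeros_like(u, dtype=float)
        span = np.broadcast_to(np.asarray(T, float) - 2 * w, u.shape)
        out[inner] = -np.broadcast_to(depth, u.shape)[inner] * np.sin(
            np.pi * (u[inner] - w) / span[inner]
        )
        return out

    periods = np.diff(e)
    bowl = np.zeros_like(t, dtype=float)
    mid = (t >= e[0]) & (t < e[-1])
    i = np.clip(np.searchsorted(e, t[mid], side="right") - 1, 0, e.size - 2)
    bowl[mid] = _bowl(t[mid] - e[i], periods[i])
    pre = t < e[0]
    bowl[pre] = _bowl(e[0] - t[pre], periods[0])
    post = t >= e[-1]
    bowl[post] = _bowl(t[post] - e[-1], periods[-1])
    return a + bowl, impact


# ---------------------------------------------------------------------------
# Stream renderers
# ---------------------------------------------------------------------------

def _sample_grid(rate: float, total_duration: float) -> np.ndarray:
    n = int(math.floor(total_duration * rate + 1e-9)) + 1
    return np.arange(n) / rate


def _grid_duration(gt: TrialGroundTruth, events_offset: float) -> float:
    # Cover the last event plus a tail so the final contact is interior.
    return events_offset + float(gt.true_tap_times[-1]) + 0.2


def render_position(
    gt: TrialGroundTruth,
    rate: float,
    noise_sd_frac: float = 0.0,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    start_offset: float = 0.0,
    total_duration: float | None = None,
) -> SampledSignal:
    """Render the camera-tracked vertical position stream for a trial.

    Taps are the global-scale minima of the waveform (finger on surface at
    height 0); additive white noise has SD ``noise_sd_frac * amplitude``.
    """
    if gt.true_tap_times.size < 2:
        raise DegenerateTrialError("need >= 2 taps to render a trial")
    if rate <= 0:
        raise InvalidArgumentError("rate must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    events_offset = start_offset + LEAD_IN_S
    events = gt.true_tap_times + events_offset
    t = _sample_grid(rate, total_duration or _grid_duration(gt, events_offset))
    y = _lift_waveform(t, events, gt.amplitude)
    if noise_sd_frac > 0:
        y = y + rng.normal(0.0, noise_sd_frac * gt.amplitude, size=t.size)
    return SampledSignal(gt.key, METHOD_VIDEO, t, y, rate, events_offset=events_offset)


def render_acceleration(
    gt: TrialGroundTruth,
    rate: float,
    noise_sd_frac: float = 0.0,
    artifact_prob: float = 0.0,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    start_offset: float = 0.0,
    total_duration: float | None = None,
) -> SampledSignal:
    """Render the IMU linear-acceleration stream for a trial.

    Every contact is a dominant positive spike.  With probability
    ``artifact_prob`` per tap cycle a secondary spike of 40-70% relative
    height appears within 0.05 s after the main spike — the double-peak
    artifact mode that the detector's 0.120 s distance rule must suppress.
    Noise SD is ``noise_sd_frac`` times the impact-spike height.
    """
    if gt.true_tap_times.size < 2:
        raise DegenerateTrialError("need >= 2 taps to render a trial")
    if rate <= 0:
        raise InvalidArgumentError("rate must be > 0")
    if not 0.0 <= artifact_prob <= 1.0:
        raise InvalidArgumentError("artifact_prob must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    events_offset = start_offset + LEAD_IN_S
    events = gt.true_tap_times + events_offset
    t = _sample_grid(rate, total_duration or _grid_duration(gt, events_offset))
    a, impact = _accel_waveform(t, events, gt.amplitude)

    periods = np.diff(events)
    for i, center in enumerate(events[:-1]):
        if rng.uniform() < artifact_prob:
            lo, hi = ARTIFACT_DELAY_RANGE_S
            delay = rng.uniform(lo, min(hi, 0.6 * periods[i]))
            height = rng.uniform(*ARTIFACT_HEIGHT_RANGE) * impact
            a += height * _cos_pulse(t, center + delay, IMPACT_WIDTH_S)
    if noise_sd_frac > 0:
        a = a + rng.normal(0.0, noise_sd_frac * impact, size=t.size)
    return SampledSignal(gt.key, METHOD_IMU, t, a, rate, events_offset=events_offset)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _subject_groups(config: CohortConfig) -> list[str]:
    if config.group_label is not None:
        return [config.group_label] * config.n_subjects
    half = config.n_subjects // 2 + config.n_subjects % 2
    return ["control"] * half + ["fibromyalgia"] * (config.n_subjects - half)


def generate_cohort(config: CohortConfig) -> list[CohortTrial]:
    """Generate the full cohort of (ground truth, position, acceleration).

    Each subject draws a tapping rate once (a subject-level random effect, SD
    ``base_rate_sd``, clipped to the 4-8 Hz physiological band) so trials
    within a subject correlate; the group sets the mean rate and ITI
    variability.  Each stream draws an independent recording-start offset so
    the two clocks disagree until event-based synchronization.
    """
    rng = np.random.default_rng(config.seed)
    groups = _subject_groups(config)
    lo_rate, hi_rate = PHYSIO_RATE_RANGE_HZ
    trials: list[CohortTrial] = []
    for s in range(config.n_subjects):
        group = groups[s]
        preset = GROUP_PRESETS[group]
        rate_mean = (
            config.base_rate_mean
            if config.base_rate_mean is not None
            else preset["base_rate_mean"]
        )
        jitter_cv = (
            config.iti_jitter_cv
            if config.iti_jitter_cv is not None
            else preset["iti_jitter_cv"]
        )
        subject_rate = float(
            np.clip(rng.normal(rate_mean, config.base_rate_sd), lo_rate, hi_rate)
        )
        subject_id = f"S{s + 1:02d}"
        for h in range(config.n_hands):
            hand = HANDS[h] if h < len(HANDS) else f"hand{h + 1}"
            for trial_index in range(1, config.n_trials_per_hand + 1):
                taps = generate_tap_times(
                    subject_rate,
                    jitter_cv,
                    config.trial_duration,
                    rng=rng,
                    min_iti=config.min_iti,
                )
                amplitude = config.amplitude * rng.uniform(0.8, 1.2)
                gt = TrialGroundTruth(subject_id, hand, trial_index, taps, amplitude)
                off_lo, off_hi = config.start_offset_range
                total = config.trial_duration + off_hi + LEAD_IN_S + 0.2
                pos = render_position(
                    gt,
                    config.position_rate,
                    config.noise_sd_frac,
                    rng=rng,
                    start_offset=rng.uniform(off_lo, off_hi),
                    total_duration=total,
                )
                acc = render_acceleration(
                    gt,
                    config.accel_rate,
                    config.noise_sd_frac,
                    config.artifact_prob,
                    rng=rng,
                    start_offset=rng.uniform(off_lo, off_hi),
                    total_duration=total,
                )
                trials.append(CohortTrial(gt, pos, acc, group))
    return trials


def perfect_sensor_config(seed: int = 0, **overrides) -> CohortConfig:
    """Noise-free, artifact-free cohort for detector validation.

    The ITI floor is raised just above the detector's 0.120 s refractory
    distance so 100% event recovery is well-posed (the detection thresholds
    assume physiological ITIs, which exceed 0.125 s).
    """
    params = dict(
        noise_sd_frac=0.0,
        artifact_prob=0.0,
        min_iti=0.130,
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def cohort_signals_frame(trials: Sequence[CohortTrial]) -> pd.DataFrame:
    """Long-format signal table: subject_id, hand, trial_index, method, t, value."""
    parts = []
    for trial in trials:
        for sig in (trial.position, trial.acceleration):
            parts.append(
                pd.DataFrame(
                    {
                        "subject_id": sig.key.subject_id,
                        "hand": sig.key.hand,
                        "trial_index": sig.key.trial_index,
                        "method": sig.method,
                        "rate_hz": sig.rate,
                        "t_seconds": sig.sample_times,
                        "value": sig.values,
                    }
                )
            )
    return pd.concat(parts, ignore_index=True)


def cohort_ground_truth_frame(trials: Sequence[CohortTrial]) -> pd.DataFrame:
    parts = []
    for trial in trials:
        gt = trial.ground_truth
        parts.append(
            pd.DataFrame(
                {
                    "subject_id": gt.subject_id,
                    "hand": gt.hand,
                    "trial_index": gt.trial_index,
                    "group": trial.group,
                    "amplitude": gt.amplitude,
                    "tap_time_seconds": gt.true_tap_times,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_cohort_csv(trials: Sequence[CohortTrial], out_dir) -> dict[str, str]:
    """Write ``signals.csv`` and ``ground_truth.csv`` under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "signals": str(out / "signals.csv"),
        "ground_truth": str(out / "ground_truth.csv"),
    }
    cohort_signals_frame(trials).to_csv(paths["signals"], index=False)
    cohort_ground_truth_frame(trials).to_csv(paths["ground_truth"], index=False)
    return paths
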
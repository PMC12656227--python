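"""Tap-event detection by prominence- and distance-constrained peak finding.

Surface contacts are extracted from each stream with the same two criteria
used for the reference MATLAB routine: a minimum distance between events of
0.120 s and a minimum topographic prominence of 20% of the total signal
amplitude (max - min).  Contacts are position minima (the stream is negated
first) and acceleration maxima; the position maxima — the flight apexes —
are detected as well but carry no metric, they are kept as metadata.

The distance constraint is resolved greedily: candidates are ranked by
descending prominence (earlier time breaks ties) and each candidate is kept
iff it lies at least the minimum distance from every candidate already kept.
This deterministic rule suppresses the IMU double-peak artifact, whose
secondary spike is both less prominent and closer than 0.120 s to the true
contact spike.  On plateaus (runs of equal samples) the first sample of the
run is the candidate, so detection is deterministic on quantized data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .signal_model import SampledSignal, TrialKey

__all__ = [
    "DEFAULT_MIN_DISTANCE_S",
    "DEFAULT_MIN_PROMINENCE_FRAC",
    "DetectionParams",
    "DegenerateSignalError",
    "PeakCandidate",
    "TapSeries",
    "TrialDetections",
    "topographic_prominence",
    "local_maxima_indices",
    "find_peaks",
    "detect_trial",
    "tap_series_frame",
    "write_taps_csv",
    "read_taps_csv",
]

DEFAULT_MIN_DISTANCE_S = 0.120
DEFAULT_MIN_PROMINENCE_FRAC = 0.20

# Two event times conflict under the distance rule iff they are closer than
# min_distance minus this slack; it absorbs float representation error in
# sample grids (e.g. 12 samples at 100 Hz is not exactly 0.12 in binary).
_DISTANCE_TOL_S = 1e-9


class DegenerateSignalError(ValueError):
    """Signal has zero amplitude or is too short for peak detection."""


class InvalidPeakError(ValueError):
    """The supplied index is not a local maximum."""


@dataclass(frozen=True)
class DetectionParams:
    min_distance: float = DEFAULT_MIN_DISTANCE_S
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC

    def __post_init__(self) -> None:
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")
        if not 0.0 <= self.min_prominence_frac <= 1.0:
            raise ValueError("min_prominence_frac must be in [0, 1]")


@dataclass(frozen=True)
class PeakCandidate:
    index: int
    time: float
    height: float
    prominence: float


@dataclass(frozen=True)
class TapSeries:
    """Ordered tap-event times for one trial and one method."""

    key: TrialKey
    method: str
    tap_times: np.ndarray
    peaks: tuple[PeakCandidate, ...] = ()
    polarity: Literal["maxima", "minima"] = "maxima"

    def __post_init__(self) -> None:
        t = np.asarray(self.tap_times, dtype=float)
        object.__setattr__(self, "tap_times", t)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("tap_times must be strictly increasing")

    @property
    def n_taps(self) -> int:
        return int(self.tap_times.size)

    def shifted(self, offset: float) -> "TapSeries":
        peaks = tuple(
            replace(p, time=p.time + offset) for p in self.peaks
        )
        return replace(self, tap_times=self.tap_times + offset, peaks=peaks)


class TrialDetections(NamedTuple):
    position_contacts: TapSeries
    position_apexes: TapSeries
    accel_contacts: TapSeries


# ---------------------------------------------------------------------------
# Local maxima and prominence
# ---------------------------------------------------------------------------

def _run_starts(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start index and value of each run of equal consecutive samples."""
    change = np.nonzero(np.diff(x) != 0)[0] + 1
    starts = np.concatenate(([0], change))
    return starts, x[starts]


def local_maxima_indices(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima; a plateau contributes its first sample.

    Endpoint runs are never maxima.  A sample (or plateau) qualifies iff the
    preceding and following distinct values are both strictly lower.
    """
    x = np.asarray(x, dtype=float)
    starts, vals = _run_starts(x)
    if vals.size < 3:
        return np.empty(0, dtype=int)
    is_max = (vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:])
    return starts[1:-1][is_max]


def topographic_prominence(values: np.ndarray, peak_index: int) -> float:
    """Topographic prominence of the local maximum at ``peak_index``.

    On each side the base is the minimum value between the peak and the
    nearest sample strictly exceeding the peak's height (or the signal end if
    none exists); prominence is the peak height minus the higher base.
    """
    x = np.asarray(values, dtype=float)
    if not 0 < peak_index < x.size - 1:
        raise InvalidPeakError("endpoints are never peaks")
    if peak_index not in local_maxima_indices(x):
        raise InvalidPeakError(f"index {peak_index} is not a local maximum")
    return _prominence_unchecked(x, int(peak_index))


def _prominence_unchecked(x: np.ndarray, i: int) -> float:
    h = x[i]
    higher_left = np.nonzero(x[:i] > h)[0]
    lo = int(higher_left[-1]) + 1 if higher_left.size else 0
    left_base = x[lo : i + 1].min()
    higher_right = np.nonzero(x[i + 1 :] > h)[0]
    hi = i + 1 + int(higher_right[0]) if higher_right.size else x.size
    right_base = x[i:hi].min()
    return float(h - max(left_base, right_base))


# ---------------------------------------------------------------------------
# Peak finding
# ---------------------------------------------------------------------------

def find_peaks(
    signal: SampledSignal,
    min_distance: float = DEFAULT_MIN_DISTANCE_S,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    polarity: Literal["maxima", "minima"] = "maxima",
) -> TapSeries:
    """Detect tap events on one stream.

    For ``polarity="minima"`` the signal is negated first, so contacts on the
    position stream are found as maxima of the inverted trace.  The
    prominence threshold is relative to the stream's total amplitude
    (max - min); an empty result is legal.
    """
    values = signal.values
    if values.size < 3:
        raise DegenerateSignalError("need >= 3 samples")
    x = -values if polarity == "minima" else values.copy()
    amplitude = float(x.max() - x.min())
    if amplitude == 0.0:
        raise DegenerateSignalError("zero-amplitude signal")

    cand = local_maxima_indices(x)
    if cand.size == 0:
        return TapSeries(signal.key, signal.method, np.empty(0), (), polarity)
    proms = np.array([_prominence_unchecked(x, int(i)) for i in cand])
    keep = proms >= min_prominence_frac * amplitude
    cand, proms = cand[keep], proms[keep]

    times = signal.sample_times[cand]
    order = np.lexsort((times, -proms))  # descending prominence, earlier first
    kept: list[int] = []
    kept_times: list[float] = []
    for j in order:
        t = times[j]
        if all(abs(t - tk) >= min_distance - _DISTANCE_TOL_S for tk in kept_times):
            kept.append(int(j))
            kept_times.append(float(t))
    kept.sort(key=lambda j: times[j])
    peaks = tuple(
        PeakCandidate(
            index=int(cand[j]),
            time=float(times[j]),
            height=float(values[cand[j]]),
            prominence=float(proms[j]),
        )
        for j in kept
    )
    return TapSeries(
        signal.key,
        signal.method,
        np.array([p.time for p in peaks]),
        peaks,
        polarity,
    )


def detect_trial(
    position: SampledSignal,
    accel: SampledSignal,
    params: DetectionParams = DetectionParams(),
) -> TrialDetections:
    """Detect contacts on both streams of one trial.

    Returns position contacts (minima), position apexes (maxima; metadata
    only, they feed no metric) and acceleration contacts (maxima).
    Degenerate-signal errors are re-raised tagged with the trial key.
    """
    out = []
    for sig, polarity in (
        (position, "minima"),
        (position, "maxima"),
        (accel, "maxima"),
    ):
        try:
            out.append(
                find_peaks(
                    sig, params.min_distance, params.min_prominence_frac, polarity
                )
            )
        except DegenerateSignalError as err:
            raise DegenerateSignalError(f"{sig.key} [{sig.method}]: {err}") from err
    return TrialDetections(*out)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def tap_series_frame(series: Sequence[TapSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for p in s.peaks:
            rows.append(
                {
                    "subject_id": s.key.subject_id,
                    "hand": s.key.hand,
                    "trial_index": s.key.trial_index,
                    "method": s.method,
                    "polarity": s.polarity,
                    "tap_time_seconds": p.time,
                    "height": p.height,
                    "prominence": p.prominence,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "hand",
            "trial_index",
            "method",
            "polarity",
            "tap_time_seconds",
            "height",
            "prominence",
        ],
    )


def write_taps_csv(series: Sequence[TapSeries], path) -> None:
    tap_series_frame(series).to_csv(path, index=False)


def read_taps_csv(path) -> list[TapSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    group_cols = ["subject_id", "hand", "trial_index", "method", "polarity"]
    for (subj, hand, idx, method, polarity), g in df.groupby(group_cols, sort=False):
        g = g.sort_values("tap_time_seconds")
        peaks = tuple(
            PeakCandidate(
                index=-1,
                time=float(r.tap_time_seconds),
                height=float(r.height),
                prominence=float(r.prominence),
            )
            for r in g.itertuples()
        )
        out.append(
            TapSeries(
                TrialKey(str(subj), str(hand), int(idx)),
                str(method),
                g["tap_time_seconds"].to_numpy(),
                peaks,
                str(polarity),  # type: ignore[arg-type]
            )
        )
    return out
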
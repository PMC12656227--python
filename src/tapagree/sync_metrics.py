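"""Event-based synchronization, 10 s windowing and per-trial tap metrics.

The camera (240 Hz) and IMU (100 Hz) streams are never resampled.  Each
detected contact series is aligned by its own first contact (t = 0) and a
closed 10 s window [0, 10] is retained, so a tap exactly on the boundary
counts.  The residual timing uncertainty of this event-based procedure is
bounded by half a sampling interval per stream (~2 ms at 240 Hz, 5 ms at
100 Hz), negligible against 125-250 ms inter-tap intervals.

Per trial the number of taps (the first tap included) and the inter-tap
intervals are computed with their mean and sample (n-1) standard deviation;
trials with fewer than two taps in either method cannot yield an ITI and are
flagged invalid.  Subject x hand scores are the arithmetic mean over the
valid trials of the hand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .detection import TapSeries

__all__ = [
    "DEFAULT_WINDOW_S",
    "UnsynchronizableTrialError",
    "TrialMetrics",
    "SubjectHandSummary",
    "timing_uncertainty",
    "synchronize",
    "trial_metrics",
    "aggregate_subject_hand",
    "metrics_frame",
    "summaries_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 10.0
_WINDOW_TOL_S = 1e-9  # closed-boundary tolerance for float tap times


class UnsynchronizableTrialError(ValueError):
    """A contact series is empty; no reference event exists."""


@dataclass(frozen=True)
class TrialMetrics:
    """Per-trial tap count and inter-tap-interval statistics for one method."""

    key: tuple
    method: str
    n_taps: int
    itis: np.ndarray
    iti_mean: float
    iti_sd: float
    valid: bool

    def __post_init__(self) -> None:
        itis = np.asarray(self.itis, dtype=float)
        object.__setattr__(self, "itis", itis)
        if self.n_taps >= 1 and itis.size != self.n_taps - 1:
            raise ValueError("n_taps must equal len(itis) + 1")
        if np.any(itis <= 0):
            raise ValueError("all inter-tap intervals must be > 0")


@dataclass(frozen=True)
class SubjectHandSummary:
    subject_id: str
    hand: str
    method: str
    n_taps_mean: float
    iti_mean_mean: float
    n_trials_used: int


def timing_uncertainty(rate: float) -> float:
    """Half-sampling-interval bound on event-time error, in seconds."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return 0.5 / rate


def synchronize(
    contacts_a: TapSeries,
    contacts_b: TapSeries,
    window: float = DEFAULT_WINDOW_S,
) -> tuple[TapSeries, TapSeries]:
    """Align two contact series on their own first contacts and window them.

    Each series is translated so its first tap sits at t = 0, then taps with
    t in the closed interval [0, window] are retained.  Native rates are
    untouched; no resampling occurs.
    """
    out = []
    for series in (contacts_a, contacts_b):
        if series.n_taps == 0:
            raise UnsynchronizableTrialError(
                f"{series.key} [{series.method}]: no taps to synchronize on"
            )
        shifted = series.shifted(-float(series.tap_times[0]))
        keep = shifted.tap_times <= window + _WINDOW_TOL_S
        out.append(
            replace(
                shifted,
                tap_times=shifted.tap_times[keep],
                peaks=tuple(p for p, k in zip(shifted.peaks, keep) if k),
            )
        )
    return out[0], out[1]


def trial_metrics(taps: TapSeries) -> TrialMetrics:
    """Tap count and ITI statistics for one synchronized series.

    A series with fewer than two taps has no ITI and is flagged
    ``valid=False`` (flagged, not thrown; exclusion happens downstream).
    The ITI standard deviation uses the n-1 denominator and is NaN when
    fewer than two intervals exist.
    """
    t = taps.tap_times
    n = taps.n_taps
    itis = np.diff(t)
    iti_mean = float(itis.mean()) if itis.size else float("nan")
    iti_sd = float(itis.std(ddof=1)) if itis.size >= 2 else float("nan")
    return TrialMetrics(
        key=tuple(taps.key),
        method=taps.method,
        n_taps=n,
        itis=itis,
        iti_mean=iti_mean,
        iti_sd=iti_sd,
        valid=n >= 2,
    )


def aggregate_subject_hand(
    metrics: Sequence[TrialMetrics],
) -> list[SubjectHandSummary]:
    """Average valid trials into subject x hand x method scores.

    Invalid trials are ignored; a (subject, hand, method) group with no valid
    trial is dropped with a logged warning.
    """
    groups: dict[tuple, list[TrialMetrics]] = {}
    dropped: set[tuple] = set()
    for m in metrics:
        subject_id, hand = m.key[0], m.key[1]
        gkey = (subject_id, hand, m.method)
        if not m.valid:
            dropped.add(gkey)
            continue
        groups.setdefault(gkey, []).append(m)
    for gkey in dropped - set(groups):
        logger.warning("no valid trials for %s; group excluded", gkey)
    out = []
    for (subject_id, hand, method), ms in groups.items():
        out.append(
            SubjectHandSummary(
                subject_id=subject_id,
                hand=hand,
                method=method,
                n_taps_mean=float(np.mean([m.n_taps for m in ms])),
                iti_mean_mean=float(np.mean([m.iti_mean for m in ms])),
                n_trials_used=len(ms),
            )
        )
    return out


def metrics_frame(metrics: Sequence[TrialMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": m.key[0],
                "hand": m.key[1],
                "trial_index": m.key[2],
                "method": m.method,
                "n_taps": m.n_taps,
                "iti_mean": m.iti_mean,
                "iti_sd": m.iti_sd,
                "valid": m.valid,
            }
            for m in metrics
        ]
    )


def summaries_frame(summaries: Sequence[SubjectHandSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
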
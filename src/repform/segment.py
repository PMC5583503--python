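"""Repetition segmentation by gyroscope peak detection and zero-crossing search.

A session is cut into single-repetition epochs using the gyroscope
channel with the largest amplitude for the exercise: local maxima of that
signal mark repetitions, and each epoch runs between the zero-crossing
immediately before and immediately after its peak.  Exercises whose
dominant gyroscope lobe is negative are handled by canonicalizing signal
polarity before detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .preprocess import SIGNAL_NAMES, SignalSet

logger = logging.getLogger(__name__)

__all__ = [
    "Repetition",
    "select_segmentation_channel",
    "detect_peaks",
    "find_boundaries",
    "segment_repetitions",
]

GYRO_CHANNELS = ("gyro_x", "gyro_y", "gyro_z")

DEFAULT_LABEL = "Acceptable"


@dataclass
class Repetition:
    """One segmented exercise repetition and its epoch of all 18 signals."""

    session_id: str
    exercise: str
    rep_number: int
    start_index: int
    peak_index: int
    end_index: int
    signals: SignalSet
    label: str = DEFAULT_LABEL
    #: True once an exercise professional (or an accepted auto-label
    #: proposal) has explicitly confirmed the label
    labeled: bool = False

    def __post_init__(self) -> None:
        if not self.start_index < self.peak_index < self.end_index:
            raise ValueError(
                f"repetition indices must satisfy start < peak < end, got "
                f"({self.start_index}, {self.peak_index}, {self.end_index})"
            )
        if self.rep_number < 1:
            raise ValueError("rep_number must be >= 1")
        if len(self.signals) != self.end_index - self.start_index:
            raise ValueError("epoch signals must cover exactly [start_index, end_index)")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.session_id, self.exercise, self.rep_number)

    def __len__(self) -> int:
        return self.end_index - self.start_index


def select_segmentation_channel(signals: SignalSet, channel: str | None = None) -> str:
    """Pick the gyroscope channel with the largest peak-to-peak range.

    An explicitly named channel is validated against the 18-channel list
    and returned as-is.  Ties break toward the lowest-index channel of
    (gyro_x, gyro_y, gyro_z).
    """
    if channel is not None:
        if channel not in SIGNAL_NAMES:
            raise ValueError(f"unknown channel {channel!r}; expected one of {SIGNAL_NAMES}")
        return channel
    ranges = [float(np.ptp(signals[name])) for name in GYRO_CHANNELS]
    return GYRO_CHANNELS[int(np.argmax(ranges))]  # argmax keeps the first on ties


def detect_peaks(
    signal: np.ndarray,
    fs: float,
    min_prominence: float = 0.3,
    min_separation: float = 1.0,
    min_height: float = 0.0,
) -> np.ndarray:
    """Indices of local maxima with prominence >= ``min_prominence`` of the
    signal's range, separated by at least ``min_separation`` seconds.

    ``min_height`` is an absolute floor in the signal's own units; the
    relative prominence criterion alone cannot reject a signal that is
    nothing but noise, since noise sets its own range.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 3:
        raise ValueError("signal must contain at least 3 samples")
    amplitude = float(np.ptp(signal))
    if amplitude == 0.0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(
        signal,
        height=min_height if min_height > 0 else None,
        prominence=min_prominence * amplitude,
        distance=max(int(round(min_separation * fs)), 1),
    )
    return peaks


def find_boundaries(signal: np.ndarray, peak: int) -> tuple[int, int]:
    """Zero-crossings bracketing a positive peak.

    ``start`` is the last index ``i < peak`` with
    ``signal[i] <= 0 < signal[i+1]`` (the sign change leading into the
    peak's lobe), clamped to 0 when the lobe reaches the stream edge;
    ``end`` is the first index ``j > peak`` with
    ``signal[j-1] > 0 >= signal[j]``, clamped to the last index.  The
    boundaries are whole-sample indices so that all 18 channels can be
    sliced identically.
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if not 0 <= peak < n:
        raise IndexError(f"peak index {peak} outside signal of length {n}")
    if signal[peak] <= 0:
        raise ValueError("find_boundaries expects a positive peak (canonicalize polarity first)")
    start = 0
    for i in range(peak - 1, -1, -1):
        if signal[i] <= 0 < signal[i + 1]:
            start = i
            break
    end = n - 1
    for j in range(peak + 1, n):
        if signal[j - 1] > 0 >= signal[j]:
            end = j
            break
    return start, end


def segment_repetitions(
    signals: SignalSet,
    session_id: str | None = None,
    exercise: str | None = None,
    channel: str | None = None,
    min_prominence: float = 0.3,
    min_separation: float = 1.0,
    min_height: float = 10.0,
) -> list[Repetition]:
    """Cut a processed session into repetition epochs.

    The segmentation channel is selected (or validated), its polarity is
    canonicalized — if the largest-magnitude extremum is negative the
    signal is negated so peaks are maxima — then peaks are detected and
    their bracketing zero-crossings become epoch boundaries.  Epochs that
    would overlap are resolved by truncating the earlier epoch's end to
    the later epoch's start.  Every repetition carries the identically
    sliced 18-channel epoch and the default "Acceptable" label.

    ``min_height`` (default 10 deg/s) is the movement noise floor: a
    session containing no motion, only sensor noise, yields zero
    repetitions rather than noise peaks.
    """
    session_id = signals.session_id if session_id is None else session_id
    exercise = signals.exercise if exercise is None else exercise
    name = select_segmentation_channel(signals, channel)
    x = np.asarray(signals[name], dtype=float)
    if abs(float(np.min(x))) > abs(float(np.max(x))):
        x = -x
    peaks = detect_peaks(x, signals.fs, min_prominence, min_separation, min_height)
    if len(peaks) == 0:
        logger.warning(
            "no repetitions found in session %r (channel %s)", session_id, name
        )
        return []
    bounds = [find_boundaries(x, int(p)) for p in peaks]
    reps: list[Repetition] = []
    for i, (peak, (start, end)) in enumerate(zip(peaks, bounds)):
        if i + 1 < len(bounds) and end > bounds[i + 1][0]:
            end = bounds[i + 1][0]  # truncate into the next epoch's start
            logger.warning("epoch %d truncated to avoid overlap", i + 1)
        end = max(end, int(peak) + 1)
        reps.append(
            Repetition(
                session_id=session_id,
                exercise=exercise,
                rep_number=i + 1,
                start_index=int(start),
                peak_index=int(peak),
                end_index=int(end),
                signals=signals.slice(int(start), int(end)),
            )
        )
    return reps
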
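"""Gait-cycle segmentation and 101-point time-normalization.

Running gait cycles are delimited by successive maxima of the right foot's
anterior-posterior position relative to the pelvis.  Each boundary-to-boundary
window is resampled by linear interpolation onto a percent-of-gait-cycle grid
of 101 points (0, 1, ..., 100 %), cycles from the acceleration and
deceleration phases of the run are trimmed symmetrically, and the retained
cycles are averaged pointwise into one waveform per signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io import SessionRecording

#: Percent-of-gait-cycle grid shared by all normalized cycles.
PERCENT_GRID = np.linspace(0.0, 100.0, 101)

#: Plausibility band for running stride durations, seconds.
DEFAULT_DURATION_BAND = (0.4, 1.5)


class SegmentationError(RuntimeError):
    """Raised when a recording cannot be segmented into gait cycles."""


@dataclass
class CycleBoundaries:
    """Detected cycle boundaries: sample indices of AP-position maxima."""

    indices: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if np.any(np.diff(self.indices) <= 0):
            raise SegmentationError("boundary indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        """Boundary times in seconds."""
        return self.indices / self.sample_rate

    @property
    def durations(self) -> np.ndarray:
        """Stride durations in seconds (one per cycle)."""
        return np.diff(self.indices) / self.sample_rate

    @property
    def n_cycles(self) -> int:
        return len(self.indices) - 1


def detect_cycles(
    rec: SessionRecording,
    min_period_s: float = 0.4,
    prominence_frac: float = 0.1,
) -> CycleBoundaries:
    """Find gait-cycle boundaries as maxima of the foot AP-position signal.

    Maxima must be separated by at least ``min_period_s`` (below any plausible
    running stride period) and have a prominence of at least
    ``prominence_frac`` of the signal's range.
    """
    if "foot_ap_position" not in rec.signals:
        raise SegmentationError("recording has no foot_ap_position signal")
    x = np.asarray(rec.signals["foot_ap_position"], dtype=float)
    if len(x) < 3:
        raise SegmentationError("need at least 3 samples to detect maxima")
    signal_range = float(np.max(x) - np.min(x))
    if signal_range == 0.0:
        raise SegmentationError(
            "segmentation failure: foot_ap_position is constant (range 0)"
        )
    distance = max(int(round(min_period_s * rec.sample_rate)), 1)
    peaks, _ = find_peaks(x, distance=distance, prominence=prominence_frac * signal_range)
    if len(peaks) < 2:
        raise SegmentationError(
            f"segmentation failure: found {len(peaks)} qualifying maxima "
            f"(need >= 2; min separation {distance} samples, "
            f"prominence threshold {prominence_frac * signal_range:.4g}, "
            f"signal range {signal_range:.4g})"
        )
    return CycleBoundaries(indices=peaks, sample_rate=rec.sample_rate)


def trim_transients(boundaries: CycleBoundaries, n_trim: int = 3) -> CycleBoundaries:
    """Drop the first and last ``n_trim`` complete cycles (run transients)."""
    if n_trim < 0:
        raise ValueError("n_trim must be >= 0")
    if n_trim == 0:
        return CycleBoundaries(indices=boundaries.indices.copy(), sample_rate=boundaries.sample_rate)
    remaining = boundaries.n_cycles - 2 * n_trim
    if remaining < 1:
        raise SegmentationError(
            f"cannot trim {n_trim} cycles from each end of {boundaries.n_cycles} cycles"
        )
    idx = boundaries.indices[n_trim : len(boundaries.indices) - n_trim]
    return CycleBoundaries(indices=idx, sample_rate=boundaries.sample_rate)


@dataclass
class NormalizedCycleSet:
    """Per-run stack of 101-point cycles per signal, plus the averaged waveform."""

    cycles: dict[str, np.ndarray]  # signal -> (n_cycles_used, 101)
    mean_waveforms: dict[str, np.ndarray]  # signal -> (101,)
    n_cycles_used: int
    n_cycles_dropped: int
    stride_frequency: float  # Hz, 1 / mean retained stride duration
    meta: dict = field(default_factory=dict)


def normalize_cycles(
    rec: SessionRecording,
    boundaries: CycleBoundaries,
    drop_outliers: bool = True,
    outlier_sd: float = 3.0,
) -> NormalizedCycleSet:
    """Resample each retained cycle onto the 101-point grid and average.

    Cycles whose duration deviates more than ``outlier_sd`` robust standard
    deviations (1.4826 x the median absolute deviation, so a lone false
    maximum cannot inflate the spread estimate) from the run's median
    duration are dropped before averaging; a 20 ms floor on the threshold
    keeps ordinary stride-to-stride timing variation from being rejected.
    The dropped count is reported in the result.
    """
    if boundaries.n_cycles < 1:
        raise SegmentationError("need at least one cycle to normalize")
    idx = boundaries.indices
    durations = boundaries.durations
    keep = np.ones(len(durations), dtype=bool)
    if drop_outliers and len(durations) > 1:
        med = np.median(durations)
        robust_sd = 1.4826 * float(np.median(np.abs(durations - med)))
        threshold = max(outlier_sd * robust_sd, 0.02)
        keep = np.abs(durations - med) <= threshold
    if not keep.any():
        raise SegmentationError("all cycles rejected as duration outliers")
    time = rec.time
    cycles: dict[str, list[np.ndarray]] = {name: [] for name in rec.signals}
    for ci in np.flatnonzero(keep):
        a, b = idx[ci], idx[ci + 1]
        if b - a < 1:
            raise SegmentationError(f"cycle {ci} shorter than 2 samples")
        grid_t = np.linspace(time[a], time[b], len(PERCENT_GRID))
        seg_t = time[a : b + 1]
        for name, series in rec.signals.items():
            cycles[name].append(np.interp(grid_t, seg_t, series[a : b + 1]))
    stacked = {name: np.vstack(rows) for name, rows in cycles.items()}
    mean_wave = {name: stack.mean(axis=0) for name, stack in stacked.items()}
    kept_durations = durations[keep]
    return NormalizedCycleSet(
        cycles=stacked,
        mean_waveforms=mean_wave,
        n_cycles_used=int(keep.sum()),
        n_cycles_dropped=int((~keep).sum()),
        stride_frequency=float(1.0 / kept_durations.mean()),
        meta={
            "participant": rec.participant_id,
            "day": rec.day,
            "surface": rec.surface,
            "run": rec.run,
            "calibration": rec.calibration,
        },
    )


def segment_recording(
    rec: SessionRecording,
    min_period_s: float = 0.4,
    prominence_frac: float = 0.1,
    n_trim: int = 3,
    drop_outliers: bool = True,
) -> NormalizedCycleSet:
    """Convenience wrapper: detect -> trim -> normalize for one recording."""
    boundaries = detect_cycles(rec, min_period_s=min_period_s, prominence_frac=prominence_frac)
    trimmed = trim_transients(boundaries, n_trim=n_trim)
    return normalize_cycles(rec, trimmed, drop_outliers=drop_outliers)
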
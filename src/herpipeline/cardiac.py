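"""R-peak detection and interbeat-interval bookkeeping.

Detection is a sliding-window local-maximum search on the (ICA-)ECG:
a sample is a peak when it is the maximum of the window centred on it,
exceeds an adaptive amplitude floor, and respects a refractory period.
Polarity is resolved automatically by scoring both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.ndimage import maximum_filter1d

__all__ = [
    "HeartbeatSource",
    "HeartbeatSeries",
    "detect_rpeaks",
    "flag_ectopic",
    "apply_corrections",
]


class HeartbeatSource(str, Enum):
    TRUE = "TRUE"
    DETECTED = "DETECTED"
    SURROGATE = "SURROGATE"


@dataclass
class HeartbeatSeries:
    """R-peak samples with derived interbeat intervals (ms) and flags."""

    rpeak_samples: np.ndarray  # strictly increasing ints
    fs: float
    source: HeartbeatSource = HeartbeatSource.DETECTED
    ectopic_flags: np.ndarray = field(default=None)  # bool, aligned to ibi_ms

    def __post_init__(self) -> None:
        self.rpeak_samples = np.asarray(self.rpeak_samples, dtype=int)
        if len(self.rpeak_samples) > 1 and np.any(np.diff(self.rpeak_samples) <= 0):
            raise ValueError("R-peak samples must be strictly increasing")
        if self.ectopic_flags is None:
            self.ectopic_flags = np.zeros(max(len(self.rpeak_samples) - 1, 0), dtype=bool)
        else:
            self.ectopic_flags = np.asarray(self.ectopic_flags, dtype=bool)
            if len(self.ectopic_flags) != max(len(self.rpeak_samples) - 1, 0):
                raise ValueError("ectopic_flags must align with the IBI series")

    @property
    def ibi_ms(self) -> np.ndarray:
        return np.diff(self.rpeak_samples) * 1000.0 / self.fs

    def __len__(self) -> int:
        return len(self.rpeak_samples)

    def ibi_flags_around(self, peak_index: int) -> tuple[bool, bool]:
        """(preceding-IBI flagged, following-IBI flagged) for one peak."""
        prev_f = bool(self.ectopic_flags[peak_index - 1]) if peak_index >= 1 else False
        next_f = (
            bool(self.ectopic_flags[peak_index])
            if peak_index < len(self.ectopic_flags)
            else False
        )
        return prev_f, next_f


def _detect_one_polarity(
    trace: np.ndarray, fs: float, window_ms: float, refractory_ms: float
) -> np.ndarray:
    win = max(int(round(window_ms / 1000.0 * fs)) | 1, 3)
    refr = int(round(refractory_ms / 1000.0 * fs))
    local_max = maximum_filter1d(trace, size=win, mode="nearest")
    is_peak = (trace >= local_max) & (trace > 0)
    cand = np.nonzero(is_peak)[0]
    if len(cand) == 0:
        return cand
    # adaptive amplitude floor: half the median of the top-K candidate
    # amplitudes, K sized from a 2 s ceiling on the RR interval so the
    # reference tracks QRS height, not the noise candidates
    k = max(1, int(len(trace) / fs / 2.0))
    top = np.sort(trace[cand])[-k:]
    floor = 0.5 * float(np.median(top))
    cand = cand[trace[cand] >= floor]
    # enforce refractory, keeping the larger of two close peaks
    kept: list[int] = []
    for c in cand:
        if kept and c - kept[-1] < refr:
            if trace[c] > trace[kept[-1]]:
                kept[-1] = int(c)
        else:
            kept.append(int(c))
    return np.asarray(kept, dtype=int)


def detect_rpeaks(
    ecg: np.ndarray,
    fs: float,
    window_ms: float = 600.0,
    refractory_ms: float = 300.0,
) -> HeartbeatSeries:
    """Sliding-window local-maximum R-peak detection.

    Both polarities are tried and the orientation whose peak train is more
    regular (lower IBI coefficient of variation, more beats) wins; an
    inverted ECG therefore yields the same peak samples as an upright one.
    An empty result is returned with a warning rather than an exception.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) <= int(window_ms / 1000.0 * fs):
        raise ValueError("trace shorter than the detection window")
    best: np.ndarray | None = None
    best_score = -np.inf
    for sign in (1.0, -1.0):
        peaks = _detect_one_polarity(sign * ecg, fs, window_ms, refractory_ms)
        if len(peaks) < 2:
            score = float(len(peaks)) - 1e6
        else:
            ibi = np.diff(peaks)
            cv = ibi.std() / ibi.mean() if ibi.mean() > 0 else np.inf
            # regularity times peak prominence: the R-peak orientation
            # beats its own filter-ringing trough on amplitude
            amp = float(np.median(sign * ecg[peaks]))
            score = len(peaks) / (1.0 + cv) * max(amp, 1e-12)
        if score > best_score:
            best_score = score
            best = peaks
    if best is None or len(best) == 0:
        import warnings

        warnings.warn("no R-peaks found; returning an empty series", RuntimeWarning)
        best = np.asarray([], dtype=int)
    return HeartbeatSeries(best, fs=fs, source=HeartbeatSource.DETECTED)


def flag_ectopic(series: HeartbeatSeries, deriv_threshold: float | None = None) -> HeartbeatSeries:
    """Flag outlier interbeat intervals via the IBI first difference.

    Positions where |diff(IBI)| exceeds the threshold (default: 3 robust
    SDs of the difference series, MAD-based) flag both adjacent IBIs.
    Flagged intervals stay in the record but their bounding R-peaks are
    excluded as heartbeat-evoked-response lock points downstream.
    """
    ibi = series.ibi_ms
    if len(ibi) < 3:
        raise ValueError("need at least 3 interbeat intervals to flag ectopy")
    d = np.diff(ibi)
    if deriv_threshold is None:
        mad = np.median(np.abs(d - np.median(d)))
        robust_sd = 1.4826 * mad
        if robust_sd == 0:
            robust_sd = d.std() if d.std() > 0 else np.inf
        deriv_threshold = 3.0 * robust_sd
    flags = np.zeros(len(ibi), dtype=bool)
    hits = np.nonzero(np.abs(d) > deriv_threshold)[0]
    flags[hits] = True      # IBI before the jump
    flags[hits + 1] = True  # IBI after the jump
    return HeartbeatSeries(
        series.rpeak_samples.copy(), fs=series.fs, source=series.source,
        ectopic_flags=flags,
    )


def apply_corrections(
    series: HeartbeatSeries,
    add_samples: list[int] | None = None,
    remove_samples: list[int] | None = None,
) -> HeartbeatSeries:
    """Deterministic replacement for interactive beat editing.

    ``add_samples`` are inserted, ``remove_samples`` dropped; the result
    is re-sorted and flags recomputed by the caller if needed.
    """
    peaks = set(series.rpeak_samples.tolist())
    for s in remove_samples or []:
        peaks.discard(int(s))
    for s in add_samples or []:
        peaks.add(int(s))
    return HeartbeatSeries(
        np.asarray(sorted(peaks), dtype=int), fs=series.fs, source=series.source
    )
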
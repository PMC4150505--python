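"""Waveform smoothing, R-peak / PPG-peak detection, and the per-beat PTT series.

Pulse transit time (PTT) is measured beat-to-beat as the interval between an
ECG R-peak and the PPG pulse maximum inside the same cardiac cycle.  Both
channels are first smoothed with a short centered moving average; R-peaks are
found with a derivative-energy statistic under an adaptive (median + k*MAD)
threshold and a physiologic refractory period, and each R-R interval is then
searched for its PPG maximum inside a plausible transit-time window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BeatAnnotations",
    "PTTSeries",
    "FluctuationReport",
    "sliding_window_filter",
    "detect_r_peaks",
    "detect_ppg_peaks",
    "compute_ptt_series",
    "check_signal_fluctuation",
    "extract_ptt",
]

log = logging.getLogger(__name__)

#: Minimum interval between successive R-peaks (s): excludes double detections.
REFRACTORY_S = 0.250

#: PPG search window after each R-peak (s): transit times below 100 ms are
#: not physiologic for a fingertip site; beyond 600 ms the pulse belongs to
#: the next cycle.
PPG_SEARCH_MIN_S = 0.100
PPG_SEARCH_MAX_S = 0.600

#: Default validity rule: a session whose PTT coefficient of variation
#: exceeds this, or with more than this fraction of unmatched cycles, is
#: considered too unstable to calibrate or estimate from.
CV_THRESHOLD = 0.2
UNMATCHED_THRESHOLD = 0.2
MIN_BEATS = 10


@dataclass
class BeatAnnotations:
    """Detected fiducials: R-peak indices, PPG peak indices, matched pairs.

    ``matched_pairs[i] = (r, p)`` satisfies ``r < p < next_r`` — the PPG peak
    lies in the same cardiac cycle as its R-peak.  Pairing is injective by
    construction (one PPG peak per R-R interval at most).
    """

    r_peak_indices: np.ndarray
    ppg_peak_indices: np.ndarray
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r_peak_indices = np.asarray(self.r_peak_indices, dtype=int)
        self.ppg_peak_indices = np.asarray(self.ppg_peak_indices, dtype=int)
        for name, idx in (("r_peak", self.r_peak_indices),
                          ("ppg_peak", self.ppg_peak_indices)):
            if len(idx) > 1 and not np.all(np.diff(idx) > 0):
                raise ValueError(f"{name} indices must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        """Number of complete cardiac cycles (R-R intervals)."""
        return max(0, len(self.r_peak_indices) - 1)


@dataclass
class PTTSeries:
    """Per-beat PTT values (ms) with the R-peak time of each beat (s)."""

    ptt_ms: np.ndarray
    beat_times_s: np.ndarray
    n_cycles: int = 0

    def __post_init__(self) -> None:
        self.ptt_ms = np.asarray(self.ptt_ms, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if len(self.ptt_ms) != len(self.beat_times_s):
            raise ValueError("ptt_ms and beat_times_s must have equal length")
        if np.any(self.ptt_ms <= 0):
            raise ValueError("all PTT values must be positive")
        if self.n_cycles == 0:
            self.n_cycles = len(self.ptt_ms)

    @property
    def deltas_ms(self) -> np.ndarray:
        """Successive differences ΔPTT[i] = PTT[i+1] − PTT[i] (ms)."""
        return np.diff(self.ptt_ms)

    def __len__(self) -> int:
        return len(self.ptt_ms)


def sliding_window_filter(
    signal: np.ndarray, fs: float, window_ms: float = 10.0
) -> np.ndarray:
    """Centered moving-average smoother with symmetric edge shrinking.

    The window duration is converted to an odd sample count (nearest odd
    integer to ``window_ms * fs / 1000``; a 10 ms window at 250 Hz spans 3
    samples).  Near the edges the half-width shrinks symmetrically so the
    output has the same length as the input and no phase shift anywhere.
    A 1-sample window is the identity.
    """
    if window_ms <= 0:
        raise ValueError(f"window_ms must be positive, got {window_ms}")
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    w = int(round(window_ms * fs / 1000.0))
    if w % 2 == 0:
        w += 1
    w = max(w, 1)
    if w > n:
        raise ValueError(f"window of {w} samples exceeds signal length {n}")
    if w == 1:
        return signal.copy()
    half = w // 2
    csum = np.concatenate(([0.0], np.cumsum(signal)))
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - h
    hi = idx + h
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Detect ECG R-peaks; returns ascending sample indices.

    Simplified Pan–Tompkins-style scheme: the detection statistic is the
    smoothed squared first difference of the (already filtered) ECG; peaks of
    the statistic above an adaptive threshold (running median + 6*MAD) and
    separated by a 250 ms refractory period mark candidate beats, and each
    candidate is refined to the local ECG maximum within ±60 ms.  An empty
    array (with a warning) is returned when nothing crosses the threshold.
    """
    ecg = np.asarray(ecg, dtype=float)
    n = len(ecg)
    if n < 3:
        warnings.warn("signal too short for R-peak detection", stacklevel=2)
        return np.array([], dtype=int)

    denergy = np.zeros(n)
    denergy[1:] = np.diff(ecg) ** 2
    # integrate over ~QRS width to merge the two derivative lobes of each R-wave
    stat = sliding_window_filter(denergy, fs, window_ms=min(80.0, 1000.0 * n / fs))

    med = np.median(stat)
    mad = np.median(np.abs(stat - med))
    thresh = med + 6.0 * mad
    if mad == 0 and np.all(stat <= thresh):
        warnings.warn("no R-peaks found (flat detection statistic)", stacklevel=2)
        return np.array([], dtype=int)

    refractory = max(1, int(round(REFRACTORY_S * fs)))
    cand, _ = find_peaks(stat, height=thresh, distance=refractory)
    if len(cand) == 0:
        warnings.warn("no R-peaks found", stacklevel=2)
        return np.array([], dtype=int)

    # refine each candidate to the ECG local maximum (earliest sample on ties)
    radius = max(1, int(round(0.060 * fs)))
    peaks = []
    for c in cand:
        lo = max(0, c - radius)
        hi = min(n, c + radius + 1)
        peaks.append(lo + int(np.argmax(ecg[lo:hi])))
    peaks = np.array(sorted(set(peaks)), dtype=int)
    # refinement can merge neighbors; enforce the refractory period again
    if len(peaks) > 1:
        keep = [0]
        for i in range(1, len(peaks)):
            if peaks[i] - peaks[keep[-1]] >= refractory:
                keep.append(i)
        peaks = peaks[keep]
    return peaks


def detect_ppg_peaks(
    ppg: np.ndarray, fs: float, r_peaks: np.ndarray
) -> BeatAnnotations:
    """Locate at most one PPG pulse peak per R-R interval.

    For each consecutive R-peak pair the search window is
    ``(r + 100 ms, min(r + 600 ms, next_r))`` and the peak is the window
    argmax (earliest sample on ties), accepted only if it is a strict local
    maximum interior to the window — a cycle whose PPG maximum lies on the
    window boundary (pulse outside the physiologic range, or no pulse at
    all) yields no pair.
    """
    ppg = np.asarray(ppg, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 2:
        warnings.warn("fewer than 2 R-peaks: no cycles to search", stacklevel=2)
        return BeatAnnotations(r_peaks, np.array([], dtype=int), [])

    lo_off = int(np.ceil(PPG_SEARCH_MIN_S * fs))
    hi_off = int(np.floor(PPG_SEARCH_MAX_S * fs))
    pairs: list[tuple[int, int]] = []
    for r, r_next in zip(r_peaks[:-1], r_peaks[1:]):
        lo = r + lo_off
        hi = min(r + hi_off, r_next - 1)
        if hi <= lo:
            continue
        seg = ppg[lo : hi + 1]
        p = lo + int(np.argmax(seg))
        if p <= lo or p >= hi:
            continue  # maximum on the boundary: true peak outside the window
        if not (ppg[p] > ppg[p - 1] and ppg[p] >= ppg[p + 1]):
            continue  # not a genuine local maximum (e.g. flat signal)
        pairs.append((int(r), int(p)))
    ppg_idx = np.array([p for _, p in pairs], dtype=int)
    return BeatAnnotations(r_peaks, ppg_idx, pairs)


def compute_ptt_series(annotations: BeatAnnotations, fs: float) -> PTTSeries:
    """Convert matched (R, PPG) pairs to per-beat PTT in milliseconds."""
    if not annotations.matched_pairs:
        return PTTSeries(np.array([]), np.array([]), annotations.n_cycles)
    r = np.array([p[0] for p in annotations.matched_pairs], dtype=float)
    p = np.array([p[1] for p in annotations.matched_pairs], dtype=float)
    return PTTSeries(
        ptt_ms=(p - r) * 1000.0 / fs,
        beat_times_s=r / fs,
        n_cycles=annotations.n_cycles,
    )


@dataclass(frozen=True)
class FluctuationReport:
    """Validity verdict for a PTT series, with the statistic that decided it."""

    valid: bool
    reason: str
    cv: float | None = None
    unmatched_fraction: float | None = None


def check_signal_fluctuation(
    series: PTTSeries,
    cv_threshold: float = CV_THRESHOLD,
    unmatched_threshold: float = UNMATCHED_THRESHOLD,
    min_beats: int = MIN_BEATS,
) -> FluctuationReport:
    """Flag a recording as invalid when its PTT stream fluctuates too much.

    Rules (all configurable): fewer than ``min_beats`` matched beats;
    coefficient of variation of PTT above ``cv_threshold``; or more than
    ``unmatched_threshold`` of the cardiac cycles without a matched PPG peak.
    """
    n = len(series)
    if n < min_beats:
        return FluctuationReport(False, "insufficient beats")
    cv = float(np.std(series.ptt_ms, ddof=1) / np.mean(series.ptt_ms))
    unmatched = 1.0 - n / series.n_cycles if series.n_cycles > 0 else 1.0
    if cv > cv_threshold:
        return FluctuationReport(False, f"PTT coefficient of variation {cv:.3f} "
                                 f"exceeds {cv_threshold}", cv, unmatched)
    if unmatched > unmatched_threshold:
        return FluctuationReport(False, f"{unmatched:.1%} of cycles unmatched",
                                 cv, unmatched)
    return FluctuationReport(True, "ok", cv, unmatched)


def extract_ptt(record, filter_window_ms: float = 10.0) -> PTTSeries:
    """Full detection chain: smooth both channels, find fiducials, return PTT.

    Convenience wrapper used by the pipeline; both detection and peak
    localization operate on the filtered waveforms.
    """
    ecg = sliding_window_filter(record.ecg, record.fs, filter_window_ms)
    ppg = sliding_window_filter(record.ppg, record.fs, filter_window_ms)
    r_peaks = detect_r_peaks(ecg, record.fs)
    ann = detect_ppg_peaks(ppg, record.fs, r_peaks)
    series = compute_ptt_series(ann, record.fs)
    log.info(
        "%s/%s: %d R-peaks, %d matched beats",
        record.subject_id, record.session_label, len(r_peaks), len(series),
    )
    return series
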
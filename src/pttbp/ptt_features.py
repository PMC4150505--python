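"""Compensation features: PTT variability (PTTV), PTT variation (VPTT), and
the rolling 5-beat PTT average.

PTTV over a short window is the sample standard deviation of the successive
PTT differences in that window — a surrogate for beat-to-beat autonomic
regulation.  VPTT is the dimensionless deviation of PTT from the
sitting-calibration reference, (PTT − PTT0) / PTT0.  Each beat's features are
computed over the trailing window of W = 5 PTT values, and the window *mean*
(not the instantaneous beat) feeds the estimation model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .beat_detection import PTTSeries

__all__ = [
    "DEFAULT_WINDOW",
    "FeatureWindow",
    "CalibrationReference",
    "ptt_variability",
    "ptt_variation",
    "rolling_features",
    "session_reference",
    "session_summary",
]

#: Number of PTT values per feature window.
DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class FeatureWindow:
    """Features of one trailing PTT window, timestamped at its last beat."""

    beat_time_s: float
    ptt_window_ms: tuple[float, ...]
    mean_ptt_ms: float
    pttv_ms: float
    vptt: float


@dataclass(frozen=True)
class CalibrationReference:
    """Per-subject reference state, derived from the calibration-sitting session.

    ``ptt0_ms`` is the session mean PTT; ``pttv0_ms`` the session-level PTTV
    (mean of the rolling window PTTVs).
    """

    ptt0_ms: float
    pttv0_ms: float

    def __post_init__(self) -> None:
        if self.ptt0_ms <= 0:
            raise ValueError("ptt0_ms must be positive")
        if self.pttv0_ms < 0:
            raise ValueError("pttv0_ms must be non-negative")


def ptt_variability(ptt_window_ms) -> float:
    """PTTV of a window: sample SD of the successive PTT differences (ms).

    With the default 5-value window there are 4 differences and the SD uses
    denominator 3 (one fewer than the number of differences).  Constant and
    linearly ramping windows both give exactly 0 — PTTV responds to
    *changes in the beat-to-beat trend*, not to level or slope.
    """
    window = np.asarray(ptt_window_ms, dtype=float)
    if window.size < 3:
        raise ValueError(
            f"need at least 3 PTT values (2 differences), got {window.size}"
        )
    deltas = np.diff(window)
    return float(np.std(deltas, ddof=1))


def ptt_variation(ptt_ms: float, ptt0_ms: float) -> float:
    """VPTT: relative deviation of PTT from the sitting reference (unitless)."""
    if ptt0_ms <= 0:
        raise ValueError(f"ptt0_ms must be positive, got {ptt0_ms}")
    return (ptt_ms - ptt0_ms) / ptt0_ms


def _window_lengths(W: int, pttv_window: int | None) -> tuple[int, int]:
    """Resolve (mean window, PTTV window) sizes; PTTV may use one extra beat."""
    if W < 1:
        raise ValueError("W must be >= 1")
    pw = W if pttv_window is None else pttv_window
    if pw < 3:
        raise ValueError("PTTV window must hold at least 3 PTT values")
    return W, pw


def rolling_features(
    series: PTTSeries,
    reference: CalibrationReference,
    W: int = DEFAULT_WINDOW,
    pttv_window: int | None = None,
) -> list[FeatureWindow]:
    """One :class:`FeatureWindow` per beat, from the trailing ``W`` PTT values.

    Windows exist for beat indices >= max(W, pttv_window) − 1, so a series of
    n beats yields ``n − W + 1`` windows under the default convention.  The
    window mean PTT drives VPTT; PTTV comes from the trailing ``pttv_window``
    values (defaults to the same ``W`` — 4 differences for W = 5; set
    ``pttv_window = W + 1`` for the 5-difference convention).
    """
    W, pw = _window_lengths(W, pttv_window)
    n = len(series)
    start = max(W, pw) - 1
    if n <= start:
        warnings.warn(
            f"series of {n} beats is shorter than the feature window", stacklevel=2
        )
        return []
    out = []
    for i in range(start, n):
        window = series.ptt_ms[i - W + 1 : i + 1]
        mean_ptt = float(np.mean(window))
        out.append(
            FeatureWindow(
                beat_time_s=float(series.beat_times_s[i]),
                ptt_window_ms=tuple(window),
                mean_ptt_ms=mean_ptt,
                pttv_ms=ptt_variability(series.ptt_ms[i - pw + 1 : i + 1]),
                vptt=ptt_variation(mean_ptt, reference.ptt0_ms),
            )
        )
    return out


def session_reference(
    series: PTTSeries, W: int = DEFAULT_WINDOW, pttv_window: int | None = None
) -> CalibrationReference:
    """Reference state (PTT0, PTTV0) from a calibration-sitting PTT series.

    PTT0 is the mean of every PTT in the session; PTTV0 is the arithmetic
    mean of the rolling-window PTTVs over the whole session.
    """
    W, pw = _window_lengths(W, pttv_window)
    n = len(series)
    if n < max(W, pw):
        raise ValueError(
            f"calibration session has {n} beats; at least {max(W, pw)} required"
        )
    ptt0 = float(np.mean(series.ptt_ms))
    pttvs = [
        ptt_variability(series.ptt_ms[i - pw + 1 : i + 1])
        for i in range(max(W, pw) - 1, n)
    ]
    return CalibrationReference(ptt0_ms=ptt0, pttv0_ms=float(np.mean(pttvs)))


def session_summary(
    series: PTTSeries,
    reference: CalibrationReference,
    W: int = DEFAULT_WINDOW,
    pttv_window: int | None = None,
) -> FeatureWindow:
    """Session-level feature summary used for calibration and evaluation.

    Aggregates exactly like :func:`session_reference` — mean PTT over all
    beats, mean rolling PTTV — so that the sitting session summarized against
    its own reference has VPTT = 0 and PTTV − PTTV0 = 0 identically.
    """
    ref_of_self = session_reference(series, W, pttv_window)
    return FeatureWindow(
        beat_time_s=float(series.beat_times_s[-1]),
        ptt_window_ms=(),
        mean_ptt_ms=ref_of_self.ptt0_ms,
        pttv_ms=ref_of_self.pttv0_ms,
        vptt=ptt_variation(ref_of_self.ptt0_ms, reference.ptt0_ms),
    )
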
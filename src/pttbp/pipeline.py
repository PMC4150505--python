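"""End-to-end orchestration: collect sessions, fit, calibrate, estimate.

The pipeline runs in two interchangeable modes:

* the *waveform* route — PTT series come out of fiducial detection on the
  recorded (or rendered) ECG/PPG channels, with the fluctuation validity
  check applied;
* the *truth* route — PTT series are taken directly from a synthetic
  cohort's ground-truth tables, bypassing detection.  This is the entry
  point for exact parameter-recovery checks, where waveform quantization
  would otherwise dominate.

Either way the downstream flow is identical: per-subject reference state
from the calibration-sitting session, session-level feature summaries, a
pooled (or leave-one-subject-out) population regression for the
compensation constants c and d, and the two-posture solve for each
subject's a and b — once with compensation (the full model) and once with
c = d = 0 (the linear baseline, calibrated from the same two points).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .beat_detection import (
    FluctuationReport,
    PTTSeries,
    check_signal_fluctuation,
    extract_ptt,
)
from .bp_model import (
    CalibrationProfile,
    CoefficientSet,
    DegenerateCalibrationError,
    calibrate_subject,
    fit_population_coefficients,
    fit_population_fixed_effects,
)
from .config import RunConfig
from .ptt_features import (
    CalibrationReference,
    FeatureWindow,
    session_reference,
    session_summary,
)
from .protocol import validate_experiment, CohortSummary
from .synthetic import Cohort
from .waveform_io import SESSION_LABELS, SessionDataset

__all__ = [
    "SubjectSessions",
    "CalibrationResult",
    "collect_subject_data",
    "collect_truth_data",
    "fit_and_calibrate",
    "per_beat_points",
]

log = logging.getLogger(__name__)

MODELS = ("compensated", "linear")


@dataclass
class SubjectSessions:
    """One subject's per-session PTT series and resolved reference BP."""

    subject_id: str
    series: dict[str, PTTSeries] = field(default_factory=dict)
    resolved: dict[str, tuple[float, float]] = field(default_factory=dict)
    fluctuation: dict[str, FluctuationReport] = field(default_factory=dict)

    def complete(self) -> bool:
        return all(
            label in self.series
            and label in self.resolved
            and self.fluctuation[label].valid
            for label in SESSION_LABELS
        )


def collect_subject_data(
    sessions: list[SessionDataset], run: RunConfig
) -> tuple[list[SubjectSessions], CohortSummary]:
    """Waveform route: detect PTT in every session, apply validity checks.

    Returns per-subject data (complete subjects only carry all three valid
    sessions) plus the cohort validity summary.
    """
    by_subject: dict[str, SubjectSessions] = {}
    fluct: dict[tuple[str, str], bool] = {}
    for session in sessions:
        sid = session.subject_id
        sub = by_subject.setdefault(sid, SubjectSessions(sid))
        series = extract_ptt(session.record, run.filter_window_ms)
        verdict = check_signal_fluctuation(
            series, cv_threshold=run.fluctuation_cv_threshold
        )
        sub.series[session.session_label] = series
        sub.fluctuation[session.session_label] = verdict
        fluct[(sid, session.session_label)] = verdict.valid
        if session.valid:
            sub.resolved[session.session_label] = (
                session.resolved_sbp, session.resolved_dbp
            )
        if not verdict.valid:
            log.info("excluding %s/%s: %s", sid, session.session_label,
                     verdict.reason)
    summary = validate_experiment(sessions, fluct)
    return list(by_subject.values()), summary


def collect_truth_data(
    cohort: Cohort, use_true_session_bp: bool = False
) -> list[SubjectSessions]:
    """Truth route: per-subject data straight from a synthetic cohort.

    With ``use_true_session_bp`` the generator's exact session-level BP is
    used as the reference (noise-free inverse tests); otherwise the resolved
    oscillometer readings are used, as with recorded data.
    """
    resolved_lookup = {
        (s.subject_id, s.session_label): (s.resolved_sbp, s.resolved_dbp)
        for s in cohort.sessions
        if s.valid
    }
    out = []
    for law in cohort.subjects:
        sub = SubjectSessions(law.subject_id)
        for label in SESSION_LABELS:
            table = cohort.truth[(law.subject_id, label)]
            series = table.to_series()
            sub.series[label] = series
            sub.fluctuation[label] = check_signal_fluctuation(series)
            if use_true_session_bp:
                sub.resolved[label] = (table.session_sbp_mmHg,
                                       table.session_dbp_mmHg)
            elif (law.subject_id, label) in resolved_lookup:
                sub.resolved[label] = resolved_lookup[(law.subject_id, label)]
        out.append(sub)
    return out


def per_beat_points(
    cohort: Cohort, pressure_type: str, W: int = 5, pttv_window: int | None = None
) -> list[tuple[FeatureWindow, CalibrationReference, float]]:
    """Per-beat regression rows from a synthetic cohort's ground truth.

    Pairs each beat's rolling feature window with that beat's (possibly
    noisy) true BP — the beat-resolution alternative to session-level
    pooling for the population fit, usable when BP exists per beat rather
    than once per session.
    """
    from .ptt_features import rolling_features

    idx = 0 if pressure_type == "SBP" else 1
    rows: list[tuple[FeatureWindow, CalibrationReference, float]] = []
    start = max(W, pttv_window or W) - 1
    for law in cohort.subjects:
        ref = cohort.references[law.subject_id]
        for label in SESSION_LABELS:
            table = cohort.truth[(law.subject_id, label)]
            bp = (table.true_sbp_mmHg, table.true_dbp_mmHg)[idx]
            for k, w in enumerate(
                rolling_features(table.to_series(), ref, W, pttv_window)
            ):
                rows.append((w, ref, float(bp[start + k])))
    return rows


@dataclass
class CalibrationResult:
    """Everything the calibration phase produces."""

    profiles: dict[str, dict[str, CalibrationProfile]]  # model -> subject -> prof
    population: dict[str, dict[str, CoefficientSet]]  # subject -> ptype -> coeffs
    excluded: dict[str, str] = field(default_factory=dict)  # subject -> reason


def _session_features(
    sub: SubjectSessions, run: RunConfig
) -> tuple[CalibrationReference, dict[str, FeatureWindow]]:
    reference = session_reference(
        sub.series["calibration_sitting"], run.window_W, run.pttv_window
    )
    summaries = {
        label: session_summary(series, reference, run.window_W, run.pttv_window)
        for label, series in sub.series.items()
        if label in sub.resolved
    }
    return reference, summaries


def fit_and_calibrate(
    data: list[SubjectSessions], run: RunConfig
) -> CalibrationResult:
    """Population regression for (a, b, c, d), then per-subject a, b.

    Incomplete subjects (a missing/invalid session or unresolved reference
    BP) are excluded with a reason.  Under ``leave_one_out`` scope each
    subject's compensation constants come from a regression over everyone
    else's sessions; under ``pooled`` a single regression serves all.
    """
    usable = [s for s in data if s.complete()]
    excluded = {
        s.subject_id: "; ".join(
            f"{label}: {s.fluctuation[label].reason}"
            if label in s.fluctuation and not s.fluctuation[label].valid
            else f"{label}: missing or unresolved"
            for label in SESSION_LABELS
            if not (
                label in s.series
                and label in s.resolved
                and s.fluctuation[label].valid
            )
        )
        for s in data
        if not s.complete()
    }
    if len(usable) < 2:
        raise ValueError(
            f"need at least 2 complete subjects, have {len(usable)} "
            f"(excluded: {excluded})"
        )

    refs: dict[str, CalibrationReference] = {}
    sums: dict[str, dict[str, FeatureWindow]] = {}
    for sub in usable:
        refs[sub.subject_id], sums[sub.subject_id] = _session_features(sub, run)

    def points(ptype: str, exclude: str | None = None):
        idx = 0 if ptype == "SBP" else 1
        return [
            (sums[s.subject_id][label], refs[s.subject_id],
             s.resolved[label][idx], s.subject_id)
            for s in usable
            if s.subject_id != exclude
            for label in SESSION_LABELS
        ]

    def fit(ptype: str, exclude: str | None = None) -> CoefficientSet:
        rows = points(ptype, exclude)
        if run.population_design == "subject_intercepts":
            return fit_population_fixed_effects(rows, ptype)
        return fit_population_coefficients(
            [(w, ref, bp) for w, ref, bp, _ in rows], ptype
        )

    population: dict[str, dict[str, CoefficientSet]] = {}
    if run.population_fit_scope == "pooled":
        pooled = {pt: fit(pt) for pt in ("SBP", "DBP")}
        for sub in usable:
            population[sub.subject_id] = pooled
    else:
        for sub in usable:
            population[sub.subject_id] = {
                pt: fit(pt, exclude=sub.subject_id) for pt in ("SBP", "DBP")
            }

    profiles: dict[str, dict[str, CalibrationProfile]] = {m: {} for m in MODELS}
    for sub in usable:
        sid = sub.subject_id
        try:
            per_model: dict[str, dict[str, CoefficientSet]] = {}
            for model in MODELS:
                per_model[model] = {}
                for pt in ("SBP", "DBP"):
                    pop = population[sid][pt]
                    if model == "linear":
                        pop = CoefficientSet(a=pop.a, b=pop.b, c=0.0, d=0.0,
                                             pressure_type=pt)
                    idx = 0 if pt == "SBP" else 1
                    per_model[model][pt] = calibrate_subject(
                        (sums[sid]["calibration_sitting"],
                         sub.resolved["calibration_sitting"][idx]),
                        (sums[sid]["calibration_standing"],
                         sub.resolved["calibration_standing"][idx]),
                        pop,
                        refs[sid],
                    )
        except DegenerateCalibrationError as exc:
            excluded[sid] = str(exc)
            log.info("excluding %s: %s", sid, exc)
            continue
        for model in MODELS:
            profiles[model][sid] = CalibrationProfile(
                subject_id=sid,
                sbp_coeffs=per_model[model]["SBP"],
                dbp_coeffs=per_model[model]["DBP"],
                reference=refs[sid],
            )
    return CalibrationResult(profiles=profiles,
                             population=population, excluded=excluded)
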
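"""Measurement-acceptance rules and cohort session bookkeeping.

Each protocol session takes two cuff readings (a third after a rest when the
first two disagree moderately).  The acceptance rule, applied to the absolute
difference between the first two readings of each pressure type:

* difference < 5 mmHg        -> the first reading stands;
* 5 mmHg <= difference <= 10 -> a third reading is required and the mean of
  the three is used;
* difference > 10 mmHg       -> the session's reference BP is discarded
  (blood pressure was not stable enough to trust).

SBP and DBP are resolved independently; a session is discarded if either
pressure type is discarded.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .waveform_io import ReferenceBPMeasurement, SessionDataset

__all__ = [
    "MeasurementResolution",
    "CohortSummary",
    "resolve_reference_bp",
    "resolve_pressure_values",
    "validate_experiment",
]

LOW_DIFF_MMHG = 5.0
HIGH_DIFF_MMHG = 10.0


@dataclass(frozen=True)
class MeasurementResolution:
    """Outcome of the duplicate-measurement acceptance rule for one session."""

    status: str  # accepted_first | accepted_mean_of_three | discarded | pending_third
    resolved_sbp: float | None
    resolved_dbp: float | None
    reason: str
    sbp_status: str = ""
    dbp_status: str = ""

    def __post_init__(self) -> None:
        accepted = self.status.startswith("accepted")
        has_values = self.resolved_sbp is not None and self.resolved_dbp is not None
        if accepted != has_values:
            raise ValueError("resolved values must be present iff status is accepted")


def resolve_pressure_values(values: list[float]) -> tuple[str, float | None]:
    """Apply the acceptance rule to one pressure type's ordered readings.

    Returns ``(status, resolved_value_or_None)``.  The rule is positional:
    only the first two readings are compared, and "first" means first in
    session order.
    """
    if not 2 <= len(values) <= 3:
        raise ValueError(f"expected 2 or 3 measurements, got {len(values)}")
    diff = abs(values[0] - values[1])
    if diff < LOW_DIFF_MMHG:
        return "accepted_first", values[0]
    if diff > HIGH_DIFF_MMHG:
        return "discarded", None
    if len(values) == 2:
        return "pending_third", None
    return "accepted_mean_of_three", sum(values) / 3.0


def resolve_reference_bp(
    measurements: list[ReferenceBPMeasurement],
) -> MeasurementResolution:
    """Resolve a session's reference BP from its ordered cuff readings.

    The rule runs independently on SBP and DBP.  The combined status is the
    most demanding of the two: either discarded -> discarded; else either
    pending -> pending_third; else accepted (mean-of-three if either type
    needed the third reading).
    """
    ordered = sorted(measurements, key=lambda m: m.order_index)
    sbp_status, sbp_value = resolve_pressure_values([m.sbp for m in ordered])
    dbp_status, dbp_value = resolve_pressure_values([m.dbp for m in ordered])

    if "discarded" in (sbp_status, dbp_status):
        return MeasurementResolution(
            "discarded", None, None,
            "first two readings differ by more than 10 mmHg",
            sbp_status, dbp_status,
        )
    if "pending_third" in (sbp_status, dbp_status):
        return MeasurementResolution(
            "pending_third", None, None,
            "difference in [5, 10] mmHg; third reading required",
            sbp_status, dbp_status,
        )
    status = (
        "accepted_first"
        if sbp_status == dbp_status == "accepted_first"
        else "accepted_mean_of_three"
    )
    return MeasurementResolution(
        status, sbp_value, dbp_value, "accepted", sbp_status, dbp_status
    )


@dataclass
class CohortSummary:
    """Who survives the protocol: analyzable subjects and session counts."""

    n_subjects: int = 0
    n_analyzable_subjects: int = 0
    n_sessions: int = 0
    n_valid_sessions: int = 0
    exclusions: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_analyzable_subjects": self.n_analyzable_subjects,
            "n_sessions": self.n_sessions,
            "n_valid_sessions": self.n_valid_sessions,
            "exclusions": self.exclusions,
        }


def validate_experiment(
    sessions: list[SessionDataset],
    fluctuation_valid: dict[tuple[str, str], bool] | None = None,
) -> CohortSummary:
    """Summarize cohort validity: a subject is analyzable iff all three of
    their sessions passed both the reference-BP resolution and (when
    supplied) the waveform fluctuation check.

    ``fluctuation_valid`` maps ``(subject_id, session_label)`` to the
    fluctuation verdict; sessions absent from the map count as passing.
    """
    by_subject: dict[str, list[SessionDataset]] = defaultdict(list)
    for s in sessions:
        by_subject[s.subject_id].append(s)

    summary = CohortSummary(n_subjects=len(by_subject), n_sessions=len(sessions))
    for subject_id, subj_sessions in by_subject.items():
        reasons = []
        labels = {s.session_label for s in subj_sessions}
        missing = {"calibration_sitting", "calibration_standing",
                   "estimation_test"} - labels
        if missing:
            reasons.append(f"missing sessions: {sorted(missing)}")
        for s in subj_sessions:
            ok_bp = s.valid
            ok_wave = (
                fluctuation_valid is None
                or fluctuation_valid.get((subject_id, s.session_label), True)
            )
            if ok_bp and ok_wave:
                summary.n_valid_sessions += 1
            else:
                why = [] if ok_bp else ["reference BP not resolved"]
                if not ok_wave:
                    why.append("waveform fluctuation check failed")
                reasons.append(f"{s.session_label}: {'; '.join(why)}")
        if reasons:
            summary.exclusions[subject_id] = reasons
        else:
            summary.n_analyzable_subjects += 1
    return summary
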
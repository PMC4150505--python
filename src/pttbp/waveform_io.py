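"""Waveform session I/O and the record types consumed by every pipeline stage.

A session is one continuous two-channel recording (ECG + PPG, synchronously
sampled) together with the cuff-oscillometer reference measurements taken in
the same session.  Waveforms travel as comma-delimited text with one header
row and columns ``ecg``, ``ppg`` (optional leading ``t`` time column); an
experiment is described by a JSON config keyed by subject then session.

Sample indexing is 0-based; sample ``k`` occurs at time ``k / fs`` seconds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FS",
    "SESSION_LABELS",
    "WaveformRecord",
    "ReferenceBPMeasurement",
    "SessionDataset",
    "WaveformFormatError",
    "ConfigError",
    "read_waveform",
    "write_waveform",
    "load_experiment_config",
    "write_experiment_config",
]

#: Default sampling rate in Hz for both channels.
DEFAULT_FS = 250.0

#: The three data sessions of the protocol, in protocol order.
SESSION_LABELS = ("calibration_sitting", "calibration_standing", "estimation_test")

_SESSION_POSTURE = {
    "calibration_sitting": "sitting",
    "calibration_standing": "standing",
    "estimation_test": "sitting",
}


class WaveformFormatError(ValueError):
    """Malformed waveform file (bad header, ragged columns, non-numeric data)."""


class ConfigError(ValueError):
    """Malformed or inconsistent experiment configuration."""


@dataclass
class WaveformRecord:
    """One session's synchronized ECG and PPG sample arrays.

    Amplitudes are in arbitrary units; only timing carries physical meaning.
    """

    ecg: np.ndarray
    ppg: np.ndarray
    fs: float = DEFAULT_FS
    subject_id: str = ""
    session_label: str = "estimation_test"
    posture: str = "sitting"

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.ecg.ndim != 1 or self.ppg.ndim != 1:
            raise ValueError("ecg and ppg must be 1-D arrays")
        if len(self.ecg) != len(self.ppg):
            raise ValueError(
                f"channel length mismatch: ecg has {len(self.ecg)} samples, "
                f"ppg has {len(self.ppg)}"
            )
        if self.session_label not in SESSION_LABELS:
            raise ValueError(
                f"unknown session_label {self.session_label!r}; "
                f"expected one of {SESSION_LABELS}"
            )
        if self.posture not in ("sitting", "standing"):
            raise ValueError(f"unknown posture {self.posture!r}")
        if len(self.ecg) < 2 * self.fs:
            warnings.warn(
                f"record holds {len(self.ecg) / self.fs:.2f} s of signal; "
                "at least 2 s are expected",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs


@dataclass(frozen=True)
class ReferenceBPMeasurement:
    """A single oscillometric cuff reading (systolic/diastolic, mmHg)."""

    sbp: float
    dbp: float
    order_index: int = 1

    def __post_init__(self) -> None:
        if not (40 <= self.dbp < self.sbp <= 300):
            raise ValueError(
                f"implausible reading sbp={self.sbp}, dbp={self.dbp}: "
                "expected 40 <= dbp < sbp <= 300 mmHg"
            )
        if self.order_index < 1:
            raise ValueError("order_index is 1-based")


@dataclass
class SessionDataset:
    """Waveforms + posture + reference BP for one protocol session.

    ``resolved_sbp``/``resolved_dbp`` are set once the duplicate-measurement
    acceptance rule has been applied; they are present iff ``valid``.
    """

    record: WaveformRecord
    measurements: list[ReferenceBPMeasurement] = field(default_factory=list)
    resolved_sbp: float | None = None
    resolved_dbp: float | None = None
    valid: bool = False

    def __post_init__(self) -> None:
        has_bp = self.resolved_sbp is not None and self.resolved_dbp is not None
        if self.valid != has_bp:
            raise ValueError("resolved BP must be present iff the session is valid")

    @property
    def subject_id(self) -> str:
        return self.record.subject_id

    @property
    def session_label(self) -> str:
        return self.record.session_label


def read_waveform(
    path: str | Path,
    fs: float = DEFAULT_FS,
    subject_id: str = "",
    session_label: str = "estimation_test",
    posture: str | None = None,
) -> WaveformRecord:
    """Read a two-channel waveform CSV into a :class:`WaveformRecord`.

    The file must carry a header row naming ``ecg`` and ``ppg`` columns; a
    leading ``t`` (or ``sample``) column is ignored.  Missing or non-numeric
    samples are rejected.
    """
    try:
        # round_trip float parsing so write -> read reproduces doubles exactly
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise WaveformFormatError(f"cannot parse {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in frame.columns}
    missing = [name for name in ("ecg", "ppg") if name not in cols]
    if missing:
        raise WaveformFormatError(
            f"{path}: header must name 'ecg' and 'ppg' columns; missing {missing}"
        )
    ecg = pd.to_numeric(frame[cols["ecg"]], errors="coerce").to_numpy()
    ppg = pd.to_numeric(frame[cols["ppg"]], errors="coerce").to_numpy()
    if np.isnan(ecg).any() or np.isnan(ppg).any():
        raise WaveformFormatError(f"{path}: missing or non-numeric samples")
    return WaveformRecord(
        ecg=ecg,
        ppg=ppg,
        fs=fs,
        subject_id=subject_id,
        session_label=session_label,
        posture=posture if posture is not None else _SESSION_POSTURE[session_label],
    )


def write_waveform(record: WaveformRecord, path: str | Path) -> None:
    """Write a record as CSV with columns ``t, ecg, ppg``.

    Amplitudes are stored with repr-level precision so that a write/read
    round trip reproduces the arrays exactly; two writes of the same record
    produce byte-identical files.
    """
    t = np.arange(record.n_samples) / record.fs
    frame = pd.DataFrame({"t": t, "ecg": record.ecg, "ppg": record.ppg})
    frame.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def _parse_measurements(raw: list[dict]) -> list[ReferenceBPMeasurement]:
    out = []
    for i, m in enumerate(raw, start=1):
        out.append(
            ReferenceBPMeasurement(
                sbp=float(m["sbp"]),
                dbp=float(m["dbp"]),
                order_index=int(m.get("order_index", i)),
            )
        )
    return out


@dataclass
class SessionDescriptor:
    """One session entry of an experiment config, waveform not yet loaded."""

    subject_id: str
    session_label: str
    posture: str
    waveform_path: Path
    measurements: list[ReferenceBPMeasurement]
    fs: float = DEFAULT_FS
    complete_subject: bool = True

    def load(self) -> WaveformRecord:
        return read_waveform(
            self.waveform_path,
            fs=self.fs,
            subject_id=self.subject_id,
            session_label=self.session_label,
            posture=self.posture,
        )


def load_experiment_config(path: str | Path) -> list[SessionDescriptor]:
    """Load an experiment config into per-session descriptors (config order).

    The config is JSON of the form::

        {"fs": 250,
         "subjects": {
           "S001": {"sessions": {
              "calibration_sitting": {"waveform": "S001_sit.csv",
                                      "measurements": [{"sbp":118,"dbp":76}, ...]},
              ...}}}}

    Waveform paths are resolved relative to the config file.  Subjects
    missing either calibration posture have every descriptor flagged with
    ``complete_subject=False``; unknown session labels and duplicate sessions
    raise :class:`ConfigError`.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh)
    fs = float(cfg.get("fs", DEFAULT_FS))
    base = path.parent
    descriptors: list[SessionDescriptor] = []
    for subject_id, sub in cfg.get("subjects", {}).items():
        sessions = sub.get("sessions", {})
        seen: set[str] = set()
        for label in sessions:
            if label not in SESSION_LABELS:
                raise ConfigError(
                    f"subject {subject_id}: unknown session label {label!r}"
                )
            if label in seen:  # pragma: no cover - dict keys are unique in JSON
                raise ConfigError(f"subject {subject_id}: duplicate session {label}")
            seen.add(label)
        complete = {"calibration_sitting", "calibration_standing"} <= seen
        if not complete:
            warnings.warn(
                f"subject {subject_id} is missing a calibration posture",
                stacklevel=2,
            )
        for label, entry in sessions.items():
            descriptors.append(
                SessionDescriptor(
                    subject_id=subject_id,
                    session_label=label,
                    posture=entry.get("posture", _SESSION_POSTURE[label]),
                    waveform_path=base / entry["waveform"],
                    measurements=_parse_measurements(entry.get("measurements", [])),
                    fs=fs,
                    complete_subject=complete,
                )
            )
    return descriptors


def write_experiment_config(
    path: str | Path,
    fs: float,
    subjects: dict[str, dict[str, dict]],
) -> None:
    """Write the experiment config JSON read back by :func:`load_experiment_config`.

    ``subjects`` maps subject id -> session label -> ``{"waveform": ...,
    "measurements": [...]}`` with waveform paths relative to the config file.
    """
    cfg = {
        "fs": fs,
        "subjects": {
            sid: {"sessions": sessions} for sid, sessions in subjects.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)
        fh.write("\n")
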
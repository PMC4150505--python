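"""Seed-controlled synthetic ECG/PPG/BP cohorts with known ground truth.

No public dataset accompanies the estimation method, so every stage of the
pipeline is validated against simulated subjects whose PTT→BP law is known
exactly.  Each subject carries:

* a baseline PTT with a postural shift (standing shortens PTT — hydrostatic
  unloading of the arm raises effective wall stiffness);
* low-frequency PTT oscillation in the Mayer-wave band (default 10 s period)
  plus white beat-to-beat jitter, giving PTTV a physiologic dynamic range;
* an affine-plus-compensation pressure law per pressure type — the same
  functional form the estimator assumes — from which per-beat "true" SBP/DBP
  are computed using the *same* rolling-window feature conventions as the
  estimator;
* cuff "oscillometer" readings: the session-level true BP plus measurement
  noise, duplicated per the protocol (third reading drawn when the first two
  disagree by 5–10 mmHg).

Waveforms are rendered with deliberately simple morphologies — Gaussian
R-wave bumps and raised-cosine PPG pulses — whose maxima are unambiguous and
quantized to the sample grid, so detection accuracy can be scored against
truth to within one sample.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beat_detection import PTTSeries
from .ptt_features import (
    DEFAULT_WINDOW,
    CalibrationReference,
    rolling_features,
    session_reference,
    session_summary,
)
from .protocol import resolve_reference_bp, resolve_pressure_values
from .waveform_io import (
    ReferenceBPMeasurement,
    SessionDataset,
    WaveformRecord,
    write_experiment_config,
    write_waveform,
)

__all__ = [
    "PressureLaw",
    "SubjectLaw",
    "TruthTable",
    "CohortConfig",
    "Cohort",
    "generate_subject_law",
    "generate_beat_sequence",
    "render_waveforms",
    "generate_cohort",
]


@dataclass(frozen=True)
class PressureLaw:
    """True (a, b, c, d) generating one pressure type. Units as the model."""

    a: float
    b: float
    c: float
    d: float

    def apply(self, mean_ptt: float, vptt: float, pttv: float, pttv0: float) -> float:
        return self.a * mean_ptt + self.b + self.c * vptt + self.d * (pttv - pttv0)


@dataclass(frozen=True)
class SubjectLaw:
    """Everything that determines one synthetic subject's physiology."""

    subject_id: str
    sbp_law: PressureLaw
    dbp_law: PressureLaw
    baseline_ptt_ms: float
    posture_ptt_shift_ms: float = -15.0  # standing minus sitting
    test_ptt_shift_ms: float = 0.0  # slow drift between calibration and test
    lf_variability_amp_ms: float = 5.0
    lf_period_s: float = 10.0
    standing_var_gain: float = 1.6  # orthostatic sympathetic activation
    test_var_gain: float = 1.0
    heart_rate_bpm: float = 70.0
    rr_jitter_ms: float = 25.0
    ptt_jitter_ms: float = 2.5
    bp_noise_sd_mmHg: float = 0.0  # per-beat BP noise around the law
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_ptt_ms <= 0:
            raise ValueError("baseline_ptt_ms must be positive")
        if not 40 <= self.heart_rate_bpm <= 180:
            raise ValueError("heart_rate_bpm must lie in [40, 180]")
        if self.lf_variability_amp_ms < 0 or self.ptt_jitter_ms < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class TruthTable:
    """Per-beat ground truth for one session, plus session-level summaries."""

    subject_id: str
    session_label: str
    posture: str
    r_time_s: np.ndarray
    true_ptt_ms: np.ndarray
    true_sbp_mmHg: np.ndarray
    true_dbp_mmHg: np.ndarray
    session_sbp_mmHg: float = float("nan")
    session_dbp_mmHg: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.r_time_s) > 1 and not np.all(np.diff(self.r_time_s) > 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.true_ptt_ms <= 0):
            raise ValueError("true PTT must be positive")

    @property
    def n_beats(self) -> int:
        return len(self.r_time_s)

    def to_series(self) -> PTTSeries:
        """The true PTT stream as a PTTSeries (feature-level pipeline entry)."""
        return PTTSeries(self.true_ptt_ms.copy(), self.r_time_s.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_time_s": self.r_time_s,
                "true_ptt_ms": self.true_ptt_ms,
                "true_sbp_mmHg": self.true_sbp_mmHg,
                "true_dbp_mmHg": self.true_dbp_mmHg,
                "posture": self.posture,
            }
        )


@dataclass(frozen=True)
class CohortConfig:
    """Population-level generator settings (per-subject draws come from these).

    Defaults emulate the study conditions: 250 Hz sampling, 3-minute
    recordings, young healthy subjects (resting HR ~70 bpm, fingertip PTT
    ~210 ms), a −15 ms standing PTT shift, Mayer-wave PTT oscillation, and a
    2 mmHg-SD oscillometer.  Setting every *_sd and jitter to zero yields a
    noise-free cohort.
    """

    fs: float = 250.0
    duration_s: float = 180.0
    W: int = DEFAULT_WINDOW
    heart_rate_mean_bpm: float = 70.0
    heart_rate_sd_bpm: float = 7.0
    baseline_ptt_mean_ms: float = 210.0
    baseline_ptt_sd_ms: float = 20.0
    posture_shift_mean_ms: float = -15.0
    posture_shift_sd_ms: float = 3.0
    test_shift_sd_ms: float = 6.0
    lf_amp_ms: float = 5.0
    lf_amp_rel_sd: float = 0.2
    lf_period_s: float = 10.0
    standing_var_gain: float = 1.6
    test_var_gain_range: tuple[float, float] = (0.5, 2.0)
    rr_jitter_ms: float = 25.0
    ptt_jitter_ms: float = 2.5
    bp_noise_sd_mmHg: float = 0.0
    oscillometer_noise_sd_mmHg: float = 2.0
    # population pressure laws; *_sd spread a and b across subjects
    sbp_law: PressureLaw = PressureLaw(a=-0.45, b=0.0, c=-8.0, d=0.2)
    dbp_law: PressureLaw = PressureLaw(a=-0.20, b=0.0, c=-20.0, d=2.5)
    sbp_target_mean_mmHg: float = 115.0
    sbp_target_sd_mmHg: float = 8.0
    dbp_target_mean_mmHg: float = 72.0
    dbp_target_sd_mmHg: float = 6.0
    a_rel_sd: float = 0.1
    #: with shared_law every subject uses the population (a, b, c, d) verbatim
    #: — the condition under which the pooled regression has a unique truth.
    shared_law: bool = False
    #: 0-based subject indices given a pathologically unstable PTT stream
    #: (CV > the fluctuation threshold) so downstream rejection can be tested.
    unstable_subjects: tuple[int, ...] = ()

    def noise_free(self) -> "CohortConfig":
        """A copy with every stochastic dial silenced (for inverse tests)."""
        return dataclasses.replace(
            self,
            heart_rate_sd_bpm=0.0,
            baseline_ptt_sd_ms=0.0,
            posture_shift_sd_ms=0.0,
            test_shift_sd_ms=0.0,
            lf_amp_rel_sd=0.0,
            rr_jitter_ms=0.0,
            ptt_jitter_ms=0.0,
            bp_noise_sd_mmHg=0.0,
            oscillometer_noise_sd_mmHg=0.0,
            sbp_target_sd_mmHg=0.0,
            dbp_target_sd_mmHg=0.0,
            a_rel_sd=0.0,
        )

    def homogeneous(self) -> "CohortConfig":
        """A copy where every subject shares the same pressure law (a, b, c, d),
        leaving physiologic variation intact — the condition under which the
        pooled population fit has a single recoverable truth."""
        return dataclasses.replace(
            self,
            sbp_target_sd_mmHg=0.0,
            dbp_target_sd_mmHg=0.0,
            a_rel_sd=0.0,
            shared_law=True,
        )


SESSION_ORDER = ("calibration_sitting", "calibration_standing", "estimation_test")


def generate_subject_law(
    subject_id: str,
    config: CohortConfig,
    rng: np.random.Generator,
    unstable: bool = False,
) -> SubjectLaw:
    """Draw one subject's physiologic parameters and pressure laws.

    ``unstable`` marks a subject whose beat-to-beat PTT jitter is made large
    enough to trip the fluctuation validity check downstream.
    """
    baseline = max(
        120.0, rng.normal(config.baseline_ptt_mean_ms, config.baseline_ptt_sd_ms)
    )
    hr = float(
        np.clip(rng.normal(config.heart_rate_mean_bpm, config.heart_rate_sd_bpm),
                45.0, 120.0)
    )

    def _law(pop: PressureLaw, target_mean: float, target_sd: float) -> PressureLaw:
        if config.shared_law:
            return pop if pop.b != 0.0 else dataclasses.replace(
                pop, b=target_mean - pop.a * config.baseline_ptt_mean_ms
            )
        a = pop.a * (1.0 + config.a_rel_sd * rng.standard_normal())
        # sitting BP tracks baseline PTT across subjects (stiffer vessels:
        # shorter transit, higher pressure), plus an idiosyncratic residual
        target = (
            target_mean
            + pop.a * (baseline - config.baseline_ptt_mean_ms)
            + rng.normal(0.0, target_sd)
        )
        b = target - a * baseline
        return PressureLaw(a=a, b=b, c=pop.c, d=pop.d)

    return SubjectLaw(
        subject_id=subject_id,
        sbp_law=_law(config.sbp_law, config.sbp_target_mean_mmHg,
                     config.sbp_target_sd_mmHg),
        dbp_law=_law(config.dbp_law, config.dbp_target_mean_mmHg,
                     config.dbp_target_sd_mmHg),
        baseline_ptt_ms=baseline,
        posture_ptt_shift_ms=rng.normal(config.posture_shift_mean_ms,
                                        config.posture_shift_sd_ms),
        test_ptt_shift_ms=rng.normal(0.0, config.test_shift_sd_ms),
        lf_variability_amp_ms=config.lf_amp_ms
        * max(0.0, 1.0 + config.lf_amp_rel_sd * rng.standard_normal()),
        lf_period_s=config.lf_period_s,
        standing_var_gain=config.standing_var_gain,
        test_var_gain=float(rng.uniform(*config.test_var_gain_range)),
        heart_rate_bpm=hr,
        rr_jitter_ms=config.rr_jitter_ms,
        ptt_jitter_ms=60.0 if unstable else config.ptt_jitter_ms,
        bp_noise_sd_mmHg=config.bp_noise_sd_mmHg,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_beat_sequence(
    law: SubjectLaw,
    posture: str = "sitting",
    duration_s: float = 180.0,
    seed: int | None = None,
    session_label: str = "calibration_sitting",
    reference: CalibrationReference | None = None,
    W: int = DEFAULT_WINDOW,
) -> TruthTable:
    """Generate one session's per-beat truth (times, PTT, SBP, DBP).

    Beat times follow the subject's heart rate with white R-R jitter; PTT is
    baseline + posture shift (+ test drift) + a low-frequency sinusoid with
    seeded random phase + white jitter.  Per-beat BP follows the subject's
    own pressure laws evaluated on the rolling features of the true PTT
    stream (the same window conventions the estimator uses), relative to
    ``reference`` — the subject's sitting calibration state; when omitted it
    is derived from this session's own stream.  Identical seeds give
    identical tables.
    """
    if duration_s < 30:
        raise ValueError("duration_s must be at least 30 s")
    rng = np.random.default_rng(law.seed if seed is None else seed)

    rr_s = 60.0 / law.heart_rate_bpm
    n_beats = int(np.floor((duration_s - 1.0) / rr_s))
    intervals = rr_s + rng.normal(0.0, law.rr_jitter_ms / 1000.0, size=n_beats - 1)
    intervals = np.clip(intervals, 0.4 * rr_s, 1.8 * rr_s)
    r_times = 0.5 + np.concatenate(([0.0], np.cumsum(intervals)))

    shift = 0.0
    var_gain = 1.0
    if posture == "standing":
        shift += law.posture_ptt_shift_ms
        var_gain = law.standing_var_gain
    if session_label == "estimation_test":
        shift += law.test_ptt_shift_ms
        var_gain = law.test_var_gain
    # var_gain scales both variability sources: the slow Mayer-band
    # oscillation (drives VPTT excursions) and the white beat-to-beat
    # jitter, which is what PTTV — the SD of successive differences over a
    # 5-beat window — actually responds to (a 10-s sinusoid is locally a
    # linear ramp at that window length and leaves PTTV nearly untouched).
    phase = rng.uniform(0.0, 2.0 * np.pi)
    ptt = (
        law.baseline_ptt_ms
        + shift
        + var_gain * law.lf_variability_amp_ms
        * np.sin(2.0 * np.pi * r_times / law.lf_period_s + phase)
        + rng.normal(0.0, var_gain * law.ptt_jitter_ms, size=n_beats)
    )
    # physiologic clamp (only binds for pathological jitter settings)
    ptt = np.clip(ptt, 60.0, 550.0)
    series = PTTSeries(ptt, r_times)

    if reference is None:
        reference = session_reference(series, W)
    windows = rolling_features(series, reference, W)

    sbp = np.empty(n_beats)
    dbp = np.empty(n_beats)
    for k, w in enumerate(windows):
        i = W - 1 + k
        sbp[i] = law.sbp_law.apply(w.mean_ptt_ms, w.vptt, w.pttv_ms,
                                   reference.pttv0_ms)
        dbp[i] = law.dbp_law.apply(w.mean_ptt_ms, w.vptt, w.pttv_ms,
                                   reference.pttv0_ms)
    sbp[: W - 1] = sbp[W - 1]  # beats before the first complete window
    dbp[: W - 1] = dbp[W - 1]
    if law.bp_noise_sd_mmHg > 0:
        sbp = sbp + rng.normal(0.0, law.bp_noise_sd_mmHg, size=n_beats)
        dbp = dbp + rng.normal(0.0, law.bp_noise_sd_mmHg, size=n_beats)

    summary = session_summary(series, reference, W)
    return TruthTable(
        subject_id=law.subject_id,
        session_label=session_label,
        posture=posture,
        r_time_s=r_times,
        true_ptt_ms=ptt,
        true_sbp_mmHg=sbp,
        true_dbp_mmHg=dbp,
        session_sbp_mmHg=law.sbp_law.apply(
            summary.mean_ptt_ms, summary.vptt, summary.pttv_ms, reference.pttv0_ms
        ),
        session_dbp_mmHg=law.dbp_law.apply(
            summary.mean_ptt_ms, summary.vptt, summary.pttv_ms, reference.pttv0_ms
        ),
    )


ECG_BUMP_SD_S = 0.010
PPG_PULSE_WIDTH_S = 0.300


def render_waveforms(
    truth: TruthTable,
    fs: float = 250.0,
    snr_db: float | None = None,
    seed: int = 0,
) -> WaveformRecord:
    """Render a truth table into sampled ECG and PPG channels.

    ECG: unit-amplitude Gaussian bumps (SD 10 ms) at each beat time.  PPG:
    raised-cosine pulses (width 300 ms) whose maxima sit exactly at
    ``round(r_time·fs) + round(PTT·fs/1000)`` samples — peak positions are
    quantized to the sample grid.  With ``snr_db`` set, white Gaussian noise
    is added to each channel at that power ratio relative to the channel's
    RMS.  A PTT reaching past the next beat's R-wave is a generation error.
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    r_idx = np.round(truth.r_time_s * fs).astype(int)
    p_idx = r_idx + np.round(truth.true_ptt_ms * fs / 1000.0).astype(int)
    if np.any(p_idx[:-1] >= r_idx[1:]):
        bad = int(np.argmax(p_idx[:-1] >= r_idx[1:]))
        raise ValueError(
            f"beat {bad}: PTT {truth.true_ptt_ms[bad]:.0f} ms exceeds the beat "
            "interval; PPG peak would leave its cardiac cycle"
        )
    n = int(p_idx[-1] + fs)  # 1 s tail
    t = np.arange(n) / fs

    ecg = np.zeros(n)
    half_e = int(np.ceil(4 * ECG_BUMP_SD_S * fs))
    for ri in r_idx:
        lo, hi = max(0, ri - half_e), min(n, ri + half_e + 1)
        ecg[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - ri / fs) / ECG_BUMP_SD_S) ** 2)

    ppg = np.zeros(n)
    half_p = int(np.floor(PPG_PULSE_WIDTH_S / 2 * fs))
    for pi in p_idx:
        lo, hi = max(0, pi - half_p), min(n, pi + half_p + 1)
        ppg[lo:hi] += 0.5 * (
            1.0 + np.cos(2.0 * np.pi * (t[lo:hi] - pi / fs) / PPG_PULSE_WIDTH_S)
        )

    if snr_db is not None:
        rng = np.random.default_rng(seed)
        for chan in (ecg, ppg):
            rms = np.sqrt(np.mean(chan**2))
            chan += rng.normal(0.0, rms * 10.0 ** (-snr_db / 20.0), size=n)

    return WaveformRecord(
        ecg=ecg,
        ppg=ppg,
        fs=fs,
        subject_id=truth.subject_id,
        session_label=truth.session_label,
        posture=truth.posture,
    )


@dataclass
class Cohort:
    """A generated cohort: subject laws, per-session truth, session datasets."""

    config: CohortConfig
    subjects: list[SubjectLaw]
    truth: dict[tuple[str, str], TruthTable]
    sessions: list[SessionDataset]
    references: dict[str, CalibrationReference] = field(default_factory=dict)
    config_path: Path | None = None

    def subject_truth(self, subject_id: str, session_label: str) -> TruthTable:
        return self.truth[(subject_id, session_label)]


def _draw_measurements(
    sbp_true: float, dbp_true: float, noise_sd: float, rng: np.random.Generator
) -> list[ReferenceBPMeasurement]:
    """Oscillometer readings per the duplicate-measurement protocol."""
    def reading(k: int) -> ReferenceBPMeasurement:
        # clamp into the device's reportable range; only binds for subjects
        # whose programmed physiology is pathological (rejected downstream)
        sbp = float(np.clip(sbp_true + rng.normal(0.0, noise_sd), 70.0, 300.0))
        dbp = float(np.clip(dbp_true + rng.normal(0.0, noise_sd),
                            40.0, sbp - 5.0))
        return ReferenceBPMeasurement(sbp=round(sbp, 1), dbp=round(dbp, 1),
                                      order_index=k)

    readings = [reading(1), reading(2)]
    needs_third = any(
        resolve_pressure_values(vals)[0] == "pending_third"
        for vals in ([m.sbp for m in readings], [m.dbp for m in readings])
    )
    if needs_third:
        readings.append(reading(3))
    return readings


def generate_cohort(
    n_subjects: int,
    config: CohortConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    render: bool = True,
    snr_db: float | None = None,
) -> Cohort:
    """Generate a full cohort: three sessions per subject with ground truth.

    With ``out_dir`` set, writes one waveform CSV per session, per-session
    truth CSVs, and the experiment config JSON that
    :func:`~pttbp.waveform_io.load_experiment_config` reads back.  With
    ``render=False`` only the truth tables (feature-level cohort) are built,
    which is much faster when waveform detection is not under test.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n_subjects)

    subjects: list[SubjectLaw] = []
    truth: dict[tuple[str, str], TruthTable] = {}
    sessions: list[SessionDataset] = []
    references: dict[str, CalibrationReference] = {}
    config_entries: dict[str, dict[str, dict]] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for i, sseq in enumerate(subject_seeds):
        rng = np.random.default_rng(sseq)
        subject_id = f"S{i + 1:03d}"
        law = generate_subject_law(
            subject_id, config, rng, unstable=i in config.unstable_subjects
        )
        subjects.append(law)

        session_tables: dict[str, TruthTable] = {}
        reference: CalibrationReference | None = None
        for label in SESSION_ORDER:
            posture = "standing" if label == "calibration_standing" else "sitting"
            table = generate_beat_sequence(
                law,
                posture=posture,
                duration_s=config.duration_s,
                seed=int(rng.integers(0, 2**31 - 1)),
                session_label=label,
                reference=reference,
                W=config.W,
            )
            if label == "calibration_sitting":
                reference = session_reference(table.to_series(), config.W)
                references[subject_id] = reference
            session_tables[label] = table
            truth[(subject_id, label)] = table

        entries: dict[str, dict] = {}
        for label, table in session_tables.items():
            measurements = _draw_measurements(
                table.session_sbp_mmHg,
                table.session_dbp_mmHg,
                config.oscillometer_noise_sd_mmHg,
                rng,
            )
            resolution = resolve_reference_bp(measurements)
            if render:
                record = render_waveforms(
                    table, config.fs, snr_db=snr_db,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            else:
                record = _stub_record(table, config.fs)
            sessions.append(
                SessionDataset(
                    record=record,
                    measurements=measurements,
                    resolved_sbp=resolution.resolved_sbp,
                    resolved_dbp=resolution.resolved_dbp,
                    valid=resolution.status.startswith("accepted"),
                )
            )
            if out_path is not None and render:
                wave_name = f"{subject_id}_{label}.csv"
                write_waveform(record, out_path / wave_name)
                table.to_frame().to_csv(
                    out_path / f"{subject_id}_{label}_truth.csv", index=False
                )
                entries[label] = {
                    "waveform": wave_name,
                    "posture": table.posture,
                    "measurements": [
                        {"sbp": m.sbp, "dbp": m.dbp, "order_index": m.order_index}
                        for m in measurements
                    ],
                }
        if entries:
            config_entries[subject_id] = entries

    cohort = Cohort(config, subjects, truth, sessions, references)
    if out_path is not None and render:
        cohort.config_path = out_path / "experiment.json"
        write_experiment_config(cohort.config_path, config.fs, config_entries)
    return cohort


def _stub_record(table: TruthTable, fs: float) -> WaveformRecord:
    """Placeholder record for feature-level cohorts (no waveform rendering)."""
    n = max(int(2 * fs) + 1, 2)
    return WaveformRecord(
        ecg=np.zeros(n),
        ppg=np.zeros(n),
        fs=fs,
        subject_id=table.subject_id,
        session_label=table.session_label,
        posture=table.posture,
    )
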
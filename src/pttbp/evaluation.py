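"""Agreement statistics between estimated and reference blood pressure.

The estimator is scored the way cuffless-BP studies conventionally score
themselves: Bland–Altman analysis of the paired differences (mean error,
SD, limits of agreement at mean ± 1.96 SD), the squared Pearson correlation
R², and a least-squares regression line of estimate on reference.  Pairing
is at session level — the mean of the per-beat estimates against the single
resolved cuff reading of that session — because the oscillometer yields one
reference value per session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .bp_model import CalibrationProfile, estimate_session
from .waveform_io import SessionDataset

__all__ = [
    "AgreementReport",
    "bland_altman",
    "correlation_r2",
    "evaluate_cohort",
    "UndefinedCorrelationError",
]


class UndefinedCorrelationError(ValueError):
    """Correlation requested on a degenerate (zero-variance or tiny) sample."""


@dataclass
class AgreementReport:
    """Bland–Altman + correlation summary for one (model, pressure type)."""

    n: int
    mean_error_mmHg: float
    sd_error_mmHg: float
    loa_low_mmHg: float
    loa_high_mmHg: float
    r2: float | None = None
    regression_slope: float | None = None
    regression_intercept: float | None = None
    pressure_type: str = ""
    model: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def bland_altman(estimates, references) -> AgreementReport:
    """Bland–Altman agreement: differences are estimate − reference (mmHg).

    SD uses the sample (n−1) denominator; limits of agreement are
    mean ± 1.96·SD.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {ref.shape}")
    if est.size < 2:
        raise ValueError("need at least 2 paired points")
    diffs = est - ref
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return AgreementReport(
        n=est.size,
        mean_error_mmHg=mean,
        sd_error_mmHg=sd,
        loa_low_mmHg=mean - 1.96 * sd,
        loa_high_mmHg=mean + 1.96 * sd,
    )


def correlation_r2(x, y) -> float:
    """Squared Pearson correlation between two sequences (sign-blind)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the sequences")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def _regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def evaluate_cohort(
    profiles: dict[str, dict[str, CalibrationProfile]],
    sessions: list[SessionDataset],
    models: tuple[str, ...] = ("compensated", "linear"),
    out_dir: str | Path | None = None,
    W: int = 5,
    pttv_window: int | None = None,
    filter_window_ms: float = 10.0,
) -> dict[tuple[str, str], AgreementReport]:
    """Score estimation-test sessions for each model and pressure type.

    ``profiles[model][subject_id]`` holds each subject's calibrated profile
    for that model.  Each valid estimation-test session contributes one
    paired point: the mean of its per-beat estimates against its resolved
    reference BP.  Returns reports keyed by ``(model, pressure_type)``;
    with ``out_dir`` set, also writes Bland–Altman and scatter plots plus a
    JSON report.  Cohorts with a single session get a report with ``n=1``
    and the correlation left undefined (None).
    """
    test_sessions = [
        s for s in sessions if s.session_label == "estimation_test" and s.valid
    ]
    if not test_sessions:
        raise ValueError("no valid estimation-test sessions to evaluate")

    reports: dict[tuple[str, str], AgreementReport] = {}
    for model in models:
        pairs: dict[str, list[tuple[float, float]]] = {"SBP": [], "DBP": []}
        for session in test_sessions:
            profile = profiles.get(model, {}).get(session.subject_id)
            if profile is None:
                continue
            estimates = estimate_session(
                session, profile, model=model, W=W, pttv_window=pttv_window,
                filter_window_ms=filter_window_ms,
            )
            if not estimates:
                continue
            pairs["SBP"].append(
                (float(np.mean([e.sbp_mmHg for e in estimates])),
                 session.resolved_sbp)
            )
            pairs["DBP"].append(
                (float(np.mean([e.dbp_mmHg for e in estimates])),
                 session.resolved_dbp)
            )
        for ptype, pts in pairs.items():
            if not pts:
                continue
            est = np.array([p[0] for p in pts])
            ref = np.array([p[1] for p in pts])
            if est.size == 1:
                report = AgreementReport(
                    n=1, mean_error_mmHg=float(est[0] - ref[0]),
                    sd_error_mmHg=float("nan"), loa_low_mmHg=float("nan"),
                    loa_high_mmHg=float("nan"),
                )
            else:
                report = bland_altman(est, ref)
            try:
                report.r2 = correlation_r2(ref, est)
                report.regression_slope, report.regression_intercept = _regression(
                    ref, est
                )
            except UndefinedCorrelationError:
                report.r2 = None
            report.pressure_type = ptype
            report.model = model
            reports[(model, ptype)] = report
            if out_dir is not None:
                _write_plots(Path(out_dir), est, ref, report)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "agreement_report.json", "w") as fh:
            json.dump(
                {f"{m}_{p}": r.to_dict() for (m, p), r in reports.items()},
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
    return reports


def _write_plots(
    out: Path, est: np.ndarray, ref: np.ndarray, report: AgreementReport
) -> None:
    """Bland–Altman and scatter plots (side artifacts; numbers live in the
    report object)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out.mkdir(parents=True, exist_ok=True)
    tag = f"{report.model}_{report.pressure_type}"

    fig, ax = plt.subplots(figsize=(5, 4))
    mean_pair = (est + ref) / 2.0
    ax.scatter(mean_pair, est - ref, s=18)
    for y, style in ((report.mean_error_mmHg, "-"),
                     (report.loa_low_mmHg, "--"), (report.loa_high_mmHg, "--")):
        if np.isfinite(y):
            ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
    ax.set_xlabel("mean of estimate and reference (mmHg)")
    ax.set_ylabel("estimate − reference (mmHg)")
    ax.set_title(f"Bland–Altman, {tag}")
    fig.tight_layout()
    fig.savefig(out / f"bland_altman_{tag}.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(ref, est, s=18)
    lims = [min(ref.min(), est.min()) - 2, max(ref.max(), est.max()) + 2]
    ax.plot(lims, lims, "k--", linewidth=0.8)
    ax.set_xlabel("reference BP (mmHg)")
    ax.set_ylabel("estimated BP (mmHg)")
    r2txt = f"$R^2$ = {report.r2:.3f}" if report.r2 is not None else ""
    ax.set_title(f"{tag} {r2txt}")
    fig.tight_layout()
    fig.savefig(out / f"scatter_{tag}.png", dpi=120)
    plt.close(fig)
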
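"""Generate a small synthetic cohort and inspect its ground truth.

Each subject gets three sessions (calibration sitting, calibration standing,
estimation test) with rendered ECG/PPG waveforms, cuff readings drawn per
the duplicate-measurement protocol, and a per-beat truth table.
"""

import dataclasses
import tempfile
from pathlib import Path

from pttbp import CohortConfig, generate_cohort

out = Path(tempfile.mkdtemp(prefix="pttbp_cohort_"))
config = dataclasses.replace(CohortConfig(), duration_s=60.0)
cohort = generate_cohort(n_subjects=3, config=config, seed=42, out_dir=out)

print(f"wrote {len(cohort.sessions)} sessions under {out}\n")
for law in cohort.subjects:
    truth = cohort.truth[(law.subject_id, "calibration_sitting")]
    print(
        f"{law.subject_id}: baseline PTT {law.baseline_ptt_ms:6.1f} ms, "
        f"standing shift {law.posture_ptt_shift_ms:+5.1f} ms, "
        f"HR {law.heart_rate_bpm:5.1f} bpm, "
        f"sitting SBP/DBP {truth.session_sbp_mmHg:5.1f}/"
        f"{truth.session_dbp_mmHg:5.1f} mmHg"
    )

truth = cohort.truth[("S001", "estimation_test")]
print(f"\nS001 estimation-test truth (first 5 of {truth.n_beats} beats):")
print(truth.to_frame().head().to_string(index=False))
print(
    "\nEach row is one cardiac cycle: the R-peak time, the programmed pulse "
    "transit time,\nand the blood pressure generated from the subject's own "
    "PTT→BP law."
)
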
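"""Estimation model, population regression and two-posture calibration."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pttbp.bp_model import (
    CalibrationProfile,
    CoefficientSet,
    DegenerateCalibrationError,
    RankDeficiencyError,
    calibrate_subject,
    estimate_bp,
    estimate_bp_linear,
    estimate_session,
    fit_population_coefficients,
    fit_population_fixed_effects,
)
from pttbp.config import RunConfig
from pttbp.pipeline import collect_truth_data, fit_and_calibrate
from pttbp.ptt_features import CalibrationReference, FeatureWindow
from pttbp.synthetic import CohortConfig, PressureLaw, generate_cohort


def window(mean_ptt, vptt=0.0, pttv=0.0, t=0.0):
    return FeatureWindow(
        beat_time_s=t, ptt_window_ms=(), mean_ptt_ms=mean_ptt,
        pttv_ms=pttv, vptt=vptt,
    )


REF = CalibrationReference(ptt0_ms=200.0, pttv0_ms=1.0)


class TestEstimateBP:
    def test_pure_linear_coefficients(self):
        coeffs = CoefficientSet(a=-0.5, b=220.0)
        assert estimate_bp(window(200.0), coeffs, REF) == pytest.approx(120.0)

    def test_full_compensation_arithmetic(self):
        # a·210 + b = 115; c·0.05 = −2; d·(1−1) = 0
        coeffs = CoefficientSet(a=-0.5, b=220.0, c=-40.0, d=2.0)
        w = window(210.0, vptt=0.05, pttv=1.0)
        assert estimate_bp(w, coeffs, REF) == pytest.approx(113.0)

    @pytest.mark.parametrize(
        "a,b,mean_ptt,expected",
        [(0.0, 120.0, 987.0, 120.0), (-0.5, 220.0, 200.0, 120.0),
         (-0.5, 220.0, 180.0, 130.0)],
    )
    def test_linear_baseline(self, a, b, mean_ptt, expected):
        assert estimate_bp_linear(window(mean_ptt), a, b) == pytest.approx(expected)

    @given(
        st.floats(-1.0, 1.0), st.floats(0.0, 300.0),
        st.floats(150.0, 300.0), st.floats(-0.2, 0.2), st.floats(0.0, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_zero_compensation_reduces_to_linear(self, a, b, ptt, vptt, pttv):
        coeffs = CoefficientSet(a=a, b=b, c=0.0, d=0.0)
        w = window(ptt, vptt=vptt, pttv=pttv)
        assert estimate_bp(w, coeffs, REF) == estimate_bp_linear(w, a, b)

    def test_monotone_decreasing_in_ptt_for_negative_a(self):
        coeffs = CoefficientSet(a=-0.4, b=210.0, c=-10.0, d=1.0)
        values = [
            estimate_bp(window(p, vptt=0.02, pttv=2.0), coeffs, REF)
            for p in np.linspace(160, 260, 25)
        ]
        assert np.all(np.diff(values) < 0)


class TestPopulationFit:
    def _synthetic_points(self, coeffs, n=40, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        points = []
        for _ in range(n):
            ref = CalibrationReference(rng.uniform(180, 240), rng.uniform(0.5, 3))
            w = window(
                mean_ptt=rng.uniform(170, 250),
                vptt=rng.uniform(-0.1, 0.1),
                pttv=rng.uniform(0.0, 6.0),
            )
            bp = (
                coeffs.a * w.mean_ptt_ms + coeffs.b + coeffs.c * w.vptt
                + coeffs.d * (w.pttv_ms - ref.pttv0_ms)
                + rng.normal(0.0, noise)
            )
            points.append((w, ref, bp))
        return points

    def test_exact_recovery_from_noise_free_points(self):
        truth = CoefficientSet(a=-0.45, b=215.0, c=-12.0, d=1.7)
        fitted = fit_population_coefficients(self._synthetic_points(truth), "SBP")
        for k in "abcd":
            assert getattr(fitted, k) == pytest.approx(getattr(truth, k), rel=1e-9)

    def test_degenerate_compensation_columns_named(self):
        points = [
            (window(p, vptt=0.0, pttv=1.0),
             CalibrationReference(200.0, 1.0), -0.5 * p + 220)
            for p in np.linspace(180, 240, 10)
        ]
        with pytest.raises(RankDeficiencyError, match="vptt"):
            fit_population_coefficients(points, "SBP")

    def test_too_few_points_rejected(self):
        truth = CoefficientSet(a=-0.45, b=215.0)
        with pytest.raises(ValueError, match="at least 4"):
            fit_population_coefficients(self._synthetic_points(truth, n=3))

    def test_fixed_effects_recover_slopes_with_subject_offsets(self):
        """Per-subject intercept shifts must not leak into a, c, d."""
        rng = np.random.default_rng(1)
        truth = CoefficientSet(a=-0.3, b=200.0, c=-15.0, d=2.0)
        rows = []
        for s in range(8):
            offset = rng.normal(0.0, 10.0)
            for w, ref, bp in self._synthetic_points(truth, n=6, seed=s):
                rows.append((w, ref, bp + offset, f"S{s}"))
        fitted = fit_population_fixed_effects(rows, "SBP")
        for k in "acd":
            assert getattr(fitted, k) == pytest.approx(getattr(truth, k), rel=1e-6)


class TestCalibration:
    def test_closed_form_two_point_solve(self):
        pop = CoefficientSet(a=0.0, b=0.0, c=0.0, d=0.0)
        sit = (window(210.0), 118.0)
        stand = (window(195.0, vptt=-0.0714, pttv=1.5), 126.0)
        coeffs = calibrate_subject(sit, stand, pop, REF)
        assert coeffs.a == pytest.approx((126 - 118) / (195 - 210))
        assert coeffs.b == pytest.approx(118 - coeffs.a * 210)

    def test_identical_posture_ptt_rejected(self):
        pop = CoefficientSet(a=0.0, b=0.0)
        with pytest.raises(DegenerateCalibrationError, match="separation"):
            calibrate_subject((window(210.0), 118.0), (window(210.5), 126.0),
                              pop, REF)

    def test_inverse_consistency_with_population_compensation(self):
        """Data generated from known (a, b) with the population c, d are
        recovered exactly by the two-posture solve."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b = rng.uniform(-0.8, -0.2), rng.uniform(150, 260)
            pop = CoefficientSet(a=0, b=0, c=rng.uniform(-30, 0),
                                 d=rng.uniform(0, 3))
            ref = CalibrationReference(rng.uniform(190, 230), rng.uniform(0, 3))
            w_sit = window(ref.ptt0_ms, vptt=0.0, pttv=ref.pttv0_ms)
            w_stand = window(ref.ptt0_ms - 15.0, vptt=-15.0 / ref.ptt0_ms,
                             pttv=ref.pttv0_ms + 1.0)
            bp = lambda w: (a * w.mean_ptt_ms + b + pop.c * w.vptt
                            + pop.d * (w.pttv_ms - ref.pttv0_ms))
            cal = calibrate_subject((w_sit, bp(w_sit)), (w_stand, bp(w_stand)),
                                    pop, ref)
            assert cal.a == pytest.approx(a, rel=1e-9)
            assert cal.b == pytest.approx(b, rel=1e-9)

    def test_sitting_point_always_interpolated(self):
        """The sitting calibration equation is solved exactly by construction."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            ref = CalibrationReference(rng.uniform(190, 230), rng.uniform(0, 3))
            pop = CoefficientSet(a=0, b=0, c=rng.uniform(-30, 0),
                                 d=rng.uniform(0, 3))
            w_sit = window(ref.ptt0_ms, vptt=0.0, pttv=ref.pttv0_ms)
            w_stand = window(ref.ptt0_ms - rng.uniform(8, 25),
                             vptt=rng.uniform(-0.1, -0.04),
                             pttv=ref.pttv0_ms + rng.uniform(-0.5, 2))
            bp_sit, bp_stand = rng.uniform(100, 130), rng.uniform(105, 140)
            cal = calibrate_subject((w_sit, bp_sit), (w_stand, bp_stand), pop, ref)
            assert estimate_bp(w_sit, cal, ref) == pytest.approx(bp_sit, abs=1e-9)


class TestEstimateSession:
    def test_invalid_session_refused(self, default_cohort, calibrated_default):
        session = next(
            s for s in default_cohort.sessions
            if s.session_label == "estimation_test"
        )
        bad = dataclasses.replace(
            session,
            record=dataclasses.replace(
                session.record, ppg=np.zeros_like(session.record.ppg)
            ),
        )
        profile = calibrated_default.profiles["compensated"][session.subject_id]
        with pytest.raises(ValueError, match="invalid"):
            estimate_session(bad, profile)

    def test_zero_compensation_profile_matches_linear_model(
        self, default_cohort, calibrated_default
    ):
        session = next(
            s for s in default_cohort.sessions
            if s.session_label == "estimation_test"
        )
        profile = calibrated_default.profiles["linear"][session.subject_id]
        comp = estimate_session(session, profile, model="compensated")
        lin = estimate_session(session, profile, model="linear")
        assert [(e.sbp_mmHg, e.dbp_mmHg) for e in comp] == [
            (e.sbp_mmHg, e.dbp_mmHg) for e in lin
        ]

    def test_noise_free_pipeline_inverts_the_law(self, short_config):
        """End-to-end estimates on a noise-free cohort match programmed BP to
        within the error implied by 250 Hz peak quantization.

        Model-application error per beat is |a|·δ + |c|·δ/PTT0 + |d|·2Δ,
        where δ = 2 ms is the worst-case window-mean PTT error (half a
        sample period per beat) and Δ = 4 ms bounds the PTTV perturbation —
        successive differences of quantized PTT can each be off by a full
        sample period, and the reference PTTV0 carries the same error.
        Calibration adds a small propagated term because cuff readings are
        reported at 0.1 mmHg resolution and session PTT means are themselves
        quantized: ~2·0.1·(1 + excursion/posture_gap) ≈ 0.35 mmHg over the
        ±10 ms LF excursion with a 15 ms posture gap.
        """
        cfg = dataclasses.replace(
            short_config.noise_free(),
            sbp_law=PressureLaw(a=-0.45, b=0.0, c=0.0, d=0.0),
            dbp_law=PressureLaw(a=-0.20, b=0.0, c=-8.0, d=0.2),
        )
        cohort = generate_cohort(3, cfg, seed=21)
        run = RunConfig(population_fit_scope="pooled")
        from pttbp.pipeline import collect_subject_data

        data, _ = collect_subject_data(cohort.sessions, run)
        result = fit_and_calibrate(data, run)
        delta, big_delta, cal_slop = 2.0, 4.0, 0.35
        bounds = {
            "SBP": 0.45 * delta + cal_slop,
            "DBP": 0.20 * delta + 8.0 * delta / 180.0
            + 0.2 * 2 * big_delta + cal_slop,
        }
        for session in cohort.sessions:
            if session.session_label != "estimation_test":
                continue
            truth = cohort.truth[(session.subject_id, "estimation_test")]
            profile = result.profiles["compensated"][session.subject_id]
            for est in estimate_session(session, profile):
                i = int(np.argmin(np.abs(truth.r_time_s - est.beat_time_s)))
                assert abs(est.sbp_mmHg - truth.true_sbp_mmHg[i]) <= bounds["SBP"]
                assert abs(est.dbp_mmHg - truth.true_dbp_mmHg[i]) <= bounds["DBP"]


class TestProfileSerialization:
    def test_json_round_trip(self, tmp_path, calibrated_default):
        profile = next(iter(calibrated_default.profiles["compensated"].values()))
        path = tmp_path / "profile.json"
        profile.to_json(path)
        back = CalibrationProfile.from_json(path)
        assert back.subject_id == profile.subject_id
        for pt in ("SBP", "DBP"):
            for k in "abcd":
                assert getattr(back.coeffs(pt), k) == pytest.approx(
                    getattr(profile.coeffs(pt), k)
                )
        assert back.reference.ptt0_ms == pytest.approx(profile.reference.ptt0_ms)
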
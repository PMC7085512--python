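import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from insolegait.biomech import GaitSignals, process_stream
from insolegait.events import Stride, StrideTable, detect_events
from insolegait.transduction import DEFAULT_CALIBRATION as CAL
from insolegait.transduction import system_force_threshold
from insolegait.validation import (
    GRAVITY,
    ReferenceRecording,
    align_and_resample,
    event_mae,
    peak_bm_percent,
    percent_ratio,
    profile_agreement,
    repeatability_rmse,
    stance_profiles,
    stance_to_stride_percent,
    validate,
)


def _ref_from(t, vgrf, cop, fs=200.0, thresh=20.0):
    return ReferenceRecording(t, vgrf, cop, fs, thresh)


class TestAlignAndResample:
    def test_identical_grids_exact(self):
        t200 = np.arange(0, 2, 1 / 200)
        v = np.sin(2 * np.pi * 1.3 * t200) + 2
        ref = _ref_from(t200, v, v)
        t100 = np.arange(0, 2, 1 / 100)
        ins = GaitSignals(t100, np.interp(t100, t200, v), np.full(len(t100), np.nan))
        _, res = align_and_resample(ins, ref, 0.0)
        # 100 Hz nodes coincide with every other 200 Hz sample: interp is exact
        assert np.max(np.abs(res.vgrf - v[::2][: len(res.vgrf)])) < 1e-12

    def test_sine_decimation_closed_form(self):
        t200 = np.arange(0, 1, 1 / 200)
        v = np.sin(2 * np.pi * 5 * t200)
        ref = _ref_from(t200, v, v)
        t100 = np.arange(0, 1, 1 / 100)
        ins = GaitSignals(t100, np.zeros(len(t100)), np.full(len(t100), np.nan))
        _, res = align_and_resample(ins, ref, 0.0)
        expected = np.sin(2 * np.pi * 5 * res.timestamps)
        assert np.max(np.abs(res.vgrf - expected)) < 1e-6

    def test_known_offset_corrected(self):
        t200 = np.arange(0, 3, 1 / 200)
        v = np.cos(2 * np.pi * 0.8 * t200)
        t100 = np.arange(0, 3, 1 / 100)
        ins = GaitSignals(t100, np.zeros(len(t100)), np.full(len(t100), np.nan))
        baseline_i, baseline_r = align_and_resample(
            ins, _ref_from(t200, v, v), 0.0
        )
        # shift the reference clock back 0.25 s, then correct via trigger offset
        shifted = _ref_from(t200 - 0.25, v, v)
        corr_i, corr_r = align_and_resample(ins, shifted, 0.25)
        common = np.intersect1d(
            np.round(baseline_r.timestamps, 9), np.round(corr_r.timestamps, 9)
        )
        a = baseline_r.vgrf[np.isin(np.round(baseline_r.timestamps, 9), common)]
        b = corr_r.vgrf[np.isin(np.round(corr_r.timestamps, 9), common)]
        assert np.max(np.abs(a - b)) < 1e-12

    def test_no_overlap_rejected(self):
        t200 = np.arange(0, 1, 1 / 200)
        ref = _ref_from(t200, np.zeros(len(t200)), np.zeros(len(t200)))
        t100 = np.arange(5, 6, 1 / 100)
        ins = GaitSignals(t100, np.zeros(len(t100)), np.zeros(len(t100)))
        with pytest.raises(ValueError):
            align_and_resample(ins, ref, 0.0)


def _table(hs_offset=0.0, n=6, stance=0.6, stride=1.0):
    return StrideTable(tuple(
        Stride(k * stride + hs_offset, k * stride + hs_offset + stance,
               stride if k + 1 < n else None)
        for k in range(n)
    ))


class TestEventMae:
    def test_identical_tables_zero(self):
        ref = _table()
        mae = event_mae(ref, ref)
        assert mae["mae_hs_s"] == 0.0
        assert mae["mae_to_s"] == 0.0
        assert mae["mae_stance_s"] == 0.0

    def test_three_sample_shift(self):
        ref = _table()
        late = StrideTable(tuple(
            Stride(s.hs_time + 0.03, s.to_time, s.stride_time) for s in ref
        ))
        mae = event_mae(ref, late)
        assert mae["mae_hs_s"] == pytest.approx(0.03, abs=1e-12)
        assert mae["mae_hs_pct_stance"] == pytest.approx(5.0, abs=1e-9)
        assert mae["mae_to_s"] == 0.0

    def test_sign_symmetric(self):
        ref = _table()
        early = StrideTable(tuple(
            Stride(s.hs_time - 0.03, s.to_time, s.stride_time) for s in ref
        ))
        assert event_mae(ref, early)["mae_hs_s"] == pytest.approx(0.03)

    def test_unmatched_strides_dropped(self):
        ref = _table(n=6)
        other = StrideTable(ref.strides[:3])
        mae = event_mae(ref, other)
        assert mae["n_pairs"] == 3

    def test_no_pairs(self):
        assert event_mae(_table(), StrideTable())["n_pairs"] == 0


class TestStanceProfiles:
    def _signals(self, vgrf, fs=100.0):
        t = np.arange(len(vgrf)) / fs
        return GaitSignals(t, np.asarray(vgrf, float), np.asarray(vgrf, float), fs)

    def test_constant_signal_constant_profile(self):
        sig = self._signals(np.full(200, 7.0))
        table = StrideTable((Stride(0.5, 1.1),))
        prof = stance_profiles(sig, table, "vgrf", 101, 20.0)
        assert prof.shape == (1, 101)
        assert np.allclose(prof, 7.0)

    def test_time_warp_invariance(self):
        fs = 100.0
        template = lambda tau: np.sin(np.pi * tau)  # noqa: E731
        n1, n2 = 60, 90
        v = np.zeros(400)
        v[50:50 + n1] = template(np.linspace(0, 1, n1, endpoint=False))
        v[250:250 + n2] = template(np.linspace(0, 1, n2, endpoint=False))
        sig = self._signals(v, fs)
        table = StrideTable((Stride(0.50, 0.50 + n1 / fs, 2.0),
                             Stride(2.50, 2.50 + n2 / fs)))
        prof = stance_profiles(sig, table, "vgrf", 101, lowpass_cutoff=None)
        assert np.max(np.abs(prof[0] - prof[1])) < 0.02

    def test_identity_configuration(self):
        rngv = np.random.default_rng(3).uniform(5, 10, 40)
        sig = self._signals(np.concatenate([np.zeros(10), rngv, np.zeros(10)]))
        table = StrideTable((Stride(0.10, 0.50),))
        prof = stance_profiles(sig, table, "vgrf", n_points=40, lowpass_cutoff=None)
        np.testing.assert_allclose(prof[0], rngv, atol=1e-12)

    def test_short_stance_skipped_with_warning(self):
        sig = self._signals(np.ones(100))
        table = StrideTable((Stride(0.50, 0.52),))
        with pytest.warns(UserWarning):
            prof = stance_profiles(sig, table, "vgrf", 101)
        assert prof.shape == (0, 101)

    def test_bad_n_points(self):
        sig = self._signals(np.ones(10))
        with pytest.raises(ValueError):
            stance_profiles(sig, StrideTable(), "vgrf", n_points=1)


class TestProfileAgreement:
    def test_identical(self):
        p = np.sin(np.linspace(0, np.pi, 101))[None, :]
        agr = profile_agreement(p, p, kind="cop")
        assert agr.rho == pytest.approx(1.0)
        assert agr.rmse == pytest.approx(0.0)

    def test_negation(self):
        p = np.sin(np.linspace(0, np.pi, 101))[None, :]
        assert profile_agreement(p, -p).rho == pytest.approx(-1.0)

    def test_constant_offset(self):
        p = np.linspace(2, 22, 101)[None, :]
        agr = profile_agreement(p, p + 2.0, kind="cop")
        assert agr.rho == pytest.approx(1.0)
        assert agr.rmse == pytest.approx(2.0)

    def test_vgrf_mode_omits_rmse(self):
        p = np.sin(np.linspace(0, np.pi, 101))[None, :]
        assert profile_agreement(p, 2 * p, kind="vgrf").rmse is None

    def test_zero_variance_flagged(self):
        flat = np.full((1, 101), 3.0)
        agr = profile_agreement(flat, flat)
        assert agr.zero_variance
        assert np.isnan(agr.rho)

    @given(st.floats(min_value=0.1, max_value=10),
           st.floats(min_value=-5, max_value=5))
    @settings(max_examples=50, deadline=None)
    def test_rho_affine_invariant(self, scale, shift):
        p = np.sin(np.linspace(0, np.pi, 101))[None, :]
        q = np.cos(np.linspace(0, np.pi, 101))[None, :] + 2
        base = profile_agreement(p, q).rho
        assert profile_agreement(p * scale + shift, q).rho == pytest.approx(base)


class TestRepeatability:
    def test_identical_strides_zero(self):
        p = np.tile(np.linspace(2, 22, 101), (5, 1))
        assert repeatability_rmse(p, "cop") == pytest.approx(0.0, abs=1e-12)

    def test_cop_plus_minus_one_cm(self):
        base = np.linspace(2, 22, 101)
        p = np.vstack([base + 1.0, base - 1.0])
        assert repeatability_rmse(p, "cop") == pytest.approx(1.0)

    def test_vgrf_ten_percent_scaling(self):
        base = np.full(101, 400.0)  # constant template: rms == mean
        p = np.vstack([base * 1.1, base * 0.9])
        rep = repeatability_rmse(p, "vgrf", body_mass=66.2)
        # per-stride: 0.1/1.1 and 0.1/0.9 -> median ~10.1 %
        assert rep == pytest.approx(10.0, abs=1.5)

    def test_single_stride_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(repeatability_rmse(np.ones((1, 101)), "cop"))

    def test_vgrf_requires_mass(self):
        with pytest.raises(ValueError):
            repeatability_rmse(np.ones((2, 101)), "vgrf")


class TestPeakAndHelpers:
    def test_peak_bm_percent_arithmetic(self):
        assert peak_bm_percent([650.0], 66.2) == pytest.approx(
            650.0 / (66.2 * GRAVITY) * 100.0
        )
        assert round(peak_bm_percent([650.0], 66.2), 1) == 100.1

    def test_peak_equals_body_weight(self):
        assert peak_bm_percent([66.2 * GRAVITY], 66.2) == pytest.approx(100.0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            peak_bm_percent([], 66.2)
        with pytest.raises(ValueError):
            peak_bm_percent([1.0], 0.0)

    def test_stance_to_stride_percent(self):
        assert stance_to_stride_percent(10.0, 0.6) == pytest.approx(6.0)
        with pytest.raises(ValueError):
            stance_to_stride_percent(10.0, 1.5)

    def test_percent_ratio(self):
        assert percent_ratio(1.0, 4.0) == 25.0
        with pytest.raises(ValueError):
            percent_ratio(1.0, 0.0)


class TestPipelineSanity:
    def test_simulated_insole_vs_noiseless_reference(self, noisy_trial):
        thresh = system_force_threshold(CAL, 16)
        sig = process_stream(noisy_trial.insole, CAL, noisy_trial.layout, thresh)
        report = validate(sig, noisy_trial.reference, noisy_trial.config.body_mass,
                          thresh)
        assert report.n_pairs == len(noisy_trial.truth)
        assert report.rho_cop > 0.95
        assert report.mae_stance_s < 3 / 100.0
        assert -1 <= report.rho_vgrf <= 1
        assert report.rmse_cop_cm >= 0

    def test_identical_inputs_perfect_agreement(self, noisy_trial):
        thresh = system_force_threshold(CAL, 16)
        sig = process_stream(noisy_trial.insole, CAL, noisy_trial.layout, thresh)
        ref = ReferenceRecording(sig.timestamps, sig.vgrf, sig.cop_ap,
                                 sig.sample_rate, thresh)
        report = validate(sig, ref, noisy_trial.config.body_mass, thresh)
        assert report.mae_hs_s == 0.0
        assert report.mae_to_s == 0.0
        assert report.rho_cop == pytest.approx(1.0)
        assert report.rho_vgrf == pytest.approx(1.0)
        assert report.rmse_cop_cm == pytest.approx(0.0, abs=1e-9)

    def test_report_serialization(self, tmp_path, noisy_trial):
        thresh = system_force_threshold(CAL, 16)
        sig = process_stream(noisy_trial.insole, CAL, noisy_trial.layout, thresh)
        report = validate(sig, noisy_trial.reference, 66.2, thresh)
        path = tmp_path / "report.json"
        report.to_json(path)
        assert path.exists()
        assert "rho_cop" in report.to_table()
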
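"""Breath segmentation, artifact flags, per-breath metrics, minute summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diaphmon.breaths import (
    DetectOptions,
    RejectOptions,
    breath_table,
    compute_breath_metrics,
    detect_breaths,
    minute_summary,
    reject_artifacts,
    trimmed_mean,
)
from diaphmon.signal_io import WaveformRecord
from diaphmon.synthetic import BreathPhenotype, simulate_breath_train

FS = 200.0


class TestDetect:
    def test_quarter_hz_sine_gives_15_breaths_at_upward_crossings(self):
        t = np.arange(int(60 * FS)) / FS
        s = np.sin(2 * np.pi * 0.25 * t)
        breaths = detect_breaths(s, FS, DetectOptions(amplitude_floor=0.05))
        assert len(breaths) == 15
        expected = np.arange(15) * 4.0 * FS  # upward zero crossings every 4 s
        onsets = np.array([b[0] for b in breaths])
        assert np.max(np.abs(onsets - expected)) <= 3

    def test_constant_signal_gives_empty_list(self):
        assert detect_breaths(np.zeros(2000), FS) == []
        assert detect_breaths(np.full(2000, 5.0), FS) == []

    def test_short_signal_gives_empty_list(self):
        assert detect_breaths(np.array([0.0, 1.0]), FS) == []

    def test_simulated_train_count_and_onsets_match_truth(self, clean_train):
        rec, truth = clean_train
        breaths = detect_breaths(rec["pdi"], FS, DetectOptions(amplitude_floor=0.5))
        assert len(breaths) == truth.n_breaths == 20
        onsets = np.array([b[0] for b in breaths])
        true_onsets = np.round(truth.onset_t * FS)
        assert np.max(np.abs(onsets - true_onsets)) <= 2

    @pytest.mark.parametrize("rr", [8, 12, 20, 30, 40])
    def test_breath_count_exact_across_rates(self, rr):
        ph = BreathPhenotype(mean_rr=rr, rr_cv=0.05, exdi_cv=0.1,
                             pdi_noise_sd=0.0, artifact_rate=0.0)
        rec, truth = simulate_breath_train(ph, 120, FS, seed=rr)
        assert len(breath_table(rec)) == truth.n_breaths

    def test_amplitude_scaling_preserves_boundaries_and_scales_metrics(self, clean_train):
        rec, _ = clean_train
        disp = rec["displacement"]
        b1 = detect_breaths(disp, FS, DetectOptions(amplitude_floor=0.05))
        b2 = detect_breaths(3.0 * disp, FS, DetectOptions(amplitude_floor=0.15))
        assert b1 == b2
        r1 = WaveformRecord(fs=FS, channels={"displacement": disp})
        r2 = WaveformRecord(fs=FS, channels={"displacement": 3.0 * disp})
        m1 = compute_breath_metrics(r1, b1)
        m2 = compute_breath_metrics(r2, b2)
        np.testing.assert_allclose(m2["exdi"], 3.0 * m1["exdi"], rtol=1e-12)
        np.testing.assert_allclose(m2["pcvdi"], 3.0 * m1["pcvdi"], rtol=1e-12)


class TestRejectArtifacts:
    def test_uniform_train_all_valid(self, clean_train):
        rec, _ = clean_train
        breaths = detect_breaths(rec["pdi"], FS, DetectOptions(amplitude_floor=0.5))
        assert reject_artifacts(breaths, rec["pdi"], FS).all()

    def test_inserted_coughs_flag_overlapping_breaths(self):
        ph = BreathPhenotype(artifact_rate=0.5, pdi_noise_sd=0.0, exdi_cv=0.1)
        rec, truth = simulate_breath_train(ph, 600, FS, seed=7)
        assert truth.artifact_intervals
        tbl = breath_table(rec)
        for a, b in truth.artifact_intervals:
            over = tbl[(tbl.onset_s < b) & (tbl.onset_s + tbl.duration_s > a)]
            assert not over["valid"].all(), f"artifact ({a:.1f},{b:.1f}) missed"
        # no more invalid breaths than artifacts
        assert int((~tbl["valid"]).sum()) <= len(truth.artifact_intervals)

    def test_infinite_k_mad_keeps_everything(self):
        ph = BreathPhenotype(artifact_rate=1.0, exdi_cv=0.2)
        rec, _ = simulate_breath_train(ph, 300, FS, seed=2)
        breaths = detect_breaths(rec["pdi"], FS, DetectOptions(amplitude_floor=0.5))
        flags = reject_artifacts(breaths, rec["pdi"], FS, RejectOptions(k_mad=math.inf))
        assert flags.all()


class TestMetrics:
    def test_triangular_pulse_exdi_and_pcvdi(self):
        # 0 -> 1.2 cm over 1.0 s then back over 1.0 s, repeated
        n_per = int(2.0 * FS)
        tri = np.concatenate([
            np.linspace(0, 1.2, int(FS), endpoint=False),
            np.linspace(1.2, 0, int(FS), endpoint=False),
        ])
        disp = np.tile(tri, 10)
        rec = WaveformRecord(fs=FS, channels={"displacement": disp})
        breaths = [(k * n_per, k * n_per + int(FS), (k + 1) * n_per) for k in range(10)]
        m = compute_breath_metrics(rec, breaths)
        assert m["exdi"].iloc[3] == pytest.approx(1.2, rel=1e-6)
        assert m["pcvdi"].iloc[3] == pytest.approx(1.2, rel=0.02)

    def test_half_sine_ptp_matches_closed_form(self):
        # half-sine Pdi, amplitude A=10 cmH2O over T=1 s: integral = 2AT/pi
        A, T = 10.0, 1.0
        n_insp = int(T * FS)
        breath = np.concatenate([A * np.sin(np.pi * np.arange(n_insp) / n_insp),
                                 np.zeros(n_insp)])
        pdi = np.tile(breath, 6)
        rec = WaveformRecord(fs=FS, channels={"pdi": pdi})
        breaths = [(k * 2 * n_insp, k * 2 * n_insp + n_insp // 2, (k + 1) * 2 * n_insp)
                   for k in range(6)]
        m = compute_breath_metrics(rec, breaths)
        assert m["ptpdi"].iloc[2] == pytest.approx(2 * A * T / np.pi, rel=1e-3)
        assert m["pdi_peak"].iloc[2] == pytest.approx(A, rel=1e-3)

    def test_square_flow_gives_500_ml(self):
        # +0.5 L/s for 1 s then -0.5 L/s for 1 s: |flow| integrates to 1 L
        one = int(FS)
        cyc = np.concatenate([np.full(one, 0.5), np.full(one, -0.5)])
        rec = WaveformRecord(fs=FS, channels={"flow": np.tile(cyc, 4)})
        breaths = [(k * 2 * one, k * 2 * one + one, (k + 1) * 2 * one) for k in range(4)]
        m = compute_breath_metrics(rec, breaths)
        assert m["vt"].iloc[1] == pytest.approx(500.0, rel=0.01)

    def test_missing_channels_leave_nan_columns(self):
        rec = WaveformRecord(fs=FS, channels={"displacement": np.sin(np.arange(2000) / 50)})
        breaths = detect_breaths(rec["displacement"], FS, DetectOptions(amplitude_floor=0.05))
        m = compute_breath_metrics(rec, breaths)
        assert m["pdi_peak"].isna().all() and m["vt"].isna().all()
        assert m["exdi"].notna().all()

    def test_time_shift_changes_boundaries_not_metrics(self, clean_train):
        rec, _ = clean_train
        shifted = WaveformRecord(fs=FS, channels=dict(rec.channels), t0=rec.t0 + 100.0)
        a = breath_table(rec)
        b = breath_table(shifted)
        np.testing.assert_array_equal(a["onset_idx"], b["onset_idx"])
        np.testing.assert_allclose(b["onset_s"], a["onset_s"] + 100.0)
        for col in ("exdi", "pcvdi", "pdi_peak", "ptpdi", "vt"):
            np.testing.assert_allclose(a[col], b[col], rtol=1e-12)


class TestTrimmedMean:
    def test_one_to_twenty(self):
        assert trimmed_mean(np.arange(1, 21), 0.05) == pytest.approx(10.5)

    def test_small_n_floor_keeps_all(self):
        v = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3]
        assert trimmed_mean(v, 0.05) == pytest.approx(np.mean(v))

    def test_constant(self):
        assert trimmed_mean(np.full(7, 2.5), 0.1) == 2.5

    def test_empty_gives_nan(self):
        assert math.isnan(trimmed_mean([], 0.05))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
           st.floats(0, 0.49))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_min_max_and_zero_fraction_is_mean(self, values, fraction):
        tm = trimmed_mean(values, fraction)
        assert min(values) - 1e-9 <= tm <= max(values) + 1e-9
        assert trimmed_mean(values, 0.0) == pytest.approx(np.mean(values))


class TestMinuteSummary:
    def _uniform_table(self):
        import pandas as pd
        # 15 breaths/min for 5 minutes, exdi 1.0 cm, vt 400 mL
        onsets = np.arange(0, 300, 4.0)
        return pd.DataFrame({
            "onset_s": onsets,
            "valid": True,
            "exdi": 1.0, "pcvdi": 1.5, "pdi_peak": 10.0, "ptpdi": 6.0, "vt": 400.0,
        })

    def test_derived_indices_arithmetic(self):
        s = minute_summary(self._uniform_table(), sbt_start=0.0, timepoints=(1, 2))
        row = s[s.minute == 1].iloc[0]
        assert row.rr == 15
        assert row.rsbi == pytest.approx(37.5)          # 15 / 0.4 L
        assert row.dia_rsbi == pytest.approx(1.5)       # 15 / 10 mm
        assert row.vt_over_exdi == pytest.approx(400.0)
        assert row.ptpdi_per_min == pytest.approx(15 * 6.0)

    def test_truncated_sbt_drops_late_windows(self):
        s = minute_summary(self._uniform_table(), sbt_start=0.0,
                           timepoints=(1, 2, 3, 4, 5, 10), end_s=240.0)
        assert list(s.minute) == [1, 2, 3, 4]

    def test_simulator_truth_recovered_within_one_percent(self):
        ph = BreathPhenotype(mean_exdi=0.8, exdi_cv=0.0, pdi_noise_sd=0.0,
                             artifact_rate=0.0)
        rec, _ = simulate_breath_train(ph, 180, FS, seed=6)
        tbl = breath_table(rec)
        s = minute_summary(tbl, sbt_start=0.0, timepoints=(2,))
        assert s.exdi_tm.iloc[0] == pytest.approx(0.8, rel=0.01)

    def test_rejected_breaths_are_counted_not_used(self):
        ph = BreathPhenotype(artifact_rate=2.0, exdi_cv=0.1)
        rec, _ = simulate_breath_train(ph, 300, FS, seed=9)
        tbl = breath_table(rec)
        s = minute_summary(tbl, 0.0, timepoints=(1, 2, 3, 4, 5))
        detected_per_min = [
            int(((tbl.onset_s >= (m - 1) * 60) & (tbl.onset_s < m * 60)).sum())
            for m in s.minute
        ]
        assert list(s.n_breaths_used + s.n_rejected) == detected_per_min
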
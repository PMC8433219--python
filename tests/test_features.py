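"""Feature-point localization and the 36-parameter feature vectors."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from cardioems import detect, features, pipeline, synth
from cardioems.detect import BeatEvent
from cardioems.features import (
    ALL_PARAMS,
    FP_PARAMS,
    FPMB_PARAMS,
    MB_PARAMS,
    BeatPair,
    FPPoints,
    MBPoints,
    edge_crossing,
)
from cardioems.synth import SimulationConfig


class TestEdgeCrossing:
    @pytest.mark.parametrize("frac,expected", [(0.10, 0.10), (0.50, 0.50), (0.90, 0.90)])
    def test_linear_ramp_crossings(self, frac, expected):
        t = np.linspace(0.0, 1.0, 101)
        v = 100.0 * t
        got, reason = edge_crossing(t, v, 0.0, 100.0, frac, "rising")
        assert reason is None
        assert got == pytest.approx(expected, abs=1e-12)

    def test_quarter_sine_matches_dense_root_finding(self):
        # brute-force oracle: locate the 50% level on a dense grid
        fs = 1000.0
        t = np.arange(0, 0.25, 1 / fs)
        v = np.sin(2 * np.pi * 1.0 * t)
        t_dense = np.arange(0, 0.25, 1e-7)
        v_dense = np.sin(2 * np.pi * 1.0 * t_dense)
        oracle = t_dense[np.argmax(v_dense >= 0.5)]
        got, reason = edge_crossing(t, v, 0.0, 1.0, 0.5, "rising")
        assert reason is None
        assert abs(got - oracle) < 1e-3

    def test_falling_takes_last_crossing(self):
        t = np.linspace(0.0, 1.0, 101)
        v = np.where(t < 0.5, 100.0 * (1 - 2 * t), 0.0)  # falls, then flat
        got, reason = edge_crossing(t, v, 100.0, 0.0, 0.5, "falling")
        assert reason is None
        assert got == pytest.approx(0.25, abs=1e-6)

    def test_level_never_crossed_reports_reason(self):
        t = np.linspace(0, 1, 50)
        got, reason = edge_crossing(t, np.zeros(50), 0.0, 100.0, 0.5, "rising")
        assert math.isnan(got) and reason == "level_not_crossed"

    def test_degenerate_refs_reported(self):
        t = np.linspace(0, 1, 50)
        got, reason = edge_crossing(t, np.ones(50), 1.0, 1.0, 0.5, "rising")
        assert math.isnan(got) and reason == "degenerate_refs"


class TestFPExtraction:
    def test_returns_exactly_eight_named_points(self, quiet_analysis):
        pts = features.extract_fp_points(
            quiet_analysis["recording"], quiet_analysis["fp_events"][3]
        )
        assert set(pts.times) == {f"E{i}" for i in range(1, 9)}
        assert pts.missing == {}

    def test_point_times_match_ground_truth_within_two_samples(self, quiet_analysis):
        rec = quiet_analysis["recording"]
        tol = 2.0 / rec.fs_fp
        for i, ev in enumerate(quiet_analysis["fp_events"]):
            pts = features.extract_fp_points(rec, ev)
            gt = rec.ground_truth["fp_points"][i]
            for name, t_true in gt.items():
                assert abs(pts.time(name) - t_true) <= tol, name

    def test_monotone_point_order_under_noise(self, noisy_recording):
        rec = noisy_recording
        fp_f = detect.apply_filter(
            rec.fp, rec.fs_fp, detect.FilterSpec("lowpass", 3000.0)
        )
        events = detect.detect_beats(fp_f, rec.fs_fp, detect.FP_DETECTION, "FP")
        for ev in events:
            pts = features.extract_fp_points(rec, ev)
            seq = [pts.time(f"E{i}") for i in range(1, 9) if f"E{i}" in pts.times]
            assert all(a < b for a, b in zip(seq, seq[1:]))

    def test_absent_second_wave_degrades_gracefully(self, zero_noise):
        fp_t = synth.FPTemplateParams(second_amplitude=0.0)
        cfg = SimulationConfig(seed=6, duration=10.0, fp_template=fp_t, noise=zero_noise)
        rec = synth.simulate_recording(cfg)
        ev = detect.detect_beats(rec.fp, rec.fs_fp, detect.FP_DETECTION, "FP")
        pts = features.extract_fp_points(rec, ev[2])
        assert {"E1", "E2", "E3", "E4"} <= set(pts.times)
        assert {"E5", "E6", "E7", "E8"} <= set(pts.missing)


class TestMBExtraction:
    def test_returns_exactly_five_named_points(self, quiet_analysis):
        pts = features.extract_mb_points(
            quiet_analysis["recording"], quiet_analysis["mb_events"][3]
        )
        assert set(pts.times) == {f"M{i}" for i in range(1, 6)}

    def test_point_times_match_ground_truth_within_two_samples(self, quiet_analysis):
        rec = quiet_analysis["recording"]
        tol = 2.0 / rec.fs_mb
        for i, ev in enumerate(quiet_analysis["mb_events"]):
            pts = features.extract_mb_points(rec, ev)
            gt = rec.ground_truth["mb_points"][i]
            for name, t_true in gt.items():
                assert abs(pts.time(name) - t_true) <= tol, name

    def test_zero_amplitude_bump_all_missing(self, quiet_recording):
        rec = quiet_recording
        flat = synth.Recording(
            fp=rec.fp,
            mb=np.zeros_like(rec.mb),
            fs_fp=rec.fs_fp,
            fs_mb=rec.fs_mb,
            metadata=rec.metadata,
        )
        ev = BeatEvent(anchor_time=2.0, window_start=1.3, window_end=2.7, signal_kind="MB")
        pts = features.extract_mb_points(flat, ev)
        assert set(pts.missing) == {f"M{i}" for i in range(1, 6)}
        assert pts.times == {}


class TestPairing:
    def test_empty_mb_list_leaves_all_unpaired(self, quiet_analysis):
        fp_ev = quiet_analysis["fp_events"]
        pairs, unpaired_fp, unpaired_mb = features.pair_beats(fp_ev, [])
        assert pairs == [] and unpaired_mb == []
        assert len(unpaired_fp) == len(fp_ev)

    def test_single_pair_within_lag(self):
        fe = BeatEvent(anchor_time=1.0, window_start=0.8, window_end=1.5, signal_kind="FP")
        me = BeatEvent(anchor_time=1.2, window_start=0.9, window_end=1.8, signal_kind="MB")
        pairs, ufp, umb = features.pair_beats([fe], [me], max_lag=0.5)
        assert len(pairs) == 1 and ufp == [] and umb == []

    def test_contraction_never_pairs_before_excitation(self):
        fe = BeatEvent(anchor_time=1.0, window_start=0.8, window_end=1.5, signal_kind="FP")
        me = BeatEvent(anchor_time=0.9, window_start=0.5, window_end=1.2, signal_kind="MB")
        pairs, ufp, umb = features.pair_beats([fe], [me], max_lag=0.5)
        assert pairs == [] and len(ufp) == 1 and len(umb) == 1

    def test_coupled_simulation_pairs_every_beat(self, quiet_analysis):
        rec = quiet_analysis["recording"]
        pairs, ufp, umb = features.pair_beats(
            quiet_analysis["fp_events"], quiet_analysis["mb_events"]
        )
        n_true = len(rec.ground_truth["beat_times"])
        assert len(pairs) == n_true and ufp == [] and umb == []
        tmpl = rec.ground_truth["mb_template"]
        want_lag = tmpl["em_delay"] + tmpl["rise_dur"]
        for fe, me in pairs:
            assert me.anchor_time - fe.anchor_time == pytest.approx(
                want_lag, abs=2.0 / rec.fs_mb
            )


class TestFeatureVector:
    def test_parameter_name_structure(self):
        assert len(FP_PARAMS) == 12
        assert len(MB_PARAMS) == 8
        assert len(FPMB_PARAMS) == 16
        assert len(ALL_PARAMS) == 36
        want = {f"E{i}M{j}" for i in (1, 4, 6, 8) for j in (1, 2, 3, 4)}
        assert set(FPMB_PARAMS) == want

    def test_simultaneous_points_give_zero_duration(self):
        fp = FPPoints(
            times={f"E{i}": 0.1 * i for i in range(1, 9)},
            values={f"E{i}": float(i) for i in range(1, 9)},
            baseline=0.0,
        )
        mb = MBPoints(
            times={"M1": 0.1, "M2": 0.2, "M3": 0.3, "M4": 0.4, "M5": 0.5},
            values={f"M{i}": float(i) for i in range(1, 6)},
            baseline=0.0,
        )
        vec = features.compute_feature_vector(BeatPair(fp, mb))
        assert vec["E1M1"] == pytest.approx(0.0, abs=1e-12)  # both at t=0.1

    def test_rate_is_reciprocal_of_interval(self, quiet_analysis):
        beats = quiet_analysis["beats"].dropna(subset=["firing_interval"])
        assert np.allclose(beats.firing_rate, 60.0 / beats.firing_interval)
        assert np.allclose(beats.beating_rate, 60.0 / beats.beating_interval)

    def test_durations_recover_template_ground_truth(self, quiet_analysis):
        rec = quiet_analysis["recording"]
        beats = quiet_analysis["beats"]
        fp_t = rec.ground_truth["fp_template"]
        tol = 2.0 / rec.fs_fp
        assert abs(beats.E3E4.mean() - fp_t["spike_fall_dur"]) <= tol
        assert abs(beats.E4E6.mean() - fp_t["second_delay"]) <= tol
        assert abs(beats.E6E8.mean() - fp_t["second_fall_dur"]) <= tol

    def test_amplitudes_recover_template_within_one_percent(self, quiet_analysis):
        rec = quiet_analysis["recording"]
        beats = quiet_analysis["beats"]
        fp_t = rec.ground_truth["fp_template"]
        mb_t = rec.ground_truth["mb_template"]
        assert beats.first_amplitude.mean() == pytest.approx(
            fp_t["first_amplitude"], rel=0.01
        )
        assert beats.second_amplitude.mean() == pytest.approx(
            fp_t["second_amplitude"], rel=0.01
        )
        assert beats.beating_amplitude.mean() == pytest.approx(
            mb_t["beat_amplitude"], rel=0.01
        )

    def test_firing_and_beating_intervals_agree(self, quiet_analysis):
        # excitation-contraction coupling: the two interval series coincide
        rec = quiet_analysis["recording"]
        beats = quiet_analysis["beats"].dropna(subset=["firing_interval", "beating_interval"])
        diff = np.abs(beats.firing_interval - beats.beating_interval)
        assert np.max(diff) <= 2.0 / rec.fs_mb


class TestSummarizeEpoch:
    def test_single_vector_sd_zero(self):
        out = features.summarize_epoch([{p: 1.0 for p in ALL_PARAMS}])
        assert (out["sd"] == 0.0).all()
        assert (out["n"] == 1).all()

    def test_closed_form_mean_and_sd(self):
        vecs = [{"firing_rate": v} for v in (1.0, 2.0, 3.0)]
        out = features.summarize_epoch(vecs)
        assert out.loc["firing_rate", "mean"] == pytest.approx(2.0)
        assert out.loc["firing_rate", "sd"] == pytest.approx(1.0)

    def test_epoch_rate_matches_configured_rate(self, quiet_analysis):
        out = features.summarize_epoch(quiet_analysis["beats"])
        rate = quiet_analysis["recording"].ground_truth["rate_bpm"]
        assert out.loc["firing_rate", "mean"] == pytest.approx(rate, rel=0.02)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            features.summarize_epoch([])
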
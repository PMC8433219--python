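"""Generator contracts: template morphology, drug modifiers, simulation."""

import numpy as np
import pytest

from cardioems import synth
from cardioems.synth import (
    DrugEffect,
    DrugEffectProfile,
    FPTemplateParams,
    InvalidParameterError,
    MBTemplateParams,
    NoiseModel,
    SimulationConfig,
)


class TestFPTemplate:
    def test_zero_amplitudes_give_flat_waveform(self):
        p = FPTemplateParams(first_amplitude=0.0, second_amplitude=0.0)
        w = synth.make_fp_template(p, 10_000.0)
        assert np.allclose(w, 0.0)

    def test_peak_to_valley_equals_first_amplitude(self):
        # 428 µV is the configured default firing amplitude of a healthy culture
        p = FPTemplateParams(first_amplitude=428.0)
        w = synth.make_fp_template(p, 10_000.0)
        fast = w[: int(0.07 * 10_000)]  # fast spike region
        assert fast.max() - fast.min() == pytest.approx(428.0, rel=1e-3)

    def test_global_max_at_spike_rise_dur(self):
        # dense-grid oracle: the analytic peak sits at the end of the rise
        p = FPTemplateParams()
        fs = 10_000.0
        w = synth.make_fp_template(p, fs)
        dense = synth.make_fp_template(p, 1_000_000.0)
        t_dense = np.argmax(dense) / 1_000_000.0
        assert abs(np.argmax(w) / fs - p.spike_rise_dur) <= 1.0 / fs
        assert abs(t_dense - p.spike_rise_dur) <= 2e-6

    def test_two_maxima_two_minima(self):
        from scipy.signal import find_peaks

        w = synth.make_fp_template(FPTemplateParams(), 10_000.0)
        maxima, _ = find_peaks(w, prominence=1.0)
        minima, _ = find_peaks(-w, prominence=1.0)
        assert len(maxima) == 2  # E3 and E6
        assert len(minima) == 2  # E4 and E8

    def test_invalid_durations_raise(self):
        with pytest.raises(InvalidParameterError):
            synth.make_fp_template(FPTemplateParams(spike_rise_dur=-0.01), 1000.0)
        with pytest.raises(InvalidParameterError):
            synth.make_fp_template(FPTemplateParams(), 0.0)

    def test_feature_times_strictly_ordered(self):
        t = synth.fp_feature_times(FPTemplateParams())
        seq = [t[f"E{i}"] for i in range(1, 9)]
        assert all(a < b for a, b in zip(seq, seq[1:]))


class TestMBTemplate:
    def test_zero_amplitude_flat(self):
        w = synth.make_mb_template(MBTemplateParams(beat_amplitude=0.0), 1000.0)
        assert np.allclose(w, 0.0)

    def test_argmax_at_rise_dur(self):
        w = synth.make_mb_template(MBTemplateParams(rise_dur=0.2), 1000.0)
        assert abs(np.argmax(w) - 200) <= 1

    def test_nonnegative_unimodal_peak_equals_amplitude(self):
        p = MBTemplateParams(beat_amplitude=17.5)
        w = synth.make_mb_template(p, 1000.0)
        assert w.min() >= 0.0
        assert w.max() == pytest.approx(17.5, rel=1e-4)
        inner = w[np.abs(w) > 1e-12]
        assert np.sum(np.diff(np.sign(np.diff(inner))) != 0) == 1

    def test_decays_90_percent_within_fall_dur(self):
        p = MBTemplateParams()
        fs = 10_000.0
        w = synth.make_mb_template(p, fs)
        i = int(round((p.rise_dur + p.fall_dur) * fs))
        assert w[i] <= 0.101 * p.beat_amplitude


class TestDrugEffects:
    def test_zero_dose_is_identity(self):
        profile = synth.load_drug_profile("lidocaine")
        factors = synth.apply_drug_effect(profile, 0.0, 5.0)
        assert all(f == 1.0 for f in factors.values())

    def test_lidocaine_top_dose_rate_factor(self):
        # at 100 µM and steady state the firing rate falls by 57.58%
        profile = synth.load_drug_profile("lidocaine")
        factors = synth.apply_drug_effect(profile, 100.0, None)
        assert factors["rate"] == pytest.approx(1.0 - 0.5758, abs=1e-4)

    def test_half_effect_at_ec50(self):
        # direct Hill evaluation: c = EC50 halves the saturating effect
        for n in (0.5, 1.0, 2.7):
            e = DrugEffect(target="rate", max_effect=-0.6, ec50=11.1, hill_n=n)
            prof = DrugEffectProfile(drug_name="x", effects=(e,))
            f = synth.apply_drug_effect(prof, 11.1, None)["rate"]
            assert f == pytest.approx(1.0 - 0.3, abs=1e-12)

    def test_onset_kinetics_single_exponential(self):
        e = DrugEffect(target="rate", max_effect=-0.5, ec50=1.0, hill_n=1.0, onset_tau=5.0)
        prof = DrugEffectProfile(drug_name="x", effects=(e,))
        hill = 100.0 / 101.0
        f5 = synth.apply_drug_effect(prof, 100.0, 5.0)["rate"]
        assert f5 == pytest.approx(1.0 - 0.5 * hill * (1 - np.exp(-1.0)), abs=1e-12)

    def test_unknown_target_rejected(self):
        e = DrugEffect(target="resistance", max_effect=0.1, ec50=1.0)
        with pytest.raises(InvalidParameterError):
            e.validate()

    @pytest.mark.parametrize("name", synth.PACKAGED_PROFILES)
    def test_packaged_profiles_monotone_over_dose_grid(self, name):
        profile = synth.load_drug_profile(name)
        prev = {e.target: 0.0 for e in profile.effects}
        for c in profile.doses:
            factors = synth.apply_drug_effect(profile, c, None)
            for target, f in factors.items():
                assert abs(f - 1.0) > prev[target]
                prev[target] = abs(f - 1.0)


class TestSimulateRecording:
    def test_beat_count_near_nominal_rate(self):
        rec = synth.simulate_recording(SimulationConfig(seed=1))
        assert 59 <= len(rec.ground_truth["beat_times"]) <= 61

    def test_degenerate_duration_gives_empty_ground_truth(self):
        rec = synth.simulate_recording(SimulationConfig(seed=1, duration=0.1))
        assert rec.ground_truth["beat_times"] == []
        assert len(rec.fp) == int(0.1 * 10_000)

    def test_seeded_determinism(self):
        a = synth.simulate_recording(SimulationConfig(seed=11))
        b = synth.simulate_recording(SimulationConfig(seed=11))
        assert np.array_equal(a.fp, b.fp) and np.array_equal(a.mb, b.mb)

    def test_channels_differ_under_same_seed(self):
        a = synth.simulate_recording(SimulationConfig(seed=11), channel=0)
        b = synth.simulate_recording(SimulationConfig(seed=11), channel=1)
        assert not np.array_equal(a.fp, b.fp)

    def test_beat_count_scales_with_duration(self, zero_noise):
        c1 = SimulationConfig(seed=2, duration=40.0, noise=zero_noise)
        c2 = SimulationConfig(seed=2, duration=80.0, noise=zero_noise)
        n1 = len(synth.simulate_recording(c1).ground_truth["beat_times"])
        n2 = len(synth.simulate_recording(c2).ground_truth["beat_times"])
        assert abs(n2 - 2 * n1) <= 2

    def test_ground_truth_times_inside_epoch(self, quiet_recording):
        gt = quiet_recording.ground_truth
        for pts in gt["fp_points"] + gt["mb_points"]:
            for v in pts.values():
                assert 0.0 < v < quiet_recording.duration

    def test_study_grid_shapes(self):
        cfg = SimulationConfig(seed=1, n_channels=2, duration=2.0)
        control = synth.simulate_study(cfg, None, (0.0,), timepoints_min=(0.0, 5.0))
        assert len(control) == 4
        profile = synth.load_drug_profile("lidocaine")
        drug = synth.simulate_study(
            cfg, profile, (0.0, 100.0), timepoints_min=(5.0, 10.0)
        )
        # per channel: one pre-dose baseline + 2 timepoints at the dose
        assert len(drug) == 2 * 3
        base = [r for r in drug if r.metadata["concentration"] == 0.0]
        assert all(r.metadata["time_min"] == 0.0 for r in base)


class TestModulateCarrier:
    def test_low_sampling_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.modulate_carrier(np.zeros(100), 1000.0, 10_000.0, fs_out=20_000.0)

    def test_fs_four_times_carrier_accepted(self):
        out = synth.modulate_carrier(np.zeros(100), 1000.0, 10_000.0, fs_out=40_000.0)
        assert len(out) > 0

    def test_flat_input_gives_constant_envelope(self):
        out = synth.modulate_carrier(np.zeros(500), 1000.0, 10_000.0, fs_out=80_000.0)
        # rectified peaks all equal the offset
        peaks = np.abs(out[np.abs(out) > 0.99 * np.max(np.abs(out))])
        assert np.allclose(peaks, peaks[0], rtol=1e-2)

    def test_envelope_matches_offset_plus_trace(self):
        # rectify + low-pass oracle recovers offset + mb within 1%; the
        # carrier must be sampled densely so mean(|sin|) converges to 2/pi
        from scipy.signal import butter, sosfiltfilt

        fs_out = 320_000.0
        t = np.arange(0, 2.0, 1e-3)
        mb = 5.0 * np.clip(np.sin(2 * np.pi * 1.0 * t), 0, None)
        out = synth.modulate_carrier(mb, 1000.0, 10_000.0, fs_out=fs_out, offset=40.0)
        sos = butter(4, 100.0 / (fs_out / 2), output="sos")
        env = sosfiltfilt(sos, np.abs(out)) * np.pi / 2.0
        t_hi = np.arange(len(out)) / fs_out
        want = 40.0 + np.interp(t_hi, t, mb)
        core = slice(int(0.05 * fs_out), -int(0.05 * fs_out))
        assert np.max(np.abs(env[core] - want[core])) < 0.01 * 45.0
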
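"""Shared fixtures: simulated recordings and analyzed study tables.

Heavy simulations are session-scoped so the detection/extraction pipeline
runs once per study and every test reads from the same tables.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardioems import pipeline, synth


@pytest.fixture(scope="session")
def zero_noise():
    return synth.NoiseModel(
        fp_white_sd=0.0, mb_white_sd=0.0, drift_amp=0.0, beat_jitter_cv=0.0
    )


@pytest.fixture(scope="session")
def quiet_recording(zero_noise):
    """Noise-free 30 s control epoch: the extraction oracle's ground truth."""
    cfg = synth.SimulationConfig(seed=3, duration=30.0, noise=zero_noise)
    return synth.simulate_recording(cfg)


@pytest.fixture(scope="session")
def quiet_analysis(quiet_recording):
    beats, events, reasons = pipeline.analyze_recording(quiet_recording)
    return {
        "recording": quiet_recording,
        "beats": beats,
        "fp_events": [e for e in events if e.signal_kind == "FP"],
        "mb_events": [e for e in events if e.signal_kind == "MB"],
        "reasons": reasons,
    }


@pytest.fixture(scope="session")
def noisy_recording():
    """Default-noise 60 s control epoch."""
    return synth.simulate_recording(synth.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def control_study_beats():
    """4-channel vehicle-control stability study: epochs at 0/5/10/15 min."""
    cfg = synth.SimulationConfig(seed=1, n_channels=4)
    recs = synth.simulate_study(cfg, None, (0.0,), timepoints_min=(0.0, 5.0, 10.0, 15.0))
    beats, _ = pipeline.study_table(recs)
    return beats


@pytest.fixture(scope="session")
def lidocaine_top_beats():
    """4-channel baseline + 100 µM lidocaine epochs at steady state."""
    cfg = synth.SimulationConfig(seed=1, n_channels=4)
    profile = synth.load_drug_profile("lidocaine")
    recs = synth.simulate_study(cfg, profile, (0.0, 100.0), timepoints_min=(None,))
    beats, _ = pipeline.study_table(recs)
    return beats


@pytest.fixture(scope="session")
def lidocaine_dose_beats():
    """4-channel full 5-dose lidocaine study (30 s epochs, steady state)."""
    cfg = synth.SimulationConfig(seed=1, n_channels=4, duration=30.0)
    profile = synth.load_drug_profile("lidocaine")
    recs = synth.simulate_study(
        cfg, profile, (0.0,) + profile.doses, timepoints_min=(None,)
    )
    beats, _ = pipeline.study_table(recs)
    return beats


@pytest.fixture(scope="session")
def lidocaine_timecourse_beats():
    """4-channel lidocaine top-dose time course at 5/10/15 min post-dose."""
    cfg = synth.SimulationConfig(seed=1, n_channels=4, duration=30.0)
    profile = synth.load_drug_profile("lidocaine")
    recs = synth.simulate_study(
        cfg, profile, (0.0, 100.0), timepoints_min=(5.0, 10.0, 15.0)
    )
    beats, _ = pipeline.study_table(recs)
    return beats
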
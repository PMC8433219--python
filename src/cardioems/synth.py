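"""Synthetic generator for synchronized cardiomyocyte FP/MB recordings.

Emulates the two signal modalities of an electrical-mechanical synchronized
(EMS) recording of beating cardiomyocytes:

* **FP** (firing potential): extracellular field potential in microvolts — a
  fast biphasic spike (rise to the first peak E3, fall to the valley E4)
  followed, after a delay, by a slower second wave (rise to the second peak
  E6, fall to the second valley E8).
* **MB** (mechanical beating): impedance fluctuation in ohms — one unimodal
  asymmetric contraction bump per beat (rise to the peak M3, slower decay),
  starting an electromechanical delay after the FP fast-spike peak.

Templates are built from half-cosine (raised-cosine) segments, so every
waveform is C^1, monotone between its extrema, and every fractional
edge-crossing time has a closed form.  The generator therefore knows the
exact ground-truth time of each E1–E8 / M1–M5 feature point of every beat it
emits, which downstream detection/extraction tests use as their oracle.

Drug action is modelled as multiplicative modifiers on rate, amplitudes,
template durations and the electromechanical delay, with a Hill
concentration dependence and single-exponential onset kinetics.  Profiles
for lidocaine and isradipine ship with the package (``load_drug_profile``),
with endpoint effect sizes transcribed from published percent changes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FPTemplateParams",
    "MBTemplateParams",
    "NoiseModel",
    "DrugEffect",
    "DrugEffectProfile",
    "SimulationConfig",
    "Recording",
    "make_fp_template",
    "make_mb_template",
    "fp_feature_times",
    "fp_feature_values",
    "mb_feature_times",
    "apply_drug_effect",
    "apply_profile_to_templates",
    "simulate_recording",
    "simulate_study",
    "modulate_carrier",
    "load_drug_profile",
    "PACKAGED_PROFILES",
]

# total cosine fall time of the MB bump per unit of 90%-decay time:
# the bump has decayed 90% when cos(pi*t/T) = -0.8, i.e. t = T*arccos(-0.8)/pi
_MB_FALL_STRETCH = math.pi / math.acos(-0.8)

# fraction of the FP first/second amplitude above baseline at the peak
_FP_FIRST_PEAK_FRAC = 0.7
_FP_SECOND_PEAK_FRAC = 0.85
_FP_TAIL_FRAC = 0.6  # post-E8 recovery length as a fraction of second_fall_dur

# the spike fall is biphasic, as in real extracellular records: a steep drop
# through _FP_FALL_KNEE_V of the first amplitude within _FP_FALL_KNEE_T of
# the fall duration, then a slow approach to the valley.  This keeps the
# crest sharp (high curvature on both flanks) so peak timing is well posed.
_FP_FALL_KNEE_T = 0.25
_FP_FALL_KNEE_V = 0.65


class InvalidParameterError(ValueError):
    """A template/simulation parameter violates its contract."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FPTemplateParams:
    """Shape of one firing-potential beat.

    Amplitudes are peak-to-valley: ``first_amplitude`` = E3 − E4,
    ``second_amplitude`` = E6 − E8.  Durations are in seconds;
    ``second_delay`` spans E4→E6 and must exceed ``second_rise_dur`` (the
    remainder is the post-valley recovery back to baseline).
    """

    first_amplitude: float = 428.0  # µV
    second_amplitude: float = 120.0  # µV
    spike_rise_dur: float = 0.010  # s, onset -> E3
    spike_fall_dur: float = 0.045  # s, E3 -> E4
    second_delay: float = 0.240  # s, E4 -> E6
    second_rise_dur: float = 0.080  # s, rise portion of second_delay
    second_fall_dur: float = 0.055  # s, E6 -> E8

    def validate(self) -> None:
        durs = (
            self.spike_rise_dur,
            self.spike_fall_dur,
            self.second_delay,
            self.second_rise_dur,
            self.second_fall_dur,
        )
        if any(d <= 0 for d in durs):
            raise InvalidParameterError("all FP template durations must be > 0")
        if self.second_delay < self.second_rise_dur:
            raise InvalidParameterError(
                "second_delay (E4->E6) must be >= second_rise_dur"
            )
        if self.first_amplitude < 0 or self.second_amplitude < 0:
            raise InvalidParameterError("FP amplitudes must be >= 0")

    @property
    def envelope_dur(self) -> float:
        """Length of the non-zero part of the template, seconds."""
        return (
            self.spike_rise_dur
            + self.spike_fall_dur
            + self.second_delay
            + self.second_fall_dur * (1.0 + _FP_TAIL_FRAC)
        )


@dataclass(frozen=True)
class MBTemplateParams:
    """Shape of one mechanical-beating bump plus its coupling to the FP spike.

    ``fall_dur`` is the time from the peak M3 to 90% decay; ``em_delay`` is
    the electromechanical latency from the FP fast-spike peak (E3) to the
    onset of the contraction bump.
    """

    beat_amplitude: float = 20.0  # Ω
    rise_dur: float = 0.300  # s, onset -> M3
    fall_dur: float = 0.250  # s, M3 -> 90% decay
    em_delay: float = 0.090  # s, E3 -> MB onset

    def validate(self) -> None:
        if self.rise_dur <= 0 or self.fall_dur <= 0 or self.em_delay <= 0:
            raise InvalidParameterError("MB durations and em_delay must be > 0")
        if self.beat_amplitude < 0:
            raise InvalidParameterError("beat_amplitude must be >= 0")

    @property
    def envelope_dur(self) -> float:
        return self.rise_dur + self.fall_dur * _MB_FALL_STRETCH


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement noise and slow baseline drift.

    ``drift_amp`` is a fraction of the signal amplitude (FP first amplitude
    / MB beat amplitude); ``beat_jitter_cv`` is the coefficient of variation
    of the inter-beat intervals (gamma renewal process).
    """

    fp_white_sd: float = 10.0  # µV
    mb_white_sd: float = 0.4  # Ω (2% of the default beat amplitude)
    drift_amp: float = 0.02
    drift_period: float = 30.0  # s
    beat_jitter_cv: float = 0.02

    def validate(self) -> None:
        fields = (
            self.fp_white_sd,
            self.mb_white_sd,
            self.drift_amp,
            self.drift_period,
            self.beat_jitter_cv,
        )
        if any(v < 0 for v in fields):
            raise InvalidParameterError("noise model fields must be >= 0")


#: drug-effect targets that scale a named template duration.  Duration
#: targets are named by the feature-point pair they control; each maps to a
#: template field (E4E6 scales the whole second-wave complex, i.e. both
#: second_delay and second_rise_dur, to keep the template valid).
DURATION_TARGETS = {
    "E1E3": "spike_rise_dur",
    "E3E4": "spike_fall_dur",
    "E4E6": "second_delay",
    "E6E8": "second_fall_dur",
    "M1M3": "rise_dur",
    "M3M5": "fall_dur",
}

SCALAR_TARGETS = (
    "rate",
    "fp_first_amplitude",
    "fp_second_amplitude",
    "mb_amplitude",
    "em_delay",
)


@dataclass(frozen=True)
class DrugEffect:
    """One Hill-type concentration-effect entry of a drug profile."""

    target: str
    max_effect: float  # signed fractional change at saturating concentration
    ec50: float  # same unit as the profile's concentrations
    hill_n: float = 2.0
    onset_tau: float = 5.0  # min

    def validate(self) -> None:
        if self.target not in SCALAR_TARGETS and self.target not in DURATION_TARGETS:
            raise InvalidParameterError(f"unknown drug-effect target {self.target!r}")
        if self.ec50 <= 0 or self.hill_n <= 0 or self.onset_tau <= 0:
            raise InvalidParameterError("ec50, hill_n and onset_tau must be > 0")
        if 1.0 + self.max_effect < 0:
            raise InvalidParameterError("max_effect must keep 1 + max_effect >= 0")


@dataclass(frozen=True)
class DrugEffectProfile:
    drug_name: str
    effects: tuple[DrugEffect, ...]
    concentration_unit: str = "uM"
    doses: tuple[float, ...] = ()  # the study's concentration grid

    def validate(self) -> None:
        for e in self.effects:
            e.validate()


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated recording epoch."""

    fs_fp: float = 10_000.0  # Hz
    fs_mb: float = 1_000.0  # Hz
    duration: float = 60.0  # s
    base_rate: float = 60.0  # beats/min
    fp_template: FPTemplateParams = field(default_factory=FPTemplateParams)
    mb_template: MBTemplateParams = field(default_factory=MBTemplateParams)
    noise: NoiseModel = field(default_factory=NoiseModel)
    drug: Optional[DrugEffectProfile] = None
    concentration: float = 0.0
    time_since_dose: Optional[float] = None  # min; None = steady state
    seed: int = 0
    n_channels: int = 1

    def validate(self) -> None:
        if self.fs_fp < 1000.0:
            raise InvalidParameterError("fs_fp must be >= 1000 Hz")
        if self.fs_mb < 100.0:
            raise InvalidParameterError("fs_mb must be >= 100 Hz")
        if self.duration <= 0 or self.base_rate <= 0:
            raise InvalidParameterError("duration and base_rate must be > 0")
        self.fp_template.validate()
        self.mb_template.validate()
        self.noise.validate()
        if self.drug is not None:
            self.drug.validate()


@dataclass
class Recording:
    """One channel's synchronized FP and MB traces plus metadata.

    Both traces share the time origin (t = 0 at the start of the epoch).
    ``ground_truth`` is present only on simulator output and carries the
    true beat onsets and feature-point times.
    """

    fp: np.ndarray  # µV, sampled at fs_fp
    mb: np.ndarray  # Ω, sampled at fs_mb
    fs_fp: float
    fs_mb: float
    metadata: dict = field(default_factory=dict)
    ground_truth: Optional[dict] = None

    @property
    def duration(self) -> float:
        return len(self.fp) / self.fs_fp

    @property
    def fp_time(self) -> np.ndarray:
        return np.arange(len(self.fp)) / self.fs_fp

    @property
    def mb_time(self) -> np.ndarray:
        return np.arange(len(self.mb)) / self.fs_mb


# ---------------------------------------------------------------------------
# half-cosine segment machinery
# ---------------------------------------------------------------------------


def _ramp_invert(frac: float) -> float:
    """Normalized time at which a half-cosine ramp has covered `frac` of its span."""
    return math.acos(1.0 - 2.0 * frac) / math.pi


def _eval_segments(segments, t):
    """Evaluate a piecewise half-cosine curve (0 outside all segments)."""
    out = np.zeros_like(t, dtype=float)
    for (t0, t1, v0, v1) in segments:
        if t1 <= t0:
            continue
        m = (t >= t0) & (t < t1)
        if not np.any(m):
            continue
        x = (t[m] - t0) / (t1 - t0)
        out[m] = v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * x))
    return out


def _fp_segments(p: FPTemplateParams):
    p1 = _FP_FIRST_PEAK_FRAC * p.first_amplitude
    v1 = p1 - p.first_amplitude
    p2 = _FP_SECOND_PEAK_FRAC * p.second_amplitude
    v2 = p2 - p.second_amplitude
    t_e3 = p.spike_rise_dur
    t_e4 = t_e3 + p.spike_fall_dur
    t_knee = t_e3 + _FP_FALL_KNEE_T * p.spike_fall_dur
    v_knee = p1 - _FP_FALL_KNEE_V * p.first_amplitude
    t_rise = t_e4 + (p.second_delay - p.second_rise_dur)
    t_e6 = t_e4 + p.second_delay
    t_e8 = t_e6 + p.second_fall_dur
    t_end = t_e8 + _FP_TAIL_FRAC * p.second_fall_dur
    return [
        (0.0, t_e3, 0.0, p1),
        (t_e3, t_knee, p1, v_knee),
        (t_knee, t_e4, v_knee, v1),
        (t_e4, t_rise, v1, 0.0),
        (t_rise, t_e6, 0.0, p2),
        (t_e6, t_e8, p2, v2),
        (t_e8, t_end, v2, 0.0),
    ]


def _mb_segments(p: MBTemplateParams):
    t_fall = p.fall_dur * _MB_FALL_STRETCH
    return [
        (0.0, p.rise_dur, 0.0, p.beat_amplitude),
        (p.rise_dur, p.rise_dur + t_fall, p.beat_amplitude, 0.0),
    ]


def fp_feature_times(p: FPTemplateParams) -> dict:
    """Analytic E1–E8 times (s) relative to the beat onset (start of the rise)."""
    p.validate()
    p1 = _FP_FIRST_PEAK_FRAC * p.first_amplitude
    v1 = p1 - p.first_amplitude
    p2 = _FP_SECOND_PEAK_FRAC * p.second_amplitude
    t = {}
    t["E1"] = p.spike_rise_dur * _ramp_invert(0.10)
    t["E2"] = p.spike_rise_dur * _ramp_invert(0.50)
    t["E3"] = p.spike_rise_dur
    t["E4"] = t["E3"] + p.spike_fall_dur
    t["E6"] = t["E4"] + p.second_delay
    t["E8"] = t["E6"] + p.second_fall_dur
    t["E7"] = t["E6"] + p.second_fall_dur * _ramp_invert(0.50)
    # E5: 50% of the second rising edge (valley E4 up to peak E6)
    recovery = p.second_delay - p.second_rise_dur
    if p2 - v1 <= 0:
        t["E5"] = t["E4"] + p.second_delay / 2.0
    else:
        level = v1 + 0.5 * (p2 - v1)
        if level <= 0 and v1 < 0:
            frac = (level - v1) / (0.0 - v1)
            t["E5"] = t["E4"] + recovery * _ramp_invert(frac)
        else:
            frac = level / p2 if p2 > 0 else 0.5
            t["E5"] = t["E4"] + recovery + p.second_rise_dur * _ramp_invert(frac)
    return t


def fp_feature_values(p: FPTemplateParams) -> dict:
    """Template values (µV) at the E1–E8 feature points."""
    p1 = _FP_FIRST_PEAK_FRAC * p.first_amplitude
    v1 = p1 - p.first_amplitude
    p2 = _FP_SECOND_PEAK_FRAC * p.second_amplitude
    v2 = p2 - p.second_amplitude
    return {
        "E1": 0.1 * p1,
        "E2": 0.5 * p1,
        "E3": p1,
        "E4": v1,
        "E5": v1 + 0.5 * (p2 - v1),
        "E6": p2,
        "E7": 0.5 * (p2 + v2),
        "E8": v2,
    }


def mb_feature_times(p: MBTemplateParams) -> dict:
    """Analytic M1–M5 times (s) relative to the bump onset."""
    p.validate()
    t_fall = p.fall_dur * _MB_FALL_STRETCH
    return {
        "M1": p.rise_dur * _ramp_invert(0.10),
        "M2": p.rise_dur * _ramp_invert(0.50),
        "M3": p.rise_dur,
        "M4": p.rise_dur + t_fall * _ramp_invert(0.50),
        "M5": p.rise_dur + p.fall_dur,
    }


def make_fp_template(params: FPTemplateParams, fs: float) -> np.ndarray:
    """Sample one FP beat waveform at `fs` Hz (baseline 0 outside the beat)."""
    params.validate()
    if fs <= 0:
        raise InvalidParameterError("fs must be > 0")
    t = np.arange(0.0, params.envelope_dur + 1.0 / fs, 1.0 / fs)
    return _eval_segments(_fp_segments(params), t)


def make_mb_template(params: MBTemplateParams, fs: float) -> np.ndarray:
    """Sample one MB bump waveform at `fs` Hz (nonnegative, unimodal)."""
    params.validate()
    if fs <= 0:
        raise InvalidParameterError("fs must be > 0")
    t = np.arange(0.0, params.envelope_dur + 1.0 / fs, 1.0 / fs)
    return _eval_segments(_mb_segments(params), t)


# ---------------------------------------------------------------------------
# drug effects
# ---------------------------------------------------------------------------


def apply_drug_effect(
    profile: DrugEffectProfile,
    concentration: float,
    time_since_dose: Optional[float] = None,
) -> dict:
    """Multiplicative modifier per target at a given dose and time.

    factor = 1 + max_effect * c^n / (c^n + EC50^n) * (1 - exp(-t/tau)).
    ``time_since_dose=None`` means steady state (the onset term is 1).
    Targets the profile does not mention default to 1.
    """
    if concentration < 0:
        raise InvalidParameterError("concentration must be >= 0")
    if time_since_dose is not None and time_since_dose < 0:
        raise InvalidParameterError("time_since_dose must be >= 0")
    profile.validate()
    factors = {}
    for e in profile.effects:
        if concentration == 0.0:
            hill = 0.0
        else:
            cn = concentration**e.hill_n
            hill = cn / (cn + e.ec50**e.hill_n)
        if time_since_dose is None or math.isinf(time_since_dose):
            onset = 1.0
        else:
            onset = 1.0 - math.exp(-time_since_dose / e.onset_tau)
        factors[e.target] = 1.0 + e.max_effect * hill * onset
    return factors


def apply_profile_to_templates(
    fp: FPTemplateParams,
    mb: MBTemplateParams,
    base_rate: float,
    factors: dict,
):
    """Return (fp', mb', rate') with all modifier factors applied."""
    fp_kw: dict = {}
    mb_kw: dict = {}
    rate = base_rate * factors.get("rate", 1.0)
    fp_kw["first_amplitude"] = fp.first_amplitude * factors.get("fp_first_amplitude", 1.0)
    fp_kw["second_amplitude"] = fp.second_amplitude * factors.get("fp_second_amplitude", 1.0)
    mb_kw["beat_amplitude"] = mb.beat_amplitude * factors.get("mb_amplitude", 1.0)
    mb_kw["em_delay"] = mb.em_delay * factors.get("em_delay", 1.0)
    for target, fld in DURATION_TARGETS.items():
        f = factors.get(target, 1.0)
        if f == 1.0:
            continue
        if fld == "second_delay":
            # scale the whole second-wave complex so second_delay >= rise holds
            fp_kw["second_delay"] = fp.second_delay * f
            fp_kw["second_rise_dur"] = fp.second_rise_dur * f
        elif fld in ("rise_dur", "fall_dur"):
            mb_kw[fld] = getattr(mb, fld) * f
        else:
            fp_kw[fld] = getattr(fp, fld) * f
    return replace(fp, **fp_kw), replace(mb, **mb_kw), rate


PACKAGED_PROFILES = ("lidocaine", "isradipine")


def load_drug_profile(name_or_path: str) -> DrugEffectProfile:
    """Load a drug-effect profile from a packaged name or a JSON file path."""
    if name_or_path in PACKAGED_PROFILES:
        ref = resources.files("cardioems.profiles").joinpath(f"{name_or_path}.json")
        raw = json.loads(ref.read_text())
    else:
        with open(name_or_path) as fh:
            raw = json.load(fh)
    effects = tuple(
        DrugEffect(
            target=e["target"],
            max_effect=float(e["max_effect"]),
            ec50=float(e["ec50"]),
            hill_n=float(e.get("hill_n", 2.0)),
            onset_tau=float(e.get("onset_tau", 5.0)),
        )
        for e in raw["effects"]
    )
    profile = DrugEffectProfile(
        drug_name=raw["drug_name"],
        effects=effects,
        concentration_unit=raw.get("concentration_unit", "uM"),
        doses=tuple(float(d) for d in raw.get("doses", ())),
    )
    profile.validate()
    return profile


# ---------------------------------------------------------------------------
# recording simulation
# ---------------------------------------------------------------------------


def _beat_onsets(rng, duration, rate_bpm, cv, envelope_dur, first_onset=0.35):
    """Gamma-renewal beat onset times that leave room for a full waveform."""
    mean_ibi = 60.0 / rate_bpm
    onsets = []
    t = first_onset
    limit = duration - envelope_dur
    while t <= limit:
        onsets.append(t)
        if cv > 0:
            shape = 1.0 / cv**2
            t += rng.gamma(shape, mean_ibi / shape)
        else:
            t += mean_ibi
    return np.asarray(onsets)


def _render(segments, onsets, fs, n):
    trace = np.zeros(n)
    if not segments:
        return trace
    seg_end = max(t1 for (_, t1, _, _) in segments)
    for onset in onsets:
        i0 = max(0, int(math.floor(onset * fs)))
        i1 = min(n, int(math.ceil((onset + seg_end) * fs)) + 1)
        if i1 <= i0:
            continue
        t_local = np.arange(i0, i1) / fs - onset
        trace[i0:i1] += _eval_segments(segments, t_local)
    return trace


def simulate_recording(config: SimulationConfig, channel: int = 0) -> Recording:
    """Simulate one channel's synchronized FP/MB epoch with ground truth.

    The random stream is derived deterministically from
    ``(config.seed, channel)``; identical configs give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, channel])

    if config.drug is not None:
        factors = apply_drug_effect(
            config.drug, config.concentration, config.time_since_dose
        )
    else:
        factors = {}
    fp_p, mb_p, rate = apply_profile_to_templates(
        config.fp_template, config.mb_template, config.base_rate, factors
    )
    fp_p.validate()
    mb_p.validate()

    # full footprint of one beat: FP envelope and the later-ending MB bump
    mb_offset = fp_p.spike_rise_dur + mb_p.em_delay  # beat onset -> MB onset
    footprint = max(fp_p.envelope_dur, mb_offset + mb_p.envelope_dur) + 0.05

    onsets = _beat_onsets(
        rng, config.duration, rate, config.noise.beat_jitter_cv, footprint
    )

    n_fp = int(round(config.duration * config.fs_fp))
    n_mb = int(round(config.duration * config.fs_mb))
    fp = _render(_fp_segments(fp_p), onsets, config.fs_fp, n_fp)
    mb = _render(_mb_segments(mb_p), onsets + mb_offset, config.fs_mb, n_mb)

    noise = config.noise
    if noise.drift_amp > 0 and noise.drift_period > 0:
        w = 2.0 * np.pi / noise.drift_period
        phi_fp, phi_mb = rng.uniform(0.0, 2.0 * np.pi, size=2)
        fp += noise.drift_amp * fp_p.first_amplitude * np.sin(
            w * np.arange(n_fp) / config.fs_fp + phi_fp
        )
        mb += noise.drift_amp * mb_p.beat_amplitude * np.sin(
            w * np.arange(n_mb) / config.fs_mb + phi_mb
        )
    if noise.fp_white_sd > 0:
        fp += rng.normal(0.0, noise.fp_white_sd, n_fp)
    if noise.mb_white_sd > 0:
        mb += rng.normal(0.0, noise.mb_white_sd, n_mb)

    e_rel = fp_feature_times(fp_p)
    m_rel = mb_feature_times(mb_p)
    ground_truth = {
        "beat_times": onsets.tolist(),
        "fp_points": [
            {k: onset + v for k, v in e_rel.items()} for onset in onsets
        ],
        "mb_points": [
            {k: onset + mb_offset + v for k, v in m_rel.items()} for onset in onsets
        ],
        "rate_bpm": rate,
        "fp_template": fp_p.__dict__.copy(),
        "mb_template": mb_p.__dict__.copy(),
    }
    metadata = {
        "channel": channel,
        "condition": "control" if config.drug is None else config.drug.drug_name,
        "drug": None if config.drug is None else config.drug.drug_name,
        "concentration": config.concentration,
        "concentration_unit": (
            config.drug.concentration_unit if config.drug is not None else ""
        ),
        "time_since_dose_min": config.time_since_dose,
    }
    return Recording(
        fp=fp,
        mb=mb,
        fs_fp=config.fs_fp,
        fs_mb=config.fs_mb,
        metadata=metadata,
        ground_truth=ground_truth,
    )


def simulate_study(
    config: SimulationConfig,
    profile: Optional[DrugEffectProfile] = None,
    concentrations: Sequence[float] = (0.0,),
    timepoints_min: Sequence[Optional[float]] = (None,),
    channel_cv: float = 0.03,
) -> list[Recording]:
    """Simulate a multi-channel, multi-epoch study.

    Without a drug profile every (concentration 0, timepoint) pair is a
    vehicle epoch labelled with its timepoint (a stability study).  With a
    profile, one pre-dose baseline epoch (labelled time 0) is generated per
    channel, plus one epoch per (non-zero concentration, timepoint) pair.
    Each channel carries a small fixed multiplicative offset on amplitudes
    and rate (CV ``channel_cv``), constant across its epochs, emulating
    well-to-well biological variability; per-epoch random streams derive
    deterministically from the master seed, channel and epoch index.
    ``timepoints_min`` of ``None`` mean steady state.
    """
    config.validate()
    if profile is None:
        grid = [(0.0, tp) for tp in timepoints_min]
    else:
        base_tp = 0.0 if any(tp is not None for tp in timepoints_min) else None
        grid = [(0.0, base_tp)] + [
            (c, tp) for c in concentrations if c > 0 for tp in timepoints_min
        ]
    recordings = []
    seed = int(config.seed) & 0x7FFFFFFF
    for ch in range(config.n_channels):
        ch_rng = np.random.default_rng([seed, ch, 9999])
        if channel_cv > 0:
            amp_f = float(np.exp(ch_rng.normal(0.0, channel_cv)))
            rate_f = float(np.exp(ch_rng.normal(0.0, channel_cv)))
        else:
            amp_f, rate_f = 1.0, 1.0
        fp_t = replace(
            config.fp_template,
            first_amplitude=config.fp_template.first_amplitude * amp_f,
            second_amplitude=config.fp_template.second_amplitude * amp_f,
        )
        mb_t = replace(
            config.mb_template,
            beat_amplitude=config.mb_template.beat_amplitude * amp_f,
        )
        for epoch, (conc, tp) in enumerate(grid):
            drug = profile if conc > 0 else None
            cfg = replace(
                config,
                fp_template=fp_t,
                mb_template=mb_t,
                base_rate=config.base_rate * rate_f,
                drug=drug,
                concentration=conc if drug is not None else 0.0,
                time_since_dose=tp if drug is not None else None,
                seed=(seed + 1_000_003 * epoch + 7) & 0x7FFFFFFF,
                n_channels=1,
            )
            rec = simulate_recording(cfg, channel=ch)
            rec.metadata["time_min"] = tp
            rec.metadata["epoch"] = epoch
            recordings.append(rec)
    return recordings


# ---------------------------------------------------------------------------
# carrier modulation (exercises detect.demodulate_impedance)
# ---------------------------------------------------------------------------


def modulate_carrier(
    mb_trace: np.ndarray,
    fs_mb: float,
    carrier_freq: float = 10_000.0,
    fs_out: float = 40_000.0,
    offset: float = 50.0,
) -> np.ndarray:
    """Amplitude-modulate the MB trace onto an impedance-drive carrier.

    The output is ``(offset + mb) * sin(2*pi*f_c*t)`` sampled at ``fs_out``;
    the envelope (offset + mb_trace) is what a demodulator must recover.
    """
    if fs_out < 4.0 * carrier_freq:
        raise InvalidParameterError(
            f"fs_out={fs_out} too low for carrier {carrier_freq} Hz (need >= 4x)"
        )
    mb_trace = np.asarray(mb_trace, dtype=float)
    dur = len(mb_trace) / fs_mb
    t = np.arange(0.0, dur, 1.0 / fs_out)
    env = offset + np.interp(t, np.arange(len(mb_trace)) / fs_mb, mb_trace)
    return env * np.sin(2.0 * np.pi * carrier_freq * t)
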
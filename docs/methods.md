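# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `cardioems`. Notation: FP = firing potential (extracellular
field potential, µV), MB = mechanical beating (impedance fluctuation, Ω),
E1–E8 / M1–M5 = the per-beat feature points defined in the README.

## Signal model (synth)

### Waveform templates

Both templates are piecewise **half-cosine (raised-cosine) ramps**: between
consecutive knots the signal moves as `v0 + (v1−v0)(1−cos(πx))/2`. Every
segment is monotone, the full waveform is C¹, and every fractional
edge-crossing time has a closed form — which is what lets the simulator
emit exact ground-truth feature-point times for every beat it renders, and
lets the extraction tests use the generator as their oracle.

The FP beat consists of a fast biphasic spike and a delayed slower second
wave. Knots, with defaults in parentheses:

| segment | span | role |
|---|---|---|
| rise | 0 → `spike_rise_dur` (10 ms) | onset → first peak E3 (70% of the first amplitude above baseline) |
| fall, steep | first 25% of `spike_fall_dur` (45 ms) | E3 → knee at 65% of the first amplitude below the peak |
| fall, slow | remainder of `spike_fall_dur` | knee → valley E4 (−30% of the first amplitude) |
| recovery | `second_delay − second_rise_dur` | E4 → baseline |
| second rise | `second_rise_dur` (80 ms) | baseline → second peak E6 (85% of the second amplitude) |
| second fall | `second_fall_dur` (55 ms) | E6 → second valley E8 (−15% of the second amplitude) |
| tail | 0.6 × `second_fall_dur` | E8 → baseline |

The biphasic fall matters: with a single slow cosine the waveform's
curvature just after the peak is nearly zero, and under noise the apparent
crest wanders several milliseconds; the steep initial drop gives the peak
comparable curvature on both flanks, making peak timing well posed.

The MB bump is unimodal: a cosine rise over `rise_dur` (300 ms) to the peak
M3 (= `beat_amplitude`, 20 Ω), then a cosine decay scaled so that exactly
90% of the amplitude is lost `fall_dur` (250 ms) after the peak (the full
cosine fall is `fall_dur·π/arccos(−0.8) ≈ 1.258·fall_dur`). The bump starts
`em_delay` (90 ms) after the FP fast-spike peak — the electromechanical
latency of excitation–contraction coupling.

Default amplitudes follow the optimized-culture values the platform reports
(first FP amplitude 428 µV, beat rate 60/min); the 120 µV second amplitude,
20 Ω beating amplitude and all default durations are this package's own
choices of a physiologically plausible operating point, tuned so that every
one of the 16 FP–MB durations is at least ~45 ms at baseline. That floor is
deliberate: the assessment metric is *percent* change, and a near-zero
baseline duration would amplify pure measurement noise into spurious
instability (an early default that put E6 within 7 ms of M2 showed exactly
this failure).

### Rhythm, noise and channels

Beat onsets form a **gamma renewal process** with mean interval
`60/base_rate` and coefficient of variation `beat_jitter_cv` (default
0.02); cv = 0 degenerates to a metronome. Beats are placed only where the
full beat footprint fits inside the epoch, so a 60 s epoch at 60/min holds
59–60 beats.

The noise model adds per-sample white Gaussian noise (`fp_white_sd` 10 µV,
`mb_white_sd` 0.4 Ω = 2% of the beat amplitude), and a sinusoidal baseline
drift of amplitude `drift_amp` (2%) × signal amplitude with period
`drift_period` (30 s) and a random phase per trace. In multi-channel
studies each channel also carries a fixed log-normal offset (CV 3%) on its
amplitudes and rate, constant across its epochs — emulating well-to-well
biological variability so that across-channel SDs are meaningful, while the
paired (per-channel baseline) design cancels it from percent changes.

Seeding: one master seed; each (channel, epoch) stream is derived
deterministically from it, so identical configurations are bit-identical.

### Drug effects

A drug profile is a list of Hill-type entries, each targeting the beat
rate, an amplitude, a named template duration (e.g. `E6E8` → the second
fall), or the electromechanical delay:

    factor(c, t) = 1 + max_effect · cⁿ/(cⁿ + EC50ⁿ) · (1 − e^(−t/τ))

with `time_since_dose = None` meaning steady state. Factors multiply the
corresponding template parameter; `factor(0) = 1` identically. The `E4E6`
duration target scales both `second_delay` and `second_rise_dur` so the
template stays valid.

**Packaged profiles.** Published drug assessments report endpoint percent
changes, not dose–response fits, so the Hill parameters here are package
choices: EC50 = the middle of the published 5-point dose grid (11.1 µM
lidocaine, 37.4 nM isradipine), Hill n = 2, onset τ = 5 min (matching the
5-minute recording cadence of such assays). Each `max_effect` is the
published endpoint divided by the Hill fraction at the top printed dose, so
the modifier at that dose equals the endpoint exactly. For lidocaine the
published top-dose endpoints are −57.58% rate and prolongations of +26.49%
(E1–M2) and +33.66% (E4–M2); both duration effects are injected through a
single em_delay endpoint of +72.93%, which with the default templates gives
E4–M2 +33.66% exactly and E1–M2 +26.47% (the two printed numbers pin the
template ratio (E1–M2)/(E4–M2) to 1.2707; the defaults give 1.2715, a
0.02-percentage-point discrepancy). The amplitude reductions (FP first
−35%, FP second −30%, MB −40%) and the isradipine rate increase (+30%) have
published directions but no printed magnitudes; the values are qualitative
choices. Isradipine's −95% MB amplitude at 333 nM deliberately drives the
contraction bump below the noise floor, reproducing the high-dose MB
dropout such assays report.

A published statement that the lidocaine firing rate *increased* directly
contradicts the quantified 57.58% decrease two sentences earlier; the
packaged profile follows the quantified decrease.

## Detection (detect)

FP traces are low-pass filtered at 3 kHz (4th-order Butterworth,
forward–backward so zero phase — feature-point timing must not be biased by
filter lag). MB carrier traces are demodulated by complex mixing at the
carrier frequency followed by zero-phase low-pass filtering (a digital
lock-in, equal to the short-time Fourier magnitude at the carrier bin),
referenced to the envelope median and resampled to `fs_mb`. With the
default ~60% bump duty cycle the median sits ~1.5% of the beat amplitude
above the true baseline; downstream extraction re-references every beat to
its local baseline, so this offset is harmless.

The **adaptive threshold** is a sliding median + k × 1.4826·MAD, computed
on half-overlapping windows and linearly interpolated to every sample. The
median tracks drift; the MAD estimates noise spread robustly against the
beats themselves; 1.4826 scales MAD to a Gaussian SD, so on pure noise the
threshold sits at k·σ. Defaults: k = 5, window 2 s for FP; k = 3, window
5 s for MB (the bump's high duty cycle inflates the MAD, so a lower k
compensates). Thresholding on median/MAD makes detection exactly invariant
to amplitude rescaling.

Suprathreshold samples are grouped into excursions; runs separated by less
than half the refractory period merge (noise dipping briefly below
threshold must not split a beat). Each excursion is anchored at its
extremum, located on a ~3 ms moving-average copy and then refined to the
raw extremum within half a smoothing window (the average alone drags the
crest toward the slower flank). Anchors closer than the refractory period
to the last accepted anchor are discarded — this is also what suppresses
the FP second wave, which crests ~0.29 s after the fast spike and would
otherwise double-count; the FP refractory is therefore 0.35 s (resolving
rates to ~170/min), MB 0.30 s. Polarity `auto` compares the magnitudes of
the global extrema after median removal and flips negative-dominant traces,
recording the flip on the event.

Extraction windows around each anchor extend up to 0.25/0.60 s (FP) and
0.50/0.75 s (MB) before/after, but never past 45% of the gap to the
previous anchor or 80% (FP) / 70% (MB) of the gap to the next — the MB cap
keeps the next bump's rise out of the post-beat baseline window.

## Feature extraction (features)

Per beat, the window is Savitzky–Golay smoothed (order 2; 1.5 ms FP, 15 ms
MB) and the noise SD estimated from robust first differences. Extrema are
located on the smoothed trace and refined to the raw extremum within half a
smoothing window (removing the asymmetric-curvature bias; on noise-free
input every point lands within a fraction of a sample of ground truth).

* E3 / M3: window maximum near the detector anchor.
* Pre-onset baseline: median of a 50 ms (FP) / 200 ms (MB) window ending at
  the rising-edge onset, where the onset is the last crossing of
  baseline + 5% amplitude before the peak; baseline and onset are iterated
  once.
* E4: global minimum after E3 (the spike valley is always deeper than the
  second wave's terminal undershoot); it must undercut the baseline by
  max(3σ, 2% of amplitude) or the beat reports `no_valley`.
* E6: global maximum after E4; it must clear baseline by max(5σ, 10⁻⁴ µV)
  or E5–E8 report `second_wave_absent`.
* E8: first sufficiently prominent minimum after E6; when the second wave
  has no distinct valley, the fallback is the *first* crossing of 90%
  return toward baseline (a return detector, so the earliest crossing is
  the right boundary under noise).
* E1/E2, E5, E7, M1/M2, M4/M5: fractional edge crossings, linearly
  interpolated. Rising fractions are of (peak − pre-onset baseline), taking
  the first crossing; falling fractions are of (peak − post-beat baseline),
  taking the last crossing; ties break to the earliest time. The MB
  post-beat baseline is the median of the last quarter of the window.
* A MB bump whose amplitude does not clear 6 noise SDs reports all five
  points missing (`bump_below_noise`) — high-dose Ca²⁺-block dropout
  degrades to missing data, never to fabricated values.

FP and MB beats are paired greedily: each FP beat takes the earliest
unpaired MB beat whose peak follows its own by 0–0.5 s (excitation precedes
contraction; the default lag ceiling accommodates the baseline latency of
em_delay + rise ≈ 0.39 s plus drug prolongation). Intervals and rates are
peak-to-peak (E3→E3, M3→M3) between consecutive beats — peaks are the most
jitter-robust anchors. Amplitudes: first = E3−E4 and second = E6−E8
peak-to-valley (standard for extracellular potentials; "second amplitude"
could alternatively be read as E6 − baseline, peak-to-valley was chosen),
beating = M3 − baseline. Missing points propagate to missing parameters.

## Assessment (assess)

The effect metric is signed percent change, `100·(treated −
baseline)/baseline`, with the pre-dose epoch of the same channel as the
paired baseline. Channel means are aggregated before percent change (the
table value is the percent change of across-channel means); the reported
spread is the SD of per-channel paired percent changes. A zero or missing
baseline yields a missing value with a reason code.

* `fluctuation_metric`: max |percent change| over a parameter set and over
  post-baseline timepoints — the vehicle-control stability statistic.
  All-missing parameters are excluded and listed.
* `dose_response_table` / `time_course_table`: parameters × ordered doses
  (or timepoints), each cell mean ± SD as above; a monotonicity flag per
  parameter from the sign of a perfect Spearman correlation over the grid
  (no p-values — the assessment is descriptive).
* `heatmap_matrix`: the fingerprint matrix under `percent` (default) or
  row-wise `zscore` normalization; published figures do not state their
  normalization, so percent change — directly interpretable — is the
  default. Missing cells stay missing; zero-variance rows under zscore
  become all-missing and are flagged.
* `radar_data`: per timepoint, min–max normalization of each parameter
  across the dose series onto [0, 1]; a constant parameter pins at 0.5.

## Pipeline, I/O, determinism

All artifacts are flat delimited text (CSV/TSV, JSON sidecars) written with
17-significant-digit floats for recordings (read back with round-trip float
parsing, so write→read is bit-identical) and 10 for derived tables.
`run_pipeline` drives a whole study from one JSON config and is
byte-identical across reruns at fixed seed; figures (heat map, radar) are
rendered with matplotlib. The CLI (`ems simulate|detect|extract|assess|run`)
is a thin layer over these functions.

## Problem sizes

The test suite and acceptance script use the study geometry the package
documents: 4 channels × 60 s epochs at 0/5/10/15 min for stability
(≈ 940 beats), 4 channels × (baseline + top dose) for drug recovery, and
30 s epochs for the 5-dose and time-course suites. These sizes put the
standard error of every epoch-mean parameter well below the published
stability bounds while keeping a full run in tens of seconds.

## What the synthetic data does and does not show

The generator reproduces the *structure* of EMS data — coupled biphasic FP
and unimodal MB morphology, electromechanical latency, renewal-process
rhythm, drift and measurement noise, Hill-shaped dose responses with
exponential onset, high-dose MB dropout — with exact ground truth. It does
not reproduce: real extracellular spike shape diversity (multi-phasic
spikes, polarity mixtures within one electrode), rate-dependent restitution
of contraction duration (templates are rate-independent; the detection test
at 120/min shortens the bump explicitly), arrhythmic events (ectopy,
alternans, fibrillation-like states), electrode aging or motion artifacts,
and any pharmacology beyond multiplicative template scaling. Passing tests
therefore demonstrate that the *pipeline* is correct and unbiased on
signals of this class — not that the packaged drug profiles predict real
cellular pharmacology.

## Known limitations

* The adaptive threshold assumes beats occupy a minority-to-moderate duty
  cycle; at duty cycles near 1 (very fast rates with the default slow MB
  bump) the MAD inflates and the bump merges into the baseline estimate.
* Feature timing precision is limited by waveform curvature at the peaks;
  broad low crests (the FP second wave, ~100 µV over ~130 ms) carry
  several-millisecond per-beat jitter under the default noise, which
  averages out in epoch means but dominates the FP–MB fluctuation budget.
* The E8 fallback (90% return) differs from a true second valley when both
  exist under heavy noise; the choice is deterministic per beat, and biases
  cancel in paired percent changes.
* Pairing is greedy nearest-forward; pathological rhythms (missed FP with
  preserved MB) can mispair at most one beat per gap.
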
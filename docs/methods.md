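# Methods

## Scope and model

The package implements the quantitative readouts of a mouse
NMDAR-hypofunction study design in which GABAergic-neuron *Grin1*
deletion produces a dual gamma-band abnormality — reduced 40-Hz
stimulus-evoked power and phase locking with elevated resting gamma
power — together with reduced spike-pair synchrony, reduced synchronous
GABA release onto pyramidal-cell pairs, and behavioral deficits, all of
which (except the N1 onset potential) are reversed by GSK3β inhibition
or knockdown. No animal data ship with the package; a synthetic-data
module generates every modality with the statistical structure the
analyses assume, and condition presets encode the group contrasts.

## Synthetic LFP generator

Each recording channel is simulated as 50 click-train trials (sampling
rate 1 kHz, window −0.5 to +1.0 s around onset, stimulus occupying
[0, 0.5) s), one 200-ms mid-ISI spontaneous segment per trial, and a
12-s pre-stimulus record. A trial is the sum of four components:

* **1/f background.** Gaussian noise spectrally shaped to
  PSD = c / max(f, 1 Hz), zero at DC. The PSD is anchored to absolute
  frequency and normalized analytically (not per realization), so
  segments of different lengths carry identical gamma-band power
  density; normalizing each segment's sample variance instead would
  give 200-ms segments ~40 % more 40-Hz power than 1.5-s trials and
  bias the spontaneous subtraction.
* **Ongoing gamma.** A random-frequency (uniform 35–44 Hz),
  random-phase sinusoid per segment, amplitude `baseline_gamma_amp`,
  present in trials, mid-ISI segments and the pre-stimulus record alike.
* **Entrained 40-Hz component** during the stimulus, amplitude
  `evoked_amp`, per-trial phase ~ von Mises(0, `phase_kappa`); κ = 0 is
  uniform phase (no locking), κ → ∞ perfect locking. A single
  concentration parameter maps directly onto intertrial coherence.
* **N1**: a negative Gaussian deflection (FWHM 25 ms) centered 40 ms
  after onset, depth `n1_amp`.

Everything is driven by one `numpy` Generator per call and is
bit-reproducible from (preset, seed).

What the generator does *not* emulate: recording artifacts, non-
stationary arousal drift, harmonic structure of real ASSRs, spatial
correlation across channels (channels are independent draws), and any
mechanistic (conductance-based) account of gamma generation. Passing
tests therefore demonstrate correctness of the estimators and the
recoverability of the programmed contrasts, not properties of real
cortical data.

## ASSR analysis

* **Normalization.** All segments are z-scored by the mean/SD of the
  channel's pre-stimulus record — the only epoch guaranteed free of
  stimulus-driven activity. Idempotent up to float tolerance; a flat
  record is an error.
* **Time-frequency decomposition.** Power path: complex Morlet wavelets,
  7 cycles, 1-Hz steps, implemented as FFT convolution with kernels
  normalized so a sinusoid of amplitude A yields power A² (squared
  amplitude envelope). Note the constant-Q consequence: broadband-noise
  wavelet power grows ∝ f across frequencies; flatness checks against a
  flat PSD are therefore performed on the STFT path, whose fixed Hann
  window has constant bandwidth. Phase path: 200-ms Hann STFT, 60 %
  overlap, zero-padded to a 1-Hz grid, 0–100 Hz. The STFT window length
  is chosen to match the 200-ms spontaneous segment length.
* **Band power of short segments.** The 200-ms analysis window and the
  200-ms mid-ISI/baseline segments are excised, symmetrically padded by
  up to their own length, decomposed, and averaged over the unpadded
  span. Excising the stimulus window (rather than decomposing the whole
  trial) makes the stimulus-window estimator *identical in form* to the
  spontaneous-reference estimator, so their difference is unbiased when
  no evoked component is present.
* **Evoked vs total.** Evoked power decomposes the trial-averaged
  trace; total power averages per-trial power. Both subtract the same
  spontaneous reference — the mean per-segment mid-ISI band power — in
  the z-scored power domain. Using one common subtrahend preserves the
  exact inequality evoked ≤ total (power of an average never exceeds
  average power, by convexity). A consequence worth knowing: because
  trial averaging suppresses the background by 1/n while the subtracted
  reference is full single-segment background power, evoked values for
  weak, poorly-locked signals are driven toward zero and can be
  negative; this is the intended reading of the power-domain
  subtraction. A `spontaneous="trace"` flag exposes the alternative
  time-domain variant (mid-ISI segment subtracted trial-wise before
  decomposition), for which the same inequality holds.
* **Baseline power** splits the final 10 s of the pre-stimulus record
  into exactly 50 contiguous 200-ms segments and averages their band
  power.
* **ITC** is the resultant length of per-trial STFT phases. Zero-power
  bins have undefined phase and are excluded per-bin and counted. A
  single trial gives ITC 1 by definition; uniform phases give
  E[ITC] = √(π/4n).
* **N1** is the magnitude of the minimum of the trial-averaged trace in
  a 10–100 ms post-onset search window ("first prominent negative
  peak" needs an operational window); if the minimum is not a strict
  interior local minimum the value is still returned, flagged. The
  averaged trace is deliberately not low-pass filtered, so the
  phase-locked 40-Hz ripple contributes a small condition-dependent
  bias to the N1 estimate; at the preset signal-to-noise levels this
  never flips the N1 group ordering.
* **Aggregation**: per-animal design averages channels within subject;
  per-channel passes through. Both must — and on preset data do — agree
  in contrast sign.

## Spike-pair synchrony

Synchrony is the zero-lag Pearson correlation of spike counts in 5-ms
half-open bins (bin width is a parameter; 5 ms resolves near-coincident
firing at usable count variance), with a correlogram over ±100 ms lags
and a peak-within-±10-ms option. The null shuffles one train's
inter-spike intervals — preserving its spike count and ISI multiset
exactly — and reports the null mean/SD and the empirical quantile of
the observed r. A zero-variance count vector yields NaN (flagged), not
a silent 0.

The generator draws a shared Poisson process at rate `p·λ` plus per-cell
independent processes at `(1 − p)·λ`, so each train's marginal rate is λ
and — since binned counts share exactly the common component's
variance — the expected zero-lag Pearson r equals `p` for any bin width.
This closed form is the oracle for the correlation estimator.

## Synchronous sIPSCs

Events are detected in rectified (positive-deflection) current traces
by block-median baseline subtraction (100-ms blocks, linearly
interpolated), light Gaussian smoothing (0.3 ms), and peak picking by
*prominence* (half the amplitude threshold) — prominence rather than
height rejects noise bumps riding the decay tail of a preceding large
event — followed by a strict amplitude rule: events must exceed 5 pA
(an exactly-5.0 pA event is excluded). Detection on rendered traces
recovers ≥ 95 % of ≥ 10-pA events within ±2 ms at 1 pA noise.

Coincidence is per-event with a closed ±10-ms interval; one event may
partner many (the simplest reading with a closed-form Poisson null:
an event is synchronous with probability `[s + (r − s)(1 − e^{−2wr})]/r`
for total rate r, shared rate s, half-window w). The reported
percentage pools both cells' events, making it symmetric and bounded;
per-cell percentages are also returned. Shared events are jittered
±3 ms independently per cell, so their relative offset (≤ 6 ms) always
falls inside the window.

The rendering kernel is a difference of exponentials (rise 1 ms, decay
10 ms) normalized to unit peak; amplitudes are log-normal (median
20 pA, σ = 0.5) truncated above 5 pA.

## Behavior and fluorescence

Y-maze sessions simulate three policies: `random` (uniform over the two
non-current arms), `alternating` (always the least recently visited
arm) and `lapse(ε)` mixing the two. The alternation index scores
overlapping triplets of entries containing three distinct arms — the
convention under which the random policy scores exactly 50 % in
expectation (each new entry matches the arm two steps back with
probability 1/2, independently). %PPI uses per-intensity trial means;
pulse-alone amplitudes are log-normal with a mean that is identical
across presets, because the startle reflex itself is unaffected by
condition. CTCF uses the standard formula (integrated density − area ×
mean background; the protocol literature does not restate it);
normalized fluorescence divides by the reference-group mean CTCF so the
reference group averages exactly 100 %.

## Presets and the virtual experiment

All preset numbers live in one table (`presets.py`). The sIPSC rates
are the printed group statistics' Poisson equivalents (e.g. total
3.493 Hz ⇒ mean IEI 286 ms; shared 0.645 Hz ⇒ ~24 % synchronous
events). LFP amplitudes, phase concentrations, spike shared fractions,
lapse rates and PPI attenuations are calibrated — once — so the
analysis round trip reproduces the direction and rough magnitude of
every published group contrast; the source figures report those values
only as z-scored group data, so no printed number is targeted. The
GSK3β-inhibited/knockdown presets equal control in every field except
the N1 depth, which stays at the mutant level; the GSK3α-inhibited
preset equals the mutant (that manipulation reverses nothing).

`run_experiment` simulates 4 condition groups × 5 animals × 3 channels
× 50 trials (matching the 15-channels-per-group design), 15 spike pairs
(120 s each), the published numbers of sIPSC pairs (300 s each) and 10
behavioral subjects per group, evaluates all contrasts, and writes
CSV/JSON/PNG outputs. Problem sizes are chosen so a full run completes
in a few seconds while keeping every group mean's sampling error well
inside the programmed effect sizes. All child seeds derive
deterministically from the single config seed via `SeedSequence`
spawning; reruns are byte-identical. A *restored* readout is one whose
recovery fraction `(treated − mutant)/(control − mutant)` exceeds 0.5
(overshoot beyond control counts as restored); N1 must stay below 0.5.

## Numerical choices and degenerate inputs

* Morlet kernels extend ±5σ; band power averages the 1-Hz grid
  35–44 Hz inclusive.
* Symmetric padding (not reflection) allows pad length equal to segment
  length.
* Binning drops spikes exactly at t = duration (half-open bins);
  ISI-shuffling requires ≥ 3 spikes; shuffle nulls require ≥ 20 draws.
* Empty event trains give 0 % synchrony with a warning, not an error;
  an all-flat current trace gives an empty detection result.
* von Mises sampling special-cases κ = 0 (uniform) and κ = ∞ (constant).
* Detected event times are kernel peak times; the event-to-peak delay
  `log(decay/rise)·decay·rise/(decay − rise)` (≈ 2.6 ms at the default
  kinetics) cancels in pair-wise coincidence because both cells shift
  equally.

## Known limitations

* The Morlet amplitude convention (sinusoid A ⇒ power A²) differs by 2×
  from mean-square power; only ratios and contrasts are interpreted.
* Evoked/total power estimates inherit a small downward smearing near
  the stimulus offset from the wavelet's temporal support.
* The detector is tuned for sparse (< ~5 Hz) sIPSC trains; heavily
  overlapping events are merged within the 2-ms separation limit.
* Group-level inferential statistics (ANOVA etc.) are intentionally out
  of scope; the pipeline reports descriptive aggregation and sign
  checks only.
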
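# Methods

This note records the models, conventions and numerical choices behind
swdkit, in the order data flows through the package.

## Session timeline

Session time is in seconds with the agonist/vehicle injection at t = 0.
The standard protocol is a 40-min control period (epochs -2, -1) and a 2-h
treatment period (epochs 0..5), all on a 20-min grid; an optional
antagonist injection sits at -600 s.  Every interval in the package —
events, epochs, masks — is half-open `[start, end)`, which makes epoch
bookkeeping exact (no sample belongs to two epochs) and rasterization
reversible.  Event times are stored at 1 ms resolution, matching the
1 kHz native acquisition rate the format targets.

## Synthetic GAERS sessions

The generator is phenomenological: it reproduces the statistical structure
a detector and spectral pipeline care about, not thalamocortical
biophysics.

**Background.** Gaussian noise shaped to a 1/f power spectrum above 1 Hz
(flat below), scaled to a 50 uV broadband SD — the scale is arbitrary
since detection thresholds are baseline-relative.  Non-REM bouts are
scheduled deterministically (one 3-min bout per 20-min epoch at minute
14), with 1.5x extra delta-band noise and 12 Hz, 0.8-s spindle bursts at
3 background SDs every 8 s.  Keeping the same within-epoch sleep phase in
every epoch makes state scheduling cancel exactly out of all
control-normalized metrics.  Movement artifacts are 0.4-s broadband
transients at 10 SDs, Poisson at 0.2/min in wake, kept clear of seizures.

**Seizure process.** Starts follow a Poisson process at 0.75/min
(a realistic GAERS rate: with 16-s seizures it yields roughly 20% of
wake time in seizure), gated off during sleep bouts and thinned by a
non-paralyzable dead time equal to the ongoing seizure plus a 5-s
refractory period.  Durations are gamma distributed, moment-matched to
mean 16.1 s and SD 14.3 s (shape 1.27, scale 12.7 s), and truncated below
1 s *by resampling* — clipping would pile a point mass exactly on the
detector's 1-s duration filter and make every downstream count a
razor's edge.

**SWD morphology.** One cycle is a periodic von-Mises-shaped spike
(FWHM 15% of the cycle, 400 uV = 8 background SDs) riding on a 100 uV
(2.4 SD) cosine wave with weak 2f/3f harmonics, raised-cosine
amplitude-ramped over 0.2 s at onset and offset.  The spike is the only
supra-threshold element per cycle at the default 6 SD threshold, so one
cycle yields one detected peak and the time-domain instantaneous frequency
equals the cycle frequency.  Cycle frequency defaults to 6.90 Hz.

**Drug-effect model.** All effects are zero before injection.  Rate,
duration and band-amplitude multipliers ramp linearly over 300 s and then
hold (an optional exponential washout exists but no shipped preset uses
it).  The cycle-frequency shift steps in at t = 0: arm-level peak
frequencies are measured on whatever treatment seizures occur, and in
strongly suppressive arms those cluster immediately after injection, so a
step is the parametrization whose expected measured frequency equals the
configured one.

**Between-animal heterogeneity.** Per animal: lognormal baseline rate
(log-SD 0.2), lognormal duration scale (log-SD 0.15), normal cycle
frequency (SD 0.10 Hz, plus 0.25 Hz per-event jitter), and a shared
drug-"exposure" draw that perturbs every effect multiplier on the log
scale with spread proportional to the effect size and the mean preserved
(E[m_animal] = m), so cohort means stay anchored while group SEMs are
biologically meaningful rather than degenerate.  Real data contain
additional structure the generator does not emulate — circadian drift,
vigilance-dependent seizure clustering, electrode artifacts correlated
with movement, inter-channel differences — so passing recovery tests here
demonstrates pipeline correctness, not field readiness for any particular
recording system.

**Presets.** Each named arm stores the published overall percent changes
it is anchored on.  Because total time, count and mean length are linked
(time = count x length) but the published overalls average over
time-varying effects, each preset anchors the two quantities its
downstream analyses use.  The solver inverts the full measurement
expectation: quasi-static renewal rate nu(t) = lambda(t) / (1 + lambda(t)
(Ed(t) + r)) for the dead-time-thinned process, truncated-gamma duration
moments, the onset ramp, sleep gating, and the epoch-edge time spill
(nu E[d^2]/2 renewal residual) that the epoch-splitting total-time metric
sees.  Band-amplitude factors solve a quadratic so the epoch-averaged
expected power ratio (ramp included) equals the published ratio.
Frequency presets store the absolute arm value; the shift is taken
against the 6.90 Hz default.

## Detection

The stage order — filter, baseline, crossings, grouping, amalgamation,
duration filter, frequency criterion — is fixed and regression-tested
(swapping amalgamation and the duration filter demonstrably changes
results on crafted fixtures).  Numerical conventions:

- DC remove is subtraction of an exponential running mean (RC high-pass,
  cutoff ~1.6 Hz at tau = 0.1 s); baseline statistics are computed on the
  same filtered signal the thresholds are applied to.
- Crossings of either polarity within 75 ms of the previously kept peak
  collapse into it.  The window must swallow the wave-trough crossing of
  the same complex (the spike's filter shadow parks the trough within
  ~2 SD of the negative threshold, and correlated 1/f noise pushes it
  over in bursts ~70 ms after the spike) while staying below the 83-ms
  period of a 12 Hz discharge; 75 ms satisfies both with margin.
- Event extent is first-to-last peak extended by half the collapse window
  per side; the duration filter keeps `duration >= 1 s` inclusive; the
  5-12 Hz band is inclusive at both edges; acceptance needs `frac >= 0.75`.
- The automatic baseline picker takes the longest seizure/artifact/
  sleep-free wake interval in the control period (earliest on ties),
  capped at 120 s, requiring at least 60 s — a deterministic stand-in for
  the traditional manual selection.  An explicit interval can always be
  passed instead.

## Ictal peak frequency

The continuous wavelet transform is evaluated as an analytic Morlet
filter bank directly in the frequency domain: at analysis frequency f the
amplitude-preserving kernel is a Gaussian of SD f/(2 pi f0) centered on f
(f0 = 1: envelope SD of one oscillation period).  This form is exactly
analytic, so a pure tone's power profile peaks at the tone frequency at
every interior time point; discretized time-domain Morlet implementations
we evaluated carry a ~0.1 Hz argmax bias from their scale normalization
plus ~0.2% non-analytic ripple, both of which matter at the 0.1 Hz grid
step this analysis needs.  Above ~13 Hz adjacent grid bins fall within
numerical ripple of each other, so exactness there holds for the ridge
mean rather than pointwise.  Segments are reflection-padded 2 s per side;
ridge ties break toward the lower frequency; the per-SWD figure is the
unweighted ridge mean over the full detected span, and the animal figure
the unweighted mean over treatment-period SWDs (missing, never zero, when
there are none).  For very short discharges (1-2 s) the edge time points
dilute the ridge mean slightly toward the background — visible only in
near-total-suppression regimes where all surviving seizures are short.

## Interictal band power

Resampling to 200 Hz uses a polyphase FIR anti-aliasing filter.  The STFT
window is a Gaussian with 1 Hz spectral SD (sigma_t = 1/(2 pi) s,
truncated at +/-4 sigma), hop half a window, evaluated on a 0.5 Hz FFT
grid from which the integer 1..80 Hz bins are taken.  Band edges are the
printed inclusive integers; the gamma band structurally excludes the
48-52 Hz bins.  Excluded samples (detected *and* annotated seizures —
annotations stand in for the visual-refinement pass that catches what
automatic detection misses — plus artifacts and sleep) are padded by
0.5 s per side so ictal onset/offset energy cannot leak into interictal
spectra; analysis runs shorter than 2 s are dropped, run spectra are
averaged weighted by run length, and epochs under 10% usable time are
reported missing.

## Normalization and statistics

Seizure metrics and band powers normalize the same way: per animal, each
epoch value over the mean of that animal's two control epochs (x100),
then over the vehicle-group mean at the matching epoch (x100).  Counts
and mean durations attribute an edge-spanning event to its start epoch;
total time splits at the edge, so summed time is conserved exactly.
Zero-seizure epochs yield a missing mean duration, never zero.  Overall
effects are animal-level means across treatment epochs, summarized as
group mean +/- SEM (sample-SD convention); a comparison SEM variant also
propagates the vehicle-group normalization error, which shifts a whole
arm coherently and is invisible to the plain across-animal SEM.  The
two-way ANOVA uses type-III sums of squares with sum-to-zero contrasts
(group sizes of 6-11 make the decomposition choice material); Dunnett
contrasts run on animal-level treatment means; the per-epoch time course
uses pooled-variance t-tests with Sidak family-wise adjustment
(1 - (1-p)^m); peak frequency uses a pooled unpaired t-test.

## Problem sizes

Validation and the reproduction script run full -40..+120 min sessions at
256 Hz with cohorts of 6-11 animals per arm, a vehicle pool shared across
comparisons, and a metrics-level (no-EEG) null generator for the
1000-replicate Sidak calibration — sizes chosen so the whole validation
cycle completes in minutes on a single core while keeping every
acceptance quantity's sampling error well inside its tolerance.

## Known limitations

- The generator's waveform realism is deliberately minimal; detector
  performance numbers on synthetic data bound, but do not guarantee,
  performance on real recordings.
- Inter-seizure statistics (Poisson + refractory) and sleep scheduling
  are assumptions, not measured properties of GAERS.
- The vehicle-normalized ratio estimator is slightly Jensen-inflated at
  small control-sample sizes (a property of the classic design with two
  control epochs); cohort comparisons inherit that from the original
  procedure by construction.
- EDF files can be read (via mne) but not written; the native format is
  float32 binary plus a JSON sidecar.
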
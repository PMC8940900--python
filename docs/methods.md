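# Methods

`csdsphys` implements the analysis chain of a chronic social defeat
stress (CSDS) circuit study — behavioral phenotyping, fiber-photometry
signal processing, patch-clamp feature extraction, and normality-gated
statistics — together with a synthetic-cohort generator that produces
data with known ground truth for every stage. This note documents the
models, the defaults and their units, the numerical choices, and what
the synthetic data does and does not establish about real recordings.

## Behavioral scoring and phenotyping

Zone membership uses the tracked center point against closed,
axis-aligned rectangles. When zones share a boundary, a sample is
assigned to the first matching zone in the arena's declaration order;
this makes occupancy over a partition exactly additive. Entries use a
minimum-dwell hysteresis (default 0.2 s) so that single-frame boundary
jitter does not count as an entry (video trackers apply a similar
internal rule); initial placement inside a zone counts as one entry.

Arena geometry: plus maze with 70 × 5 cm arms and a 5 × 5 cm hub; open
field 44 × 44 cm with a 10 × 10 cm center; the social-interaction (SI)
arena is an open field with a wire-mesh cage on one wall, with a
configurable interaction zone (default 26 × 16 cm) since that zone is
not standardized across laboratories; three-chamber arena of 44 × 17 cm
chambers with 3 × 5 cm sniffing zones. The video rate defaults to
30 Hz (typical commercial tracking; the rate is a configuration knob).

Indices follow the standard definitions: SI ratio = 100 × (interaction-
zone time with target present) / (same with target absent); sucrose
preference = 100 × sucrose / (sucrose + water) consumed; urine-sniffing
preference = urine-zone time / water-zone time. Zero denominators raise
an explicit undefined-ratio error rather than fabricating a value.
Classification: unstressed mice are CTL; stressed mice with SI ratio
≥ 100 are resilient (A, anxiety-like only); below 100, susceptible
(AD, anxiety plus depressive-like). The boundary is inclusive on the
resilient side. SI locomotion (distance, velocity) is reported from the
no-target phase to avoid social-approach bias.

## Photometry processing

The 405 nm isosbestic channel is fit to the 490 nm calcium-dependent
channel by ordinary least squares over the whole session;
ΔF/F = (F490 − fit) / fit per sample, then z-scored over the session
for cross-animal comparison. A constant control channel degrades to an
intercept-only fit with a warning.

Compartment activity is the trapezoidal integral of the session z-score
over contiguous in-zone visits, summed per zone; both the total (z·s)
and the time-normalized mean (z·s per second in zone) are emitted, and
the correlation stage uses the normalized form (total AUC confounds
activity with time in zone).

Transient events are samples where ΔF/F exceeds the session median by
2.91 × raw MAD. The MAD is deliberately unscaled (no 1.4826 consistency
factor): 2.91 × 0.6745 ≈ 1.96 standard deviations for Gaussian data,
i.e. the two-sided 95% band — the calibration the multiplier encodes.
The threshold is centered on the median, the MAD-consistent location
choice. One event is timestamped at the maximum of each supra-threshold
excursion, with a 0.5 s minimum inter-event interval (configurable).
Events are detected on ΔF/F before z-scoring; z-scoring is monotone, so
only the threshold units differ. Note that for noise-dominated signals
this rule flags ~2.5% of samples by construction; the events-per-minute
metric is therefore meaningful as a relative, not absolute, rate when
transients do not dominate the trace.

Peri-event analysis extracts ΔF/F from −5 to +5 s around behavior
onsets (nearest-sample snap, ties to the earlier sample), z-scores each
10-s window within itself, and offsets it so the window mean over
[−5, −4] s is exactly zero; at most five epochs per mouse per onset
label (the first five chronologically) enter the average to keep mice
with many events from dominating. Summaries are the mean z in the 1-s
bin centered on the onset, and a 0.5-s sliding-window least-squares
slope of the averaged trace (edges truncated to full windows).

The identical chain runs on the 405 nm channel (against its own linear
time trend) as an artifact control: behavior-locked structure there
indicates movement or bleaching artifacts rather than calcium dynamics.

GCaMP6s and GCaMP6f recordings are processed identically and are
poolable; the sensors differ only in the generator's kernel constants.

## Patch-clamp features

Cell-attached spike detection high-pass filters at 100 Hz, then smooths
with a 0.5 ms Gaussian kernel approximately matched to the spike trough
width, and thresholds the negative-going phase at 4.5 × robust SD
(1.4826 × MAD) with a 2 ms refractory period. The smoothing narrows the
noise bandwidth so that threshold crossings on spike-free stretches are
rare (≲0.03 Hz) while the spike deflection, much wider than the noise
correlation time, loses little amplitude; at a 4 SD threshold without
smoothing, Gaussian level-crossing theory puts the false-positive rate
near 0.1–0.3 Hz for kilohertz-bandwidth noise, which is incompatible
with percent-level precision at dopamine-like firing rates. Both the
threshold and the smoothing width are configurable. Spike-onset-to-
trough latency is measured on the average detected waveform: onset is
where it first exceeds 10% of the positive-peak height before the
trough.

Putative dopamine units require a firing rate between 1 and 10 Hz
(inclusive) and trough latency strictly greater than 1.1 ms; only such
units enter per-mouse averages by default (overridable). Per-mouse
aggregation is the unweighted arithmetic mean over qualifying neurons,
and correlations run at the mouse level.

Whole-cell protocols: excitability = spike count per 1 s current step,
−100 to 280 pA in 20 pA increments; rheobase = smallest step with at
least one spike (undefined when none fire, no positivity assumed); Ih =
steady-state minus instantaneous current per 3 s voltage step, −120 to
−60 mV from a −60 mV hold, with the instantaneous window at 20–60 ms
after the step transient and steady state over the final 10% of the
step (neither window is standardized; both are configurable); sag
amplitude = V_ss − V_peak during a hyperpolarizing step pulled to about
−80 mV, with sag ratio = (V_ss − V_peak)/(V_baseline − V_peak) reported
alongside (the ratio has no universal definition; this one normalizes
by the step depth). Peaks outside −90..−70 mV log a warning but are
measured. Ih is stored signed (inward negative).

## The synthetic cohort

The generator draws a latent anxiety trait a_i ~ Beta(2, 4) per mouse
(clipped to [0, 1]); stress adds 0.25 before clipping. Open-arm
occupancy (0.45 − 0.40·a_i + noise) and dopamine firing
(5.0 − 3.0·a_i + noise, Hz) are both linear in the trait, so firing and
open-arm time covary positively through it. The SI ratio is drawn
independently of the trait: susceptible mice (probability 0.6 among
stressed, the typical susceptible share in this paradigm) around 60% truncated
strictly below the boundary, others around 140% truncated at or above
105%. This architecture implements the study's dissociation — circuit
activity couples to anxiety-like, not depressive-like, behavior — as a
generative fact that the analysis chain must rediscover.

Cohort defaults (28 CTL + 60 stressed) match a typical behavioral
cohort for this paradigm. Firing defaults put controls near 4 Hz with a ~0.7 Hz stressed
depression, inside the 1–10 Hz dopamine band. The "stressed firing
below control" invariant holds at the group-mean level (the per-mouse
linear trait model, required by the correlation oracle, admits
overlap).

Trajectories come from a scheduled random walk: dwell segments are
allocated to zones by largest-remainder apportionment in proportion to
the occupancy targets (shuffled order, ~4 s dwells with ±20% jitter);
within a dwell the walk diffuses with reflecting walls inside one
rectangle of the zone, and between dwells it moves at bounded speed
toward the next zone — via the hub for plus-shaped arenas, where arms
only connect through the center. Quota scheduling (rather than i.i.d.
zone draws) keeps realized occupancy within a few percent of target at
5-minute trial length, so behavioral measurements carry realistic but
bounded sampling noise. Entry/exit micro-structure, thigmotaxis, and
velocity profiles are not modeled: passing tests demonstrates correct
scoring arithmetic, not tracker-grade realism.

Photometry signals are built as
490 = (baseline + transients) × bleach + motion + noise and
405 = baseline405 × bleach + motion × (baseline405/baseline490) + noise:
a double-exponential bleach with shared shape, a ~2 Hz low-pass shared
motion artifact scaling with channel brightness, and transient kernels
k(t) = A(1 − e^(−t/τr))e^(−t/τd) with (τr, τd) = (0.18, 1.4) s for
GCaMP6s and (0.05, 0.40) s for GCaMP6f (typical sensor literature
values; configurable). Transients are an inhomogeneous Bernoulli/
Poisson process whose rate rises in a designated zone. Because the
artifact subspace of the 490 channel is spanned by the 405 channel by
construction, the control fit removes it almost entirely; real data
violate this (wavelength-dependent bleaching, hemodynamics), so the
recovery tests validate the arithmetic, not artifact removal in
general.

The membrane model is a single-compartment leaky integrate-and-fire
cell with one hyperpolarization-activated conductance:
C·dV/dt = −g_L(V−E_L) − g_h·x·(V−E_h) + I, with first-order gating
x_inf(V) = 1/(1 + exp((V−V_half)/k)). Defaults: C = 100 pF, g_L = 5 nS,
E_L = −60 mV, V_th = −40 mV, V_reset = −50 mV, g_h = 2 nS, E_h =
−30 mV, V_half = −85 mV, k = 6 mV, τ_h = 400 ms. Forward-Euler
integration at 0.05 ms (0.1 ms for generated sweeps; always ≤ 0.1 ms)
with exact exponential gating updates; voltage-clamp currents use the
analytic piecewise-exponential gating solution. Spikes are rendered as
a single +20 mV sample followed by reset. This is the minimal model
exhibiting every measured feature (rheobase, excitability slope, sag,
Ih); it is in no sense a biophysical dopamine-neuron model.

Cell-attached traces place spikes by a gamma renewal process (shape 5 —
regular, pacemaker-like firing) with a stereotyped biphasic waveform
whose trough latency is configurable, on Gaussian noise at 10 kHz.

All randomness descends from one master seed through a
`numpy.random.SeedSequence` splitting scheme keyed by stage name
(CRC-32, so the split is stable across interpreter sessions) and mouse
index; any stage of any mouse can be regenerated independently, and
identical (config, seed) reproduce outputs bit-identically.

## Statistics

Normality is checked by a plain Kolmogorov–Smirnov test of the
standardized sample against the standard normal at α = 0.05. With
estimated parameters this test is conservative (the Lilliefors effect
understates non-normality); the plain form is the convention adopted
here and the threshold is configurable. Samples with n < 5 or zero
variance route nonparametric with a warning. Correlations take Pearson
only when both variables pass the gate, else Spearman; group
comparisons take one-way ANOVA (plus pairwise two-sided t-tests) only
when every group passes the gate and Levene's test accepts equal
variances, else Kruskal–Wallis with pairwise Mann–Whitney. All
p-values are two-sided; pairwise p-values are Bonferroni-corrected
(family-wise control without multivariate-t machinery). Repeated-
measures designs and sphericity corrections are out of scope.

The pipeline's correlation panel computes SI-linked correlations
(firing × SI ratio, SI × sucrose/urine preference) on stressed mice —
the SI ratio is a post-defeat phenotype, and pooling CTL mice would
induce a spurious group-offset correlation — and anxiety-linked
correlations (firing × open-arm time, open-arm × open-field center) on
all mice. The statistics stage operates exclusively on the extracted
per-mouse metrics table and raises if latent generator columns leak in;
ground-truth recovery checks live only in the test suite.

## Problem sizes and tolerances

Test and validation runs use 5-minute behavioral sessions at 30 Hz,
photometry at 381 Hz, and 60 s cell-attached records at 10 kHz with 3–7
neurons per mouse. Cohort-recovery checks run ten seeded cohorts of
28 CTL + 60 stressed mice with the photometry stage disabled (none of
the recovered quantities depend on it). Occupancy convergence is tested
at 3000 s within ±0.05; Ih extraction agrees with the analytic
window-averaged gating solution within 2%; firing-rate extraction is
unbiased within 3% at 60 s; the peri-event baseline offset is exact to
1e−9. The event-threshold calibration (2.91 × raw MAD ≈ 1.96 SD, 95%
Gaussian coverage) is verified analytically and by Monte-Carlo at
n = 10^6.

## Known limitations

* The trajectory model reproduces occupancy, not locomotor dynamics;
  distance and velocity metrics are internally consistent but not
  calibrated to mouse behavior.
* The photometry generator's artifacts are exactly removable by the
  isosbestic fit; it cannot probe robustness to wavelength-dependent
  artifacts.
* The MAD event rule has a built-in noise-crossing floor on
  noise-dominated traces (by design of the 95% threshold); event rates
  are comparative measures.
* The membrane model's excitability curve saturates only through the
  reset mechanism; no adaptation or channel diversity.
* Lock-in demodulation of the excitation carriers, hemodynamic
  correction, and spike inference from calcium are out of scope.
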
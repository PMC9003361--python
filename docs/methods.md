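# Methods

This note documents the generative model, the analysis conventions and the
numerical choices behind `flexemg`, and states what the synthetic study
conditions do and do not establish about real recordings.

## Signal model

### Voluntary contraction sEMG

A channel is the superposition of `mu_count` independent motor-unit action
potential (MUAP) trains. Each unit fires as a Poisson process with an
absolute refractory floor of 20 ms and mean rate `firing_rate` (default
15 Hz), and contributes a first-order Hermite–Rodriguez kernel

    w(t) = a * (t/tau) * exp(-(t/tau)^2),   t >= 0,

the standard parsimonious MUAP surrogate. Per-unit `tau` is jittered
±20 % around `3 ms * tau_scale` and per-unit amplitude ±30 % around
`0.3 mV * amplitude_scale`; these base scales place maximum-contraction
surface EMG near 0.1 mV RMS with spectral mass around 60–120 Hz, inside
the 20–500 Hz analysis band. Gaussian baseline noise (`noise_sd`, default
0.01 mV) and a random-phase 50 Hz powerline sinusoid (`powerline_amp`,
default 0.02 mV) are added. The noiseless signal is exactly linear in
`amplitude_scale` (up to FFT-convolution rounding, ~1e-16 absolute).

### Evoked responses

A stimulation train places a sharp biphasic artifact (one period of a sine,
1 ms wide, fixed 10 mV — deliberately *not* scaled by condition, so the
artifact cannot leak the class label) at each exact stimulus time `k/rate`.
After the condition's latency the compound muscle response follows. The
response is a canonical biphasic template

    r(t) = (A/2) * sin(2*pi*(t - t0)/D)  on [t0, t0 + D],

parameterized directly by onset time `t0`, peak-to-peak amplitude
`A = 0.05 mV * mu_count * amplitude_scale` and duration
`D = 8 ms * tau_scale`. This direct parameterization was chosen over
summing individual synchronized MUAP kernels because it makes the per-epoch
ground truth exact by construction: latency, amplitude and duration are the
parameters themselves and the rectified area has the closed form
`A * D / pi` (mV·ms). A literal MUAP superposition with the same
macroscopic parameters would force ground truth to be *measured* from the
noiseless trace, entangling it with the extraction rules it is meant to
validate. Per-epoch physiology is emulated by jitter: latency ± 0.3 ms
(Gaussian), amplitude lognormal with σ = 0.15, duration ± 8 %.

### Conditions

| condition | mu_count | amplitude_scale | tau_scale | latency |
|---|---|---|---|---|
| healthy | 20 | 1.0 | 1.0 | 5.0 ms |
| nerve injury | 8 (×0.4) | 1.0 | 0.85 | 7.0 ms (+40 %) |
| immobilization | 18 (×0.9) | 0.7 | 1.0 | 5.0 ms |

Denervation removes motor units and slows conduction; disuse atrophy
shrinks fibre contributions with near-normal timing. The nerve-injury
`tau_scale = 0.85` serves double duty: it shortens the evoked response
(preserving the clinical ordering: nerve duration < immobilization
duration) and shifts voluntary spectra upward, so in voluntary mode the
amplitude features (RMS, iEMG) of the two atrophy conditions overlap
heavily — asynchronous-train RMS grows only with the square root of the
unit count, leaving a ~10 % gap — while the frequency features (MDF, MPF)
separate them. That overlap-plus-multidomain-separability structure is the
premise of classifying on combined time- and frequency-domain features
rather than thresholding any single one.

### Cohorts

*Evoked (rat) protocol*: two groups of 6 subjects, 150 acquisitions each;
one acquisition is a single-stimulus 0.5 s record. Each subject also
contributes 10 pre-injury healthy baseline records (averaged into the ratio
denominator) and carries a random effect — lognormal amplitude (σ = 0.12)
and time-scale (σ = 0.05) factors plus a ± 0.3 ms latency offset — shared
between its baseline and post-injury records, which the ratio largely
cancels. Label convention: positive = immobilization (1), negative = nerve
injury (0). The default design yields 1800 labeled samples, 900 per class.

*Patient protocol*: 7 immobilization + 3 nerve-injury subjects, one 60 s
four-channel record each (tibialis anterior and gastrocnemius, affected and
unaffected limb). Affected channels use the condition parameters,
unaffected channels the healthy ones, under the same subject effect with a
small per-channel gain (lognormal, σ = 0.05).

Sampling rates: voluntary records default to 2 kHz (≥ 4× the 500 Hz band
edge); evoked records default to 10 kHz, standard for clinical evoked
responses — a 1 ms biphasic artifact sampled at 2 kHz would alias to
near-zero samples and millisecond-scale latencies need sub-0.1 ms grids.

## Preprocessing

Channels are sorted into canonical role order, then each passes a 50 Hz IIR
notch (Q = 30, ≈ 1.7 Hz width at −3 dB) followed by a 20–500 Hz Butterworth
band-pass of overall order 4 (two poles per edge; a per-edge-order variant
is available). Filtering is zero-phase (forward–backward) by default so
evoked latencies are unbiased by group delay; a causal mode exists. With
the Q = 30 notch the chain's ringing decays below 1e-6 of its peak within
about 2.6 s (the pole envelope is exp(−π·50·t/Q)); the stability test
asserts 3 s. Feature windows for voluntary records are taken from a
configurable stable segment (default 15–45 s of the 60 s move), which also
keeps filter warm-up out of the analysis.

## Evoked parameter extraction

Stimulus artifacts are local maxima of |x| above 8× the median absolute
deviation of the raw trace, separated by at least half the inter-stimulus
interval (within that distance the larger peak — the artifact — shadows
the response). Finding nothing raises an explicit error.

Per epoch (100 ms window from the artifact): after 2 ms blanking, onset is
the first sample where |x| exceeds `max(3 × SD(baseline), 5 % of the
post-blanking peak)` sustained for ≥ 1 ms, offset the last such sample;
both are refined to sub-sample precision by linear interpolation of the
threshold crossing. Latency = onset time; duration = offset − onset;
amplitude = max − min over [onset, offset] with light Savitzky–Golay
smoothing (0.6 ms, order 2) and parabolic peak interpolation; AUC is the
trapezoidal integral of |x| over [onset, offset]. The threshold's relative
component makes timing parameters scale-invariant and amplitude/AUC exactly
scale-equivariant. An epoch with no sustained supra-threshold run returns
an explicit no-response marker (NaN fields), never zeros.

Measured recovery on 200 fresh epochs spanning latency 3–10 ms, amplitude
1–10 mV, duration 4–12 ms at 10 kHz: noiseless worst-case errors ~0.1 ms
(latency), < 0.03 % (amplitude), ~0.2 ms (duration), < 1 % (AUC) — the test
suite asserts the looser clinical tolerances (±0.5 ms, ±2 %, ±1 ms, ±5 %)
per epoch. With noise at 5 % of the response peak the *mean* absolute
errors stay within twice those tolerances; worst-case single-epoch
amplitude error is noise-limited at the peaks, which is why the noisy
assertion is on the mean, not the per-epoch maximum.

## Features and ratios

Windows are 0.5 s advancing by `0.5 × (1 − 1/8) = 0.4375 s` (the overlap is
read as a fraction of the window; the step-=-overlap reading is available
via `step_is_overlap`). A 30 s segment gives 68 windows, 40 s gives 91;
partial final windows are dropped. Spectral features use a Hann-tapered
periodogram zero-padded to ≥ 1024 points — a 0.5 s window is too short for
Welch averaging without destroying resolution — with MDF linearly
interpolated between bins, both restricted to 20–500 Hz.

Classifiers consume the 4-feature ratio set {rms, iemg, mdf, mpf}; ARV is
computed and stored but excluded from the default model. For the evoked
protocol the features of each acquisition are computed on the 2–100 ms
post-stimulus window (artifact blanked) and divided by the subject's
baseline means; for patients each affected-muscle row is divided by the
mean over the contralateral channel of the same muscle.

## Classification

A standardize-then-classify pipeline (train-fold statistics only) with
small grids searched by 3-fold inner accuracy: gbdt depth {2,3,4} × trees
{100,300} × lr 0.1; RBF-SVM C {1,10,100} × γ {0.125,0.25,0.5} (the `scale`
heuristic for 4 standardized features, ×{0.5,1,2}); kNN k {3,5,7,9} (odd,
avoiding ties). Gradient boosting is realized by
`sklearn.ensemble.GradientBoostingClassifier`; any compliant
gradient-boosted-tree implementation fits the protocol. Metrics are
computed by exact rational arithmetic from the confusion counts; a
zero-denominator metric is reported as undefined (`None`), never 0.

Row-level random splitting follows the stated protocol, but windows of one
subject are correlated, so row-level splits leak subject identity into the
test set; subject-wise splitting (stratified group folds) is provided via
`groups=`/`subject_wise` and reported alongside, not silently substituted.
The permutation null in the acceptance script uses the kNN spec: the
permuted-label accuracy distribution is classifier-independent (~0.5), and
kNN makes 20 full CV repeats cheap where gradient boosting would not be.

## Determinism

Every generator, split and classifier derives its randomness from one
master seed through `numpy` `SeedSequence` spawning in a fixed order;
identical configuration + seed reproduces cohorts, tables and pipeline
reports byte for byte. Pipeline outputs embed a 16-hex config hash.

## Problem sizes

The test suite runs the full default evoked cohort (1800 samples) for
accounting and cross-validation, 200-epoch recovery sweeps, and
scaled-down cohorts (2–3 subjects per group, 10–25 acquisitions) for
pipeline-level checks; the acceptance script additionally runs the full
10-patient protocol. These sizes were chosen to keep a complete run in the
low minutes on a single CPU.

## What the synthetic conditions do not show

The generator emulates the *statistical structure* the analysis assumes —
group orderings, overlap, subject effects, powerline and baseline noise —
not the physics of real recordings: no volume conduction or electrode
geometry, no skin impedance, no motion artifacts, no fatigue drift within
a contraction, no electrode-size effects. Passing tests therefore
demonstrate that the pipeline recovers what the model encodes and meets its
accounting and accuracy contracts under these conditions; they do not
certify clinical performance on human data. Classification accuracies on
synthetic cohorts depend directly on the chosen effect sizes and are
reported as properties of these study conditions.
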
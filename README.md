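# flexemg

Non-invasive evaluation of **what caused a muscle to atrophy** after limb
fracture. Two etiologies dominate and demand different rehabilitation:
peripheral **nerve injury** (denervation) and **limb immobilization**
(disuse). The clinical standard for telling them apart — needle EMG with
electrical nerve stimulation — is invasive and painful. `flexemg`
implements the surface-EMG alternative as a tested, reusable Python
pipeline: simulate the two study protocols with known ground truth,
preprocess, extract evoked-response parameters and windowed sEMG features,
ratio-normalize, classify, and report accuracy / specificity / sensitivity.

It is a library first: import it, or start from the narrative scripts in
`examples/`.

## What it computes

**Evoked responses** (the invasive-diagnosis analogue). A stimulation train
(2 mA, 2 Hz, 100 µs pulses) elicits one compound muscle response per
stimulus. For each epoch the pipeline measures the four clinical
parameters: onset latency *t*<sub>lat</sub>, peak-to-peak amplitude
*A*<sub>pp</sub>, duration *D* (onset → return to baseline) and rectified
area ∫|x(t)|dt. Nerve injury shows smaller *A*<sub>pp</sub>, *D* and area
with longer *t*<sub>lat</sub>; groups are contrasted by two-tailed Welch
t-tests at α = 0.05.

**Windowed sEMG features** (the non-invasive route). Records are notch-
filtered at 50 Hz and band-passed 20–500 Hz (4th-order Butterworth,
zero-phase), then cut into 0.5 s windows with 1/8 overlap. Per window:

    RMS  = sqrt(mean(x^2))          MDF : median frequency of the PSD
    ARV  = mean(|x|)                MPF = sum(f*P(f)) / sum(P(f))
    iEMG = sum(|x|) / fs

Features are expressed as **ratios** — affected limb over unaffected limb
(patients), or post-injury over the subject's pre-injury baseline (evoked
protocol) — removing the subject's overall effort and electrode gain.

**Classification.** Gradient-boosted trees, RBF-SVM and kNN are evaluated
with a stratified 80/20 split and 5-fold cross-validation (grid-searched on
inner folds). With positive = immobilization:

    Accuracy    = (TP + TN) / (TP + TN + FP + FN)
    Specificity = TN / (TN + FP)
    Sensitivity = TP / (TP + FN)

**Synthetic cohorts.** No public recordings exist for this problem, so the
`synthetic` module generates both protocols with exact ground truth: a rat
study (6 + 6 subjects × 150 evoked acquisitions plus pre-injury baselines →
1800 labeled samples, 900 per class) and a patient study (7 immobilization
+ 3 nerve-injury subjects, 60 s four-channel maximum-voluntary-contraction
records). Voluntary sEMG is a superposition of motor-unit action-potential
trains (Hermite–Rodriguez kernels, Poisson firing with refractoriness);
evoked epochs carry a biphasic compound response whose true latency,
amplitude, duration and area are known exactly. See `docs/methods.md`.

## Worked example

`python examples/02_evoked_parameters.py` simulates 50 evoked epochs per
group and contrasts them:

```
   parameter  mean_a     sd_a  mean_b     sd_b        t   p  significant
  latency_ms  7.2642 0.301747  4.9474 0.327783  36.7699 0.0         True
amplitude_mv  0.4261 0.062662  0.6426 0.096490 -13.3048 0.0         True
 duration_ms  6.3386 0.444573  7.6087 0.471785 -13.8543 0.0         True
    auc_mvms  0.9030 0.145513  1.6133 0.283726 -15.7517 0.0         True
```

`mean_a` is the nerve-injury group, `mean_b` immobilization: the nerve
group's response arrives ~2.3 ms later and is smaller, shorter and carries
less area — the full clinical sign pattern, every contrast significant.

`python examples/04_rat_classification.py` runs the classification stage on
a scaled-down cohort (3 + 3 subjects × 25 acquisitions):

```
feature samples: 150 (75 positive / 75 negative)
gbdt     accuracy 92.00 % specificity 94.67 % sensitivity 89.33 %
svm_rbf  accuracy 96.00 % specificity 97.33 % sensitivity 94.67 %
knn      accuracy 95.33 % specificity 98.67 % sensitivity 92.00 %
```

The three families land within a few points of one another; on the
full-size 1800-sample cohort (see below) gradient boosting reaches ~98 %
cross-validated accuracy, while the patient protocol — weaker effect sizes,
only 10 subjects — lands around 90 %, echoing the expected gap between the
controlled evoked study and bedside voluntary recordings.

## Layout

- `src/flexemg/synthetic.py` — condition parameters, MUAP/evoked generators, cohorts
- `src/flexemg/preprocess.py` — notch + Butterworth band-pass chain
- `src/flexemg/evoked.py` — stimulus detection, parameter extraction, group stats
- `src/flexemg/features.py` — windowing, time/frequency features, ratio tables
- `src/flexemg/classify.py` — splits, CV, confusion-matrix metrics
- `src/flexemg/pipeline.py` — one-call end-to-end runs with provenance
- `src/flexemg/records.py` — signal containers and plain-text I/O
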
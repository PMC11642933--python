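# Methods

## Problem

Apneas and hypopneas in neonates at risk of upper-airway obstruction are
brief (seconds-long) events that currently require manual intervention.
`namts` frames their *prediction* as binary classification of 30-second
multichannel polysomnography windows: does this window shortly precede an
adverse event (target) or not (control)?  The emphasis is on inherent
interpretability — every prediction decomposes exactly into per-modality
contributions and time-resolved activation maps, so a clinician can see
which signal, and which part of it, drove an alarm.

## Model

The classifier is a neural additive model (NAM) over six signal modalities
(nasal pressure NP, summed thoracic+abdominal effort T+A, photoplethysmogram
PPG, heart rate HR, SpO2, PCO2):

    p̂ = σ( Σᵢ fᵢ(xᵢ) + β )

Each fᵢ is a fully convolutional subnetwork: three 1-D convolution layers
("same" zero padding, so the time axis is preserved), each followed by batch
normalization and ReLU; a per-timepoint linear combination of the hidden
channels then yields a single **activation map** aᵢ(t), and global average
pooling yields the scalar fᵢ(xᵢ) = meanₜ aᵢ(t).  Two identities therefore
hold *architecturally*, not approximately:

* logit = Σᵢ contributionᵢ + β, and
* contributionᵢ = time-mean of activation map i.

The classical NAM weighting αᵢ·fᵢ is absorbed into each subnetwork's final
linear-combination layer (an equivalent parameterization); the reported
contribution is the combined scalar.  All reported predictions,
contributions and maps are computed in evaluation mode (batch-norm running
statistics), which makes them deterministic and strictly per-window: editing
one modality of one window changes exactly that window's one contribution.

The networks are implemented directly in NumPy (`namts._nn`): 1-D
convolution as a GEMM over an im2col view, hand-written backpropagation
(verified against numerical differentiation in the test-suite), and Adam
with coupled L2 weight decay applied to convolution/dense weights only —
not to biases or batch-norm parameters.

A non-additive **blackbox** reference shares the convolutional extractors
but concatenates channel-wise pooled features from all modalities
(20 x 6 = 120 features) into a two-hidden-layer MLP (width 64), trained
end-to-end with the same schedule.  Two classical baselines fit 24
engineered features (per oscillatory modality: time-domain skewness/excess
kurtosis and spectral centroid/spread/skewness/kurtosis; per slow modality:
mean and range) with an L2 logistic regression or a one-hidden-layer MLP,
each behind a column-standardization pipeline.

### Key hyperparameters

| parameter | default | meaning |
|---|---|---|
| kernel_size | 9 (grid 5–17) | conv kernel length, in model-rate samples |
| hidden_channels | 20 | channels per conv layer |
| n_conv_layers | 3 | subnetwork depth |
| epochs / lr / weight decay | 10 / 1e-4 / 0.01 | Adam training schedule |
| batch_size | 4 | minibatch size; under the fixed 10-epoch / lr 1e-4 schedule, the step count — not the epoch count — determines how far training gets, so the small batch keeps the number of Adam steps on desk-scale cohorts (a few hundred balanced windows per fold) comparable to training on cohorts an order of magnitude larger; config-exposed |

Each subnetwork's final combination layer is **zero-initialized**: every
contribution starts at exactly zero (an unbiased p̂ = 0.5 model), and a
modality's contribution spread can only arise from gradient-driven learning,
never from random initialization — which keeps the importance analysis
meaningful for lightly trained networks.

## Windowing and preprocessing

All five apnea/hypopnea kinds form one adverse-event class; isolated
intermittent hypoxia annotations are neither adverse nor masked.  Signal
annotated as adverse event or movement is masked.  Intervals are half-open
`[start, end)` seconds; sample k at rate r covers `[k/r, (k+1)/r)`.

* **Targets** are anchored per event: the window `[onset−45, onset−15)`
  (30 s length, 15 s prediction horizon).  Candidates outside the recording,
  intersecting the mask, or overlapping an earlier target are dropped
  (earlier events win — deterministic, time-ordered).  The 15 s horizon
  exceeds the annotated event durations, so prediction cannot ride on
  imprecise annotation timestamps.
* **Controls** tile, left to right, each maximal region whose every point is
  ≥ 180 s from every adverse event boundary; tails shorter than one window
  are discarded.
* Windows containing NaN are dropped, never imputed.

Per window: NP, THOR, ABD, PPG are decimated to 5 Hz; SpO2/PCO2 from 2 to
1 Hz; HR stays at 1 Hz.  Decimation uses an order-8 Chebyshev type-I
low-pass per integer stage (stages ≤ 10, e.g. 200→5 Hz as 10×4), cutoff
0.8× the target Nyquist, applied forward-backward (zero phase, so pre-event
signatures are not displaced in time) and rescaled to exact unit DC gain.
The passband ripple is set to 0.01 dB: after zero-phase (magnitude-squared)
application over multiple stages this keeps in-band sinusoids accurate to
well under 1%, which a 0.05 dB design would not.  NP/PPG are z-scored per
window (population SD; SD < 1e-12 returns zeros); T+A = zscore(zscore(THOR)
+ zscore(ABD)); HR/SpO2/PCO2 are clamped to [50,240] bpm / [60,100] % /
[30,70] mmHg and mapped affinely onto [−1, 1].  Constant signals
short-circuit the decimator exactly so the zero-variance guard still fires
after filtering.

## Evaluation protocol

Patient-based leave-one-out cross-validation: each patient's windows are the
test set; training (and hyperparameter selection by patient-grouped k-fold,
k = min(5, #training patients), ties → smaller kernel, then fewer channels)
uses only the other patients.  Training pools are class-balanced by
undersampling the majority class *within each patient* (symmetric — it also
handles the occasional patient where targets outnumber controls); a patient
with a single class is excluded from training with a warning.  Test sets are
never rebalanced.  Reported per patient: AuROC, ROC points, TPR/precision
and the confusion matrix at fixed FPR (10/20/30%), the chosen grid point and
seeds.  The procedure can be repeated n_repeats times with fresh seeds and
per-patient scores averaged (default 1 at desk scale; set 10 to average the
way larger studies do).  Averaged ROC curves use vertical (FPR-parameterized)
averaging on a 101-point grid.

Significance: a one-sided permutation test of AuROC (labels permuted within
one patient's test set; add-one p-value `(1+#{null ≥ obs})/(1+n_perm)`,
n_perm = 999) and two-sided Wilcoxon signed-rank tests for paired model
comparisons across patients (zero differences dropped; exact sign-flip null
via dynamic programming for ≤ 25 informative pairs — also under tied ranks —
normal approximation with tie correction and continuity correction above).

## Synthetic cohorts

The generator (`namts.synthgen`) is phenomenological: it emulates the
statistical regime of overnight infant recordings, not neonatal physiology.
Defaults: 8 patients x 2 h; native rates 200/50/50/1/100/2/2 Hz; ~30
adverse events/h lasting 3–8 s; ~10 movements/h; 35% of events followed by
another within 60–180 s.

* **Signals.**  NP/THOR/ABD share a breathing oscillator (~0.7–1.1 Hz with
  slow frequency and amplitude wander, AR(1)); PPG is a cardiac-band
  oscillator driven by the HR trace plus respiratory coupling and baseline
  wander; HR (~140 bpm), SpO2 (~97%) and PCO2 (~41 mmHg) are clipped AR(1)
  baselines.  Movements inject broadband noise bursts into NP/THOR/ABD/PPG.
* **Events.**  Placement is a clustered two-state renewal process: the night
  alternates gamma-distributed *active* (mean 10 min) and *quiet* (mean
  8 min) phases; events occur only in active phases, at a within-phase rate
  solved so the long-run rate matches `event_rate_per_h`.  This mirrors how
  clinical events concentrate in parts of the night and is what leaves
  stretches long enough to host controls at the 180 s buffer.  No two events
  are closer than 25 s; non-cluster successors are capped at 44 s
  end-to-onset so they are always rejected as targets (their windows would
  overlap the predecessor's mask) and never contain a predecessor's
  desaturation tail.  During events, airflow collapses (and effort too, for
  central events); every event is followed by a ≤ 15 s SpO2 desaturation,
  which is the carry-over that makes clustered events informative.
* **Pre-event signatures.**  In `[onset − 45 s, onset)` the generator plants
  breathing-amplitude irregularity in NP (full weight) and THOR/ABD (half
  weight), an SpO2 dip (3% x strength) and a small HR drift (5 bpm x
  strength), all scaled by `signature_strength`; 0 disables them, making
  pre-event windows statistically indistinguishable from controls (tested).
  The default span covers the default target window, so the horizon sweep
  decays toward chance once the window slides past the span.

Under the default training schedule the strong cohort is nearly saturated
(leave-one-patient-out AuROC ~0.99): the planted signatures are by design
cleaner than clinical pre-event irregularity, so desk-scale recovery checks
bind on orderings and floors, not on reproducing any particular AuROC value.

What passing tests on this generator do **not** show: robustness to real
sensor artifacts, annotation jitter, inter-patient pathophysiology
differences, or waveform morphology (the oscillators are sinusoidal).  They
do show that the pipeline recovers planted discriminative structure, ranks
the informative modality correctly, localizes it in time, and reports chance
when nothing is planted.

## Reference experiments and problem sizes

`namts.experiments.run_recovery_suite` runs, on one CPU in roughly a
quarter hour: LOOCV of the NAM, blackbox, logistic regression and MLP on a
strong-signature 8 x 2 h cohort (shared dataset); the same on a null cohort
(`signature_strength = 0`); single-modality networks for NP, T+A, SpO2;
an importance-recovery experiment (10 x 2 h, signature only in NP, events
sparse and unclustered — with clustered events, targets bunch in time and
slowly wandering uninformative channels like PCO2 acquire spurious
within-patient class differences that inflate their contribution spread;
the controlled cohort removes that confound so the spread ranking must
single out NP); a horizon sweep (0/15/150 s) on a sparse 6 x 1.5 h cohort
(8 events/h, unclustered, no sleep-phase chaining: typical inter-event gaps
of several hundred seconds guarantee that no earlier event's footprint
reaches into a window 150 s before onset, so the 150 s point has nothing to
detect); and an
activation-map localization experiment (6 x 1.5 h, signature only in NP and
confined to the last 15 s of horizon-0 windows; fraction of correctly
classified targets whose positive activation mass concentrates inside the
planted segment).  These sizes are the package's reference configuration;
all are config-exposed.

## Numerical choices and edge cases

* Population (ddof 0) moments throughout; excess kurtosis in the time
  domain, raw kurtosis for the spectral distribution (conventions pinned by
  tests).  Spectral moments exclude the DC bin and guard degenerate spectra.
* Batch norm: eps 1e-5, momentum 0.1; training uses batch statistics,
  all reported outputs use running statistics.
* float32 parameters/activations; contributions and maps are accumulated in
  float64 so the additive identities hold to machine precision.
* Thresholds at fixed FPR pick the loosest threshold whose empirical FPR
  does not exceed the level; precision is defined as 0 when nothing is
  predicted positive.
* Undersampling, initialization, batching and permutation tests all draw
  from explicit seeds; cohort generation is bit-reproducible.

## Known limitations

* EDF input is read through `mne`, which loads all channels at the file's
  common (highest) sampling rate; the plain-text fixture dialect is the
  bit-exact reference format.
* The exact decimation stage factorization (largest factor ≤ 10 first) and
  the inner-CV fold structure are declared conventions; other choices would
  be defensible.
* Single-patient recordings cannot be evaluated (LOOCV needs ≥ 3 patients);
  a patient whose test set contains one class has undefined AuROC and is
  reported as NaN with a warning.
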
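# Methods

`hfamark` is a desk-scale reimplementation of an interictal
high-frequency-activity (HFA) biomarker pipeline for epilepsy surgery
evaluation: detect brief >80 Hz events in intracranial EEG (iEEG), quantify
each event's morphology, train a gradient-boosted model that assigns every
electrode a seizure-onset-zone (SOZ) probability, and relate
resection-completeness summaries of the resulting biomarker maps to
postoperative seizure freedom. Because the corresponding patient recordings
are not desk-available, a synthetic cohort generator provides the entire
data substrate with full ground truth; every quantitative claim the package
makes is therefore a claim about recovery of known generative structure,
not about patients.

## Signal model and montage

Recordings are multichannel epochs (default 5 or 20 minutes at 1,000 Hz, in
microvolts) from subdural grids/strips and depth shafts. Channels flagged as
artifact/white-matter/out-of-brain are excluded before anything else.
Subdural channels are re-referenced to the common average of the included
subdural set; each depth shaft is converted to ordered bipolar pairs
(contact k minus contact k+1). Detection and morphology run on montaged
signals; pair-level electrode statistics are mapped back to contacts as the
mean of the adjacent pairs' values, with shaft-end contacts inheriting the
single adjacent pair (a convention chosen to avoid dropping shaft ends; the
two-pair interior rule is the defined case).

## Detectors

Four detector families run on the 80–500 Hz band-passed signal (zero-phase
FIR, upper edge clipped to 98% of Nyquist): short-time energy (STE;
moving-RMS SD threshold plus a rectified-peak count), short line length
(SLL; moving line-length energy against an empirical percentile), Hilbert
envelope (HIL; per-epoch envelope SD threshold), and an MNI-style detector
(baseline segments identified first, energy threshold from baseline
percentiles, with an iterative-percentile fallback when less than 5 s of
baseline exists). Intervals are half-open `[onset, offset)` with 0-based
sample indexing; detections closer than 10 ms are merged; each detector
enforces its minimum duration.

All numeric defaults live in `src/hfamark/detector_defaults.yaml`. Two
defaults deviate deliberately from the cited originals, and are calibrated
against the synthetic background rather than patient data:

* **SLL percentile 99.5** (originally 97.5). A within-channel percentile
  threshold marks a fixed share of samples supra-threshold by construction;
  at 97.5 this produces ~29 spurious events/min on featureless background.
  99.5 bounds false detections below ~2/min while keeping full recall at
  clinical event rates. A consequence worth knowing: any within-channel
  percentile threshold saturates when events occupy more of the recording
  than the percentile tail (at 99.5, roughly >0.5% of samples), so
  extremely active channels will be under-counted.
* **MNI baseline entropy threshold 0.78**. Baseline segments are 125-ms
  windows whose band-passed spectral entropy is high (noise-like). Measured
  on the synthetic background, noise segments score ~0.77–0.88 while
  event-bearing segments fall to ~0.4–0.75; thresholds much lower let event
  segments contaminate the baseline and inflate the energy percentile until
  recall collapses.

Numerical replication of the MATLAB originals is explicitly out of scope;
the contracts verified instead are behavioral: recall >= 0.9 on events
injected at >= 5x the in-band background RMS, <= 5 false events/min on
event-free channels, determinism, amplitude-scale invariance, and
monotonicity of event count in the primary threshold.

## Event morphology

Each event gets four features: duration (ms), maximum spectral power
(uV^2), frequency at maximum power (Hz), and normalized spectral entropy.
Power comes from a multitaper time–frequency transform: 200-ms DPSS-tapered
windows (time-bandwidth 2, 3 tapers — the taper count is unstated in the
source protocol; this choice respects the 200 ms x 5 Hz resolution), a 5-Hz
frequency grid from 80 to 500 Hz (85 bins at 1 kHz), sliding by one sample
(1 ms). Events near epoch edges are supported by reflection padding; events
extending beyond the epoch get missing features. Peak extraction breaks
power ties toward the lower frequency bin.

Entropy is Shannon entropy of the event's normalized power distribution,
`H = -sum P(f_i) log2(P(f_i) + eps)` with `eps = 1e-12`, normalized by
`log2 N` so `H_norm` spans [0, 1]: 0 for a single-band oscillation, 1 for a
flat (spike-like) spectrum. The spectrum entering the entropy is the
time-averaged power over the event's extent (the peak-time slice is the
alternative; the time average was chosen for noise robustness and the
choice is a function argument). With the epsilon guard, a uniform spectrum
reaches 1 only to within ~1e-11 and a one-bin spectrum can dip marginally
below 0; outputs are clipped to [0, 1] and tolerances of 1e-6 apply.

Electrode rows aggregate events as rate = count / epoch minutes plus the
median of each morphology feature (mean aggregation was the alternative;
medians match the protocol's summary convention). Electrodes with zero
events keep rate 0 and NaN morphology — the missingness is passed to the
tree model, which splits on it natively; dropping those electrodes would
bias the sample toward high-rate sites.

## SOZ classification

The model is a gradient-boosted decision-tree classifier
(`HistGradientBoostingClassifier`) over seven features: rate, median
duration, median power, median peak frequency, median entropy, anatomical
region (fixed 12-level vocabulary, one-hot), and patient age. sklearn's
histogram GBDT was chosen over the XGBoost library (not available in this
environment) as an equivalent model family, with the added benefit of
native NaN routing for the missing-morphology convention.

Evaluation is nested cross-validation: 10 outer folds stratified by label
and grouped by patient (the source protocol does not state the grouping
unit; grouping by patient prevents within-patient leakage), with the
hyperparameter grid searched on inner folds of the outer-training portion
only. The grid is a small versioned default (`classify.DEFAULT_GRID`), not
a fidelity claim — the original grid lives in supplementary material that
is not desk-available. Training rows are SOZ versus non-epileptic sites
only (spiking-only and resected-non-SOZ sites carry no label); per-detector
tables are never pooled. Class imbalance is handled by the model's
`class_weight="balanced"` option, exposed through the grid.

The pseudo-label null redraws labels for an exact 16.8% of electrode sites
per replicate and reruns the entire nested procedure; the permutation
p-value is add-one, `p = (1 + #{null >= observed}) / (n_models + 1)`,
flooring at 1/101 = 0.0099 for the canonical 100 replicates.

Feature attribution is an exact additive path decomposition over the
fitted trees (each split's contribution is the change in the
count-weighted node value along the sample's path): per-row contributions
plus the base value reconstruct the model's margin to machine precision,
and the global ranking orders features by mean |contribution|. This is the
Saabas-style decomposition, not Shapley-exact SHAP (unavailable here); it
satisfies the additivity and ranking contracts but can distribute credit
differently from SHAP for strongly interacting features. Probability
calibration is never asserted; all downstream use is rank-based.

## Outcome analysis

Per patient, a biomarker map and the resection mask are summarized by: the
biomarker difference, mean(resected) − mean(preserved); the difference
index (R − P)/(R + P); the resection ratio (resected sum over total sum);
the critical resection percentage (% of supra-critical electrodes resected;
the critical value defaults to the patient's 90th percentile since no
default is published); and the distinguishability statistic (rank
probability that a random resected electrode outranks a random preserved
one — the AUROC of the mask against the values). The exact published
formulas live in supplementary material; each measure here follows its
original source's construction, and the tests assert internal consistency
(perfect-separation, invariance, and pair-counting-oracle cases) rather
than fidelity to the supplement. Patients with an undefined measure (e.g.
no preserved electrode) are excluded listwise with a warning.

Outcome models: a maximum-likelihood logistic regression of ILAE class 1 on
the ten standard-care covariates (age, sex, daily seizures, ASM count,
hemisphere, MRI lesion, habitual-seizure capture, incomplete SOZ removal,
extratemporal resection, resection extent) plus the optional summary
measure — with a ridge fallback flagged on separation — and a
leave-one-patient-out comparison of AUROC/AUPRC with versus without the
measure (DeLong test on the paired AUROC difference). The univariate odds
ratio is per unit of the measure, not per SD. Etiology subgrouping is
evaluation-only.

## Evaluation statistics

AUROC is the Mann–Whitney pair probability with half credit for ties, with
DeLong asymptotic CIs and the paired DeLong test; AUPRC is the
interpolation-free step sum (estimator unstated in the protocol); the
paired bootstrap resamples rows and takes a two-sided add-one percentile
p-value of zero in the replicate difference distribution. The Wilcoxon
paired signed-rank test reports r = |Z|/sqrt(N) signed by the median
difference (the protocol's methods text says rank-sum while its table
legend specifies the paired signed-rank with per-patient pairing; the
paired test is implemented since the pairing is explicit). The
four-detector comparison family uses a strict Bonferroni gate at
p < 0.05/4 = 0.0125.

## The synthetic world

The generator's defaults are the stated conditions of the study design
wherever one exists, and one-time realism choices elsewhere:

* SOZ prevalence 0.168 (the training cohort's 822/4,905); epochs of 5 or
  20 minutes at 1,000 Hz; subdural arrays (60 contacts) plus a depth shaft
  of >= 4 contacts so bipolar pairing is well defined.
* Background: pink noise (10 uV RMS) plus one ~1.1 Hz slow wave (40 uV),
  standing in for non-REM sleep; the published study never specifies
  background statistics. In-band (80–500 Hz) background RMS is ~5 uV.
* Three event classes — Hann-windowed oscillation (90–300 Hz, 20–80 ms),
  broadband spike (biphasic transient plus enveloped 80–400 Hz noise burst,
  40–80 ms), and their superposition — with SOZ sites receiving higher
  rates, higher amplitudes, and a larger spike–oscillation share.
* Class-conditional feature medians follow the published SOZ versus
  non-epileptic contrasts for the Hilbert detector family (rate 2.65 vs
  0.63/min; entropy 0.70 vs 0.65; power 9.11 vs 4.71 uV^2; near-identical
  frequency and duration). Electrode-level spreads are not published;
  rate_sigma = 1.1 (lognormal log-SD) was calibrated once so the realized
  model-level SOZ discriminability of the stated world lands inside the
  published internal AUROC band (0.79–0.85), and morphology spreads are
  set wide enough that occurrence rate remains the dominant feature, as in
  the published effect-size ordering.
* Feature-level electrode sampling adds a per-electrode random effect so
  morphology medians keep between-electrode variance regardless of event
  count — otherwise high-rate electrodes' medians concentrate and
  morphology features become covert rate detectors.
* Outcome: ILAE class 1 is Bernoulli with probability
  `logistic(beta * z)`, where z is the cohort-standardized true biomarker
  difference (mean latent event rate over resected minus preserved
  electrodes) and beta defaults to 2.0; beta can be overridden per
  etiology, which is how the inverted-association subgroup (modelled on
  the encephalomalacia finding) is generated.

What the generator does **not** emulate: spatial clustering of SOZ sites,
volume conduction and shared noise across channels, ictal dynamics,
artifacts, non-stationary sleep architecture, and any dependence of
detector disagreement on physiology. A green test therefore establishes
that the pipeline recovers known structure under a favorable, stationary,
channel-independent world — not clinical performance. The published
patient-data AUROCs are expressly not reproduction targets.

Waveform synthesis at the scale of classifier and outcome experiments
(hundreds of patients) is prohibitive on one CPU, so those experiments use
`sample_feature_cohort`, which draws electrode feature rows directly from
the same generative distributions; the waveform path is exercised end to
end on small cohorts and by the detector/morphology contracts.

## Numerical and degenerate-case conventions

Fixed seeds make every generator and model run byte-reproducible; all
stage seeds derive from one global seed. Zero signals yield zero events.
All-zero spectra have undefined entropy (NaN, warned). Single-sided
resections make side-mean measures NaN (warned, listwise-excluded).
Identical paired scores give p = 1 in both DeLong and bootstrap tests.
Percentile and SD thresholds are strict inequalities, so constant signals
produce no detections. The Bonferroni gate is strict (< 0.0125; the
boundary value is not significant).
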
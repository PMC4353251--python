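# Methods

## Problem and scope

`pbci` reproduces, on fully synthetic data, the analysis pipeline of a
dual-session passive brain-computer interface (pBCI) for binary cognitive
workload assessment: multichannel physiological recordings are reduced to a
37-dimensional feature vector once per second, classifiers are trained on
session 1 and applied as fixed pattern classifiers to session 2, and
performance is quantified with the edge-corrected sensitivity index d′
against empirical null distributions. The package's purpose is to let the
central methodological question — does replacing the electrode montage
between sessions degrade transfer performance? — be exercised as a testable
property under a generative model where the ground truth is known.

## Synthetic recordings

Eight channels are generated at 200 Hz: five EEG sites (Fz, F7, Pz, P7, O2),
bipolar VEOG and HEOG, and bipolar ECG.

* **EEG** is a sum over the five clinical bands (delta 0.5–3, theta 4–7,
  alpha 8–12, beta 13–30, gamma 31–42 Hz) of 4th-order-Butterworth band-pass
  filtered white noise, normalized to unit RMS and scaled by a per-channel,
  per-band amplitude in µV. Band power therefore scales as amplitude², which
  is the oracle used by the spectral-fidelity tests.
* **Blinks** are 350 ms raised-cosine positive deflections (~250 µV, ±15%
  amplitude jitter) injected into VEOG and propagated into the EEG channels
  with fixed frontal-dominant gains (Fz 0.35, F7 0.30, Pz 0.08, P7 0.06,
  O2 0.04). **Saccades** are step–hold–return deflections (~60 µV, 1 s hold)
  in HEOG. Event placement is jittered-regular by default, so event counts
  are exactly rate × duration and count-recovery tests are exact; a Poisson
  mode is available.
* **ECG** is a train of biphasic QRS templates (1 mV R peak, ~90 ms) with
  inter-beat gaps drawn from N(mean IBI, IBI sd) truncated to [300, 2000] ms.

Two workload states differ in exactly four parameters: high workload has
Fz theta amplitude +50%, Pz alpha amplitude −30%, blink rate −5/min
(15 → 10), and mean IBI −100 ms (850 → 750). The magnitudes are free
parameters of the generator (`effect_scale` scales all four); the defaults
were chosen once as plausible moderate-to-strong effects of a demanding
multitask environment, strong enough that a session-transfer classifier is
clearly above chance but not trivially perfect at short trial lengths.

**Electrode replacement** is modeled as a per-session perturbation: channel
gains log-uniform in [1/(1+0.2s), 1+0.2s] at severity s ∈ [0, 1], additive
sensor noise and small row-stochastic cross-mixing of the EEG channels
growing with severity, and DC offsets up to ±5s µV. Severity 0 is the exact
identity. A "remained" subject re-uses session 1's perturbation in session
2; a "replaced" subject draws a fresh one at the same severity.

What the generator does **not** emulate: volume-conduction head geometry,
1/f background spectra, non-stationary drift within or between sessions,
EMG contamination, or task-correlated artifacts. Passing tests therefore
show that the pipeline behaves correctly under its own assumptions, not that
the headline finding holds for real recordings.

## Preprocessing

Ocular artifact is removed from each EEG channel by an exponentially
weighted recursive-least-squares (RLS) adaptive noise canceller with VEOG
and HEOG as reference inputs: M = 3 taps per reference (one joint
6-coefficient weight vector), forgetting factor λ = 0.9999, inverse
correlation matrix initialized to δI with δ = 100. The filter is causal;
with identically zero references it is an exact identity. Filter state is
reset at trial boundaries so trials are independent test units.

## Features (frozen 37-column contract)

Columns, in order: 25 EEG log band powers (channel-major: Fz, F7, Pz, P7,
O2 × delta…gamma, computed on RLS-corrected EEG), 10 EOG log band powers
(VEOG, HEOG × bands, on raw EOG), blink rate, IBI. One row per elapsed
second of each trial.

* **Band powers**: Hanning-window periodogram of each non-overlapping 1 s
  window (1 Hz bins; Parseval-consistent scaling), band power as the sum of
  bins with lo ≤ f ≤ hi times the bin width. At 1 Hz resolution the delta
  band's 0.5 Hz edge first captures the 1 Hz bin. The 1 s estimates are
  averaged over a trailing 10 s window and log10-transformed with a
  1e-12 µV² floor.
* **Blink rate**: causal VEOG detector (adaptive threshold at median +
  4 robust SD, half-amplitude width gate 0.1–0.5 s, return-to-baseline
  requirement that rejects saccade-like steps); counts in the trailing 30 s
  window × 2 give blinks/min.
* **IBI**: Pan-Tompkins-family R-wave detector (5–15 Hz band-pass,
  derivative, squaring, 150 ms integration, adaptive dual thresholds, 200 ms
  refractory, apex refinement on the raw trace); mean of intervals whose
  terminating R falls in the trailing 10 s, with last-valid carry-over.

**Warm-up rule**: output seconds earlier than a full averaging window use
the expanding window of all estimates available so far (band powers, IBI),
or count over the truncated-at-zero trailing window (blink rate). Every
trial of T whole seconds yields exactly T rows, so a 15-min trial gives 900
samples and a two-trial session 1800.

## Learning protocol

Per-feature z-scoring is fitted on the learning set only and re-applied,
with the stored statistics, to the nested and between-session test sets;
constant features fall back to sd 1 (mapping to zero columns). Folds
subsample 90% of the learning session per class without replacement
(1620 of 1800 at full scale); the complement (180) is the nested test set.
Folds differ by random stream, not by partition. The nested-test size
follows from the complement rule; a 10%-of-learning-set reading (162) is
arithmetically inconsistent with the 1800/1620 accounting and was not used.

Four classifier kinds, all trained unweighted on balanced classes:

* **LDA** — pooled-covariance linear discriminant (scikit-learn, SVD
  solver).
* **SVM-LIN / SVM-RBF** — soft-margin SVMs (scikit-learn SVC); cost (and RBF
  kernel coefficient) tuned by Nelder-Mead simplex on log10 parameters
  minimizing inner stratified-CV error (default 5 inner folds, ≤ 50
  iterations). The cost search starts at 1; the RBF coefficient starts at
  1/n_features — in 37 standardized dimensions a coefficient of 1 makes the
  Gram matrix near-diagonal and transfer degenerates to one-class
  predictions, so the conventional scale heuristic is the right origin for
  the simplex.
* **ANN** — 37-input, one sigmoidal hidden layer (20 units), 2 sigmoidal
  output nodes (node 0 = low, node 1 = high), squared-error backpropagation
  with mini-batches of 32, learning rate 0.01, momentum 0.9, ≤ 500 epochs;
  33% of the learning set is held out (stratified) and the weights at
  minimum validation RMSE are kept. Prediction is the larger output node.

Decision-boundary ties (and equal ANN outputs) resolve to low workload —
arbitrary but frozen. All four kinds are deterministic given the seed.

## Evaluation

High workload is the positive class. TPR and FPR use the edge substitutions
0 → 1/n and perfect → (n−1)/n of the respective truth-class denominator, so
both rates live strictly inside (0, 1) and d′ = Φ⁻¹(TPR) − Φ⁻¹(FPR) is
finite for every matrix with at least one member per truth class. The
perfect-rejection substitution for FPR triggers on TN = 0 (the condition
that actually makes the ordinary branch degenerate).

Empirical nulls re-run the identical fold indices and feature matrices with
labels randomly permuted — a uniform permutation of a balanced label vector,
which preserves the class counts — in both the learning and test sets.
Per-subject medians across the k folds summarize each approach; paired
two-tailed t-tests (α = 0.01, Bonferroni over approaches) compare true
medians with matched nulls.

## Saliency

Ruck saliency of input j is the mean over sampled inputs of
Σ_outputs |∂o/∂x_j| for the trained network, evaluated analytically at the
normalized training points (a tractable surrogate for grid sampling, noted
as such). Per-fold vectors are aggregated as (a) mean proportion of summed
saliency and (b) mean ordinal rank with mid-rank ties. The two rankings
answer different questions and may disagree across folds; the report exposes
both without reconciliation.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at desk scale:
120 s trials (240 balanced epochs per session; 90–120 s keeps every feature
window rule exercised), 6–20 subjects depending on the property, k = 10
throughout, 3 inner CV folds / 15 simplex iterations for SVM tuning and 200
ANN epochs. Full-scale sample accounting (900/1800/1620) is verified on one
15-min session. Replacement severity 0.5 is the package's definition of a
moderate perturbation (gains within ±10%, ≤ 2.5% EEG cross-mixing). The
full-vs-EEG-only property is evaluated at `effect_scale` 0.5, where EEG
features are informative but below ceiling, so the peripheral channels'
contribution is measurable.

Degenerate inputs: all-zero windows hit the log floor; constant features
z-score to zero; trials shorter than the longest window, non-finite samples,
unbalanced label vectors, and empty truth classes raise errors rather than
propagate silently.

## Known limitations

* The generator's effect sizes are not calibrated to any real dataset; only
  directions and orders of magnitude are physiologically motivated.
* d′'s robustness to between-session feature shifts (the reason the
  replacement-invariance property holds at moderate severity) depends on the
  shift acting mostly like a criterion change along the discriminant; large
  perturbations that rotate the class geometry would degrade transfer.
* The RLS canceller assumes additive, reference-linear ocular contamination;
  it does not model bidirectional EEG-into-EOG leakage.
* EDF export is not provided (no EDF writer library in the supported
  dependency set); recordings round-trip through long-format CSV, and EDF
  reading is available through mne where installed.
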
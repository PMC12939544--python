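# Methods

This note documents the models, parameters and design choices behind
`eegaffect`: a pipeline for discriminating pathological depression from
transient negative emotion in 8-channel EEG.

## Problem setting

Two affective phenotypes can look alike on a questionnaire but differ
neurophysiologically: a clinically depressed state is a stable, trait-like
disruption of emotional regulation, while a strongly negative emotional
episode in a healthy person is a transient, state-dependent fluctuation.
The pipeline classifies single 7.5 s EEG epochs (8 channels x 960 samples
at 128 Hz; electrodes Fp1, Fp2, F3, F4, F7, F8, C3, C4 of the 10-20
system) into these two classes using three feature families with distinct
physiological rationales:

* **F1, alpha/beta band-power ratio** (8 values, one per channel).
  Alpha (8-13 Hz) reflects cortical inhibition, beta (14-30 Hz) alertness
  and arousal; their ratio is a scale-free index of emotional activation.
* **F2, normalized frontal alpha asymmetry** (8 values). For each channel
  and its homologous mirror, `A = (P_L - P_R) / (P_L + P_R)` on alpha
  power. Under the approach-withdrawal hypothesis, depression shows
  left-frontal hypoactivation (relatively elevated left alpha), making A
  a trait marker. A is computed per channel rather than per pair, so
  `A(left) = -A(right)`; the redundancy is accepted to keep the three
  families channel-aligned (3 x 8 = 24 features).
* **F3, sample entropy** (8 values). SampEn(m=2, r=0.2*SD) quantifies
  time-series irregularity; the "loss of complexity" hypothesis predicts
  lower entropy in depression. With r proportional to the SD, SampEn is
  invariant to affine amplitude changes.

A multi-head additive attention network fuses the 24-vector and outputs a
depression probability.

## Preprocessing

Continuous recordings are band-passed 4-45 Hz (zero-phase Butterworth,
order 5 — chosen so that forward-backward filtering attenuates 1 Hz and
55 Hz by more than 20 dB) and downsampled to 128 Hz (polyphase,
anti-aliased; upsampling is refused). Rated trials are screened for
strongly negative content (valence < 2.5 and arousal < 5 on the 1-9 SAM
scale, both strict), cropped to the steady-state window 15-60 s after
stimulus onset (a 63 s archive trial carries a 3 s pre-trial baseline,
inferred as `duration - 60`), reduced to the 8 analysis channels, and cut
into non-overlapping 7.5 s epochs (trailing remainders discarded;
overlap is a config option defaulting to 0). The majority class is
randomly down-sampled to a strict 1:1 ratio. Artifact removal (ICA,
re-referencing, blink detection) is out of scope: inputs are assumed
pre-cleaned. A 50 Hz notch is unnecessary after the 4-45 Hz band-pass and
is omitted.

No per-epoch amplitude normalization is applied before feature
extraction: F1 and F2 are ratios and F3's tolerance scales with the SD,
so all three families are already scale-free.

## Band power via wavelet packets

A four-level wavelet packet decomposition (WPD) splits 0-64 Hz into
sixteen 4 Hz leaves, returned in frequency (sequency) order. The
transform is periodized and orthogonal, so summed leaf energies equal the
signal energy to machine precision on 960-sample epochs (960 is a
multiple of 2^4; for other lengths padding breaks exactness).

Because 4 Hz leaves do not align with the band table (alpha ends at 13 Hz
mid-leaf), band power is computed by reconstructing the leaves
overlapping `[lo, hi)` and integrating the Welch PSD of that
reconstruction over exactly `[lo, hi)` (1 s Hann windows, 50% overlap,
1 Hz resolution). "Band power" means the integrated total (uV^2), not
the mean density; the distinction only scales F1 by a constant
(bandwidth ratio) and is recorded in the JSON sidecar.

The default mother wavelet is **db16**. Shorter filters leak heavily at
this leaf granularity: with db4 only 82% of a 10 Hz sine's energy stays
in the alpha-overlapping leaves (measured), biasing band power down by a
third; db16 retains 99% and reproduces the closed-form sine power 0.5
within 2%. Any orthogonal Daubechies wavelet can be selected in
`FeatureConfig`; non-orthogonal wavelets are refused because the energy
invariant would fail.

## Sample entropy

SampEn is `-ln(A/B)`, where B counts pairs of m-length templates within
Chebyshev distance `r = 0.2 * SD(x)` and A the same for (m+1)-length
templates; template start indices run over `0 .. N-m-1` for both lengths
(so the counts are comparable) and self-matches are excluded. The
vectorized implementation builds the scalar distance matrix once and
AND-reduces shifted slices; the test suite verifies exact count equality
against an independent O(N^2) double loop. Edge rules: a constant series
returns 0 (no variability implies no complexity); if A = 0 the largest
estimable value `ln((N-m)(N-m-1))` is returned instead of infinity so
feature matrices stay finite. Valid series lengths are 100-5000 samples
(m = 2 is unreliable outside that range); epochs have N = 960.

## Statistical screening

Each feature column is screened for a class difference: Mann-Whitney U
for the ratio and asymmetry families (no normality assumption), Welch's
t-test for sample entropy. U counts pairs with `x > y` plus half-ties;
p-values are exact by enumeration when both samples are small (n_x + n_y
<= 12, no ties) and otherwise use the normal approximation with tie and
continuity corrections. Significance is reported at alpha = 0.05 with no
multiple-testing correction (raw per-channel p-values; a
Benjamini-Hochberg option exists, default off). Screening is diagnostic
only — non-significant channels stay in the model.

ROC curves are compared with the DeLong test: mid-rank AUC estimates
(identical to U / (n_pos * n_neg)), covariance from the structural
components, two-sided p from the standard normal. All models are
evaluated on identical stratified folds, so score vectors are paired as
the test requires. Feature importance is permutation importance
(held-out accuracy drop, 20 permutations per column, min-max normalized
so the top feature scores 1.0); it applies uniformly to every model,
unlike attention-weight inspection, which is exposed separately via
`attention_state` and never blended into the importance ranking.

## The attention classifier

Input is the 24-vector (z-scored with training-split statistics by
default; the statistics are stored on the model and reapplied at
inference). Each of three heads computes `alpha_h = softmax(W_h x + b_h)`
and rescales the input elementwise, `o_h = alpha_h (*) x`; the
concatenated head outputs (72 dimensions) pass through a dense layer
(16 units, ReLU), dropout 0.4 (training only) and a sigmoid unit.
Training: Adam (lr 0.001, beta1 0.9, beta2 0.999, eps 1e-8), batch size
30, 30 epochs, binary cross-entropy, per-epoch shuffling under a seed;
training is bit-deterministic on one thread. Everything is plain numpy
with hand-written backpropagation, verified against central finite
differences (norm-relative error < 1e-4 per parameter tensor).

Two head layouts exist. The default, `full_vector`, lets every head weigh
the full 24-vector: fused dimension 3 x 24 = 72 and attention parameter
count 3 x (24 x 24 + 24) = 1800. The alternative `subspace` layout gives
each head only its 8-wide family block (fused dimension 24, 216 attention
parameters). The full-vector reading is the default because it is the
only one consistent with both a 72-dimensional fusion and a ~1.8k
parameter budget; the subspace variant is retained for comparison.

The positive class is depression, so headline precision/recall/F1 refer
to depression detection; per-class and macro values are always emitted.
Cross-validation is stratified 5-fold (80/20), with all per-fold
preprocessing fitted on the training split only.

### Ablation protocol

The ablation compares three variants sharing all head and training
hyperparameters: no attention (the 24-vector feeds the dense head
directly), single-head (one softmax over the full vector, fused dim 24),
and the full multi-head model. The comparison trains **without**
z-scoring: input normalization is this package's addition to the
training recipe, and with it on, the three variants perform identically —
the gated variants' advantage is precisely their ability to rescale
features adaptively during optimization. Ablating under the original
recipe isolates that mechanism; the protocol is config-overridable
(`ablation_params`).

## Reference classifiers

* **SVM with nested cross-validation**: RBF kernel; outer 5-fold
  generalization loop; inner 3-fold grid search over C in
  {0.1, 1, 10, 100} and gamma in {0.001, 0.01, 0.1, 1} by mean validation
  accuracy; features standardized inside each training split. The inner
  indices are recorded in global coordinates so the no-leakage property
  is assertable, and the tests assert it.
* **XGBoost**: logistic objective, depth 3, 200 rounds, learning rate
  0.1, single thread, seeded.
* **RNN**: the 24-vector reshaped to 8 channel steps of 3 features
  (ratio/asymmetry/entropy per electrode; the spatial arrangement of
  channels is the sequence axis, with a 3-step domain-wise option), tanh
  recurrent cell (hidden 16), sigmoid head, same Adam/batch/epoch
  settings, hand-written BPTT.

A note on directions: with the nested-CV protocol above the SVM is a
strong baseline. On single-family (asymmetry-only) features it is not
outperformed by XGBoost on the synthetic benchmark — a well-tuned,
standardized RBF SVM has no structural handicap there. What does hold,
for both reference classifiers, is that the 24-feature fusion set beats
any single family, which is the substantive claim behind multi-domain
fusion.

More generally, on this benchmark every competently implemented
classifier (attention network, nested-CV SVM, XGBoost, RNN) converges
near the cohort's attainable accuracy, so between-model orderings sit
inside seed noise and the package does not assert them; the DeLong
comparison in the metrics report quantifies exactly this. The one
contrast that does reproduce mechanistically is the attention ablation
under the original training recipe.

## The synthetic cohort generator

The generator exists so the full pipeline is testable without any data
download. Each epoch is a sum of band-limited oscillators plus an AR(1)
background, per channel:

* Oscillators: per band, 5 sinusoids at frequencies drawn uniformly
  in-band with random phases, normalized so a band of amplitude a
  contributes mean-square power a^2/2 regardless of the sinusoid count.
  This keeps band power analytically attributable (no filtered-noise
  ambiguity).
* Background: stationary AR(1) with lag-1 coefficient `regularity` and
  SD `noise_sd`. Higher regularity means a smoother background and lower
  sample entropy, without touching the oscillator band structure.
* Asymmetry: alpha amplitude scaled by (1 + c) on left channels
  (Fp1, F3, F7, C3) and (1 - c) on right channels.

Class presets (frozen defaults):

| parameter | depression | negative emotion |
|---|---|---|
| theta/alpha/beta/gamma amplitude | 0.5 / 0.7 / 1.3 / 0.3 | 0.5 / 1.05 / 1.3 / 0.3 |
| asymmetry coefficient | 0.2 | 0.0 |
| background regularity | 0.8 | 0.2 |
| noise SD | 0.8 | 0.8 |

The directions encode the three target signatures: the negative-emotion
class has a 1.5x higher alpha/beta amplitude ratio, the depression class
a positive left-alpha asymmetry and a smoother background (lower
entropy). Magnitudes are package presets chosen once so the benchmark is
realistic rather than saturated: the default 510-per-class cohort yields
5-fold accuracies in the low-to-mid 0.9 range, comparable to published
EEG depression classifiers, with each feature family class-separable on
at least 7 of 8 channels (Mann-Whitney / Welch p < 0.05 at 100 epochs
per class).

Within-class variability is modelled as shared per-epoch latent states
(trial-level physiology), not per-channel noise, so channel averaging
cannot remove it: lognormal band-amplitude jitter (sigma 0.15), Gaussian
jitter on the asymmetry coefficient (0.05) and regularity (0.2), and
lognormal noise-amplitude jitter (0.3). In addition, a *heterogeneous
expression* gate g ~ Uniform(0,1) trades the spectral signature against
the asymmetry signature within each epoch (effective asymmetry scaled by
2g, the alpha amplitude's log-deviation from the class-neutral reference
0.857 scaled by 2(1-g)), preserving class means. This emulates the
well-documented heterogeneity of depressive EEG phenotypes — individual
recordings express different subsets of the group-level markers — and it
is what gives input-dependent feature weighting something real to
exploit: without it, the attention variants and the plain dense network
are indistinguishable on this benchmark.

What the generator does **not** emulate: ocular/EMG artifacts, electrode
drift, volume conduction, 1/f broadband structure, subject identity, or
the empirical feature distributions of any real dataset. Passing the
synthetic benchmark therefore demonstrates that the pipeline recovers
class structure of the designed kind at realistic effect sizes — it does
not certify performance on clinical recordings.

## Numerical choices and degenerate inputs

* Welch: 128-sample Hann windows, 50% overlap, density integrated by
  rectangle sum over in-band bins.
* Ratio with zero beta power (possible only for synthetic input): clamped
  to a configured cap (1e6) with a warning. Asymmetry with both alpha
  powers zero: defined as 0 with a warning.
* Constant feature column in screening: p = 1. Zero variance in both
  t-test samples with equal means: t = 0, p = 1.
* Identical score vectors in the DeLong test: z = 0, p = 1 (zero variance
  of the difference).
* Undefined precision/recall (zero denominator): reported as 0 with an
  `undefined` flag, never silently.
* ROC ties: tied scores collapse to one threshold step, making the
  trapezoidal area exactly equal to the mid-rank AUC.
* EDF export maps each channel to the full 16-bit range; round-trip error
  is bounded by one quantization step per channel.

## Known limitations

* The EDF writer emits single-record files only — adequate for epoch
  export, not a general-purpose writer.
* The RNN and attention networks are single-threaded numpy; they are
  faithful and deterministic but not fast on large cohorts.
* Screening p-values are raw; with 24 correlated tests the family-wise
  error is not controlled unless the BH option is enabled.
* The synthetic benchmark shares one generator family between classes;
  distribution shift, subject-level clustering and artifacts are absent,
  so cross-validated accuracy on it is an upper bound on what the same
  features could achieve on comparable real data.
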
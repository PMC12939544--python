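# eegaffect

Discriminating **pathological depression** from **transient negative
emotion** in 8-channel EEG: wavelet-packet multi-domain feature
extraction, statistical feature screening, and a lightweight multi-head
additive attention classifier, with reference classifiers, ablations and
paired ROC comparisons.

The package is aimed at researchers in affective computing and
computational psychiatry who want a complete, reproducible, testable
implementation of this analysis — including a seeded synthetic EEG
generator, so every stage runs and is verified without downloading any
clinical dataset. Real recordings (EDF, or preprocessed per-subject trial
archives with valence/arousal ratings) are supported through the same
interfaces.

## The analysis

Each 7.5 s epoch (8 channels — Fp1, Fp2, F3, F4, F7, F8, C3, C4 — at
128 Hz, 960 samples) is summarized by 24 features, three families of
eight:

* **F1** `ratio_<ch>` — alpha/beta band-power ratio per channel. A
  four-level wavelet packet decomposition splits 0–64 Hz into sixteen
  4 Hz leaves; leaves overlapping a band are reconstructed and the Welch
  PSD of the reconstruction is integrated over the exact band
  (α = [8, 13) Hz, β = [14, 30) Hz).
* **F2** `asym_<ch>` — normalized frontal alpha asymmetry
  `(P_α(ch) − P_α(mirror)) / (P_α(ch) + P_α(mirror))` over homologous
  pairs (Fp1↔Fp2, F3↔F4, F7↔F8, C3↔C4).
* **F3** `sampen_<ch>` — sample entropy, SampEn(m = 2, r = 0.2·SD):
  −ln(A/B) over Chebyshev template matches, a complexity measure that is
  lower for more regular signals.

Features are screened per channel (Mann–Whitney U for F1/F2, Welch t for
F3, α = 0.05, diagnostic only), then classified by a multi-head additive
attention network: three heads each compute `α_h = softmax(W_h x + b_h)`
and rescale the 24-vector elementwise; the concatenated 72-dimensional
fusion passes through a dense layer (16 units, ReLU), dropout 0.4 and a
sigmoid output. Training is Adam (lr 0.001, batch 30, 30 epochs, binary
cross-entropy), evaluated with stratified 5-fold cross-validation.
Baselines (nested-CV RBF SVM, XGBoost, a vanilla RNN over channel-ordered
features) run on identical folds so ROC curves can be compared with the
DeLong test.

## Worked example

Run the full synthetic study (generate a 1020-epoch cohort, extract
features, screen, train, ablate, run baselines, write reports):

```bash
eegaffect run --seed 1 --out-dir artifacts --n-per-class 510
```

or from Python:

```python
from eegaffect import (
    default_cohort, build_feature_matrix,
    MultiHeadAttentionClassifier, cross_validate_model,
)
from eegaffect.report import aggregate_reports

X, y = build_feature_matrix(default_cohort(510, seed=1))
reports = cross_validate_model(MultiHeadAttentionClassifier(), X.to_numpy(), y, k=5, seed=1)
agg = aggregate_reports(reports)
print(f"accuracy {agg['accuracy_mean']:.3f} +/- {agg['accuracy_sd']:.3f}, "
      f"AUC {agg['auc_mean']:.3f}")
```

On the default synthetic benchmark this prints accuracy in the low 0.9s
(one run: `accuracy 0.924 +/- 0.012, AUC 0.980`): 510 epochs per class,
204 held-out samples per fold, with each of the three feature families
separating the classes on at least 7 of 8 channels. The artifact directory contains `features.csv`
(the 1020 × 24 matrix plus labels), `screening.csv` (per-channel test
statistics and p-values), `metrics.json` (per-fold and aggregate
accuracy/precision/recall/F1/AUC for every model, pooled confusion
counts, DeLong comparisons), `importance.csv` (normalized permutation
importance, top feature = 1.0) and ROC/confusion figures. Reruns with the
same seed are byte-identical.

Interpreting the outputs: the depression class is the positive label, so
headline precision/recall/F1 refer to depression detection; per-class and
macro variants are always included. The ablation block of `metrics.json`
compares multi-head / single-head / no-attention variants under identical
hyperparameters (trained, like the original recipe, without input
normalization — see `docs/methods.md`); on the default benchmark the
multi-head model comes out on top and no-attention last.

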
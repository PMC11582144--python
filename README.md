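# sadfmri

Semi-supervised automatic detection (SAD) of BOLD activations in
high-temporal-resolution fMRI voxel time-series.

## The problem

First-level fMRI analysis usually asks, voxel by voxel, "did this time-series
contain a hemodynamic response?" The standard answer fits an assumed
hemodynamic response function (HRF) in a general linear model (GLM) and
thresholds a t- or F-statistic. When the true response is shifted, reshaped
or small — which fast sampling (effective TR in the tens of milliseconds,
e.g. 75 ms stimulus-locked windows) makes very visible — the assumed model
mismatches the data and sensitivity drops.

`sadfmri` implements a model-free alternative for users of such
high-temporal-resolution (HiHi-style) data: a compact bidirectional LSTM
classifier trained without manual labels.

## The method

For a voxel series `x_v` of length `T`, the summed sample autocorrelation

    SA_v = sum_{i=0}^{h_max} rho_v(i),
    rho_v(i) = sum_{k=0}^{T-1-i} (x[k+i]-x̄)(x[k]-x̄) / (Var(x_v) · (T-i))

is near 1 for temporally random baseline signal and large for a structured
hemodynamic response (`h_max` = 19 lags by default). The pipeline:

1. **Self-labelled initialization.** A tail fraction `alpha` is chosen by
   minimising `(E[SA | SA ≥ q_{1−α/2}] − E[SA | SA ≤ q_{α/2}]) / range(SA) + α`
   (a tail-value-at-risk trade-off); voxels above `q_{1−α/2}(SA)` are
   labelled activated, voxels below `q_{α/2}(SA)` baseline, classes balanced.
2. **Iterative pseudo-labelling.** A Bi-LSTM (bidirectional hidden sizes
   15/10/3, batch normalization, sigmoid head — 4734 trainable parameters)
   is trained with Adam (lr 1e-3, batch 32, 50 epochs) on the pool. Unseen
   voxels are scored with `P_pred = P_NN / (1 + exp(−SA_v))`; scores above a
   confidence level `c = 0.98` (below `1 − c`) contribute up to 500 new
   class-1 (class-0) pseudo-labels per round. New samples are split 70/30
   into train/validation; the loop stops when a round adds fewer than 500
   class-1 labels, and the lowest-validation-loss checkpoint is kept.
3. **Decision.** A voxel is called activated when `P_pred > 0.5`.

GLM comparators (canonical double-gamma t-test, canonical + temporal and
dispersion derivatives F-test, FIR boxcar F-tests with 10 or 20 boxes) and a
Bonferroni family-wise error threshold are included, together with a
synthetic generator of labelled HiHi-style windows and the repeated
equal-class-subsampling evaluation protocol (TPR, TNR, PPV, ACC, F1, FNR,
FPR, FDR, FOR, AUC).

## Worked example

```python
import sadfmri as sf

train = sf.generate(sf.SyntheticSpec(n_active=150, n_baseline=1350,
                                     amplitude_pct=2.0, seed=5))
test = sf.generate(sf.SyntheticSpec(n_active=300, n_baseline=300,
                                    amplitude_pct=2.0, seed=6))

clf = sf.SadClassifier(alpha=0.10, epochs=100, max_iterations=3,
                       per_class_add=50, allow_unsafe_confidence=True,
                       random_state=0)
clf.fit(train.series.values)          # no labels used
print(f"alpha = {clf.alpha_:.3f}, pool = {len(clf.pool_ids_)} voxels, "
      f"validation loss = {clf.val_losses_[-1]:.4f}")

p_pred = clf.decision_function(test.series.values)
m = sf.confusion_metrics(p_pred, test.truth, threshold=0.5)
print(f"TPR = {m.TPR:.3f}, TNR = {m.TNR:.3f}, AUC = {m.AUC:.4f}, F1 = {m.F1:.3f}")
```

prints

```
alpha = 0.100, pool = 150 voxels, validation loss = 0.1607
TPR = 0.963, TNR = 1.000, AUC = 0.9993, F1 = 0.981
```

The classifier was fitted on 1500 unlabelled series (10% of which truly
carry a 2% response), self-labelled its 150-voxel initialization pool from
the SA tails, and on 600 held-out series detects 96% of true activations
with no false positives; the AUC close to 1 says the regularized scores of
the two classes barely overlap.

A `sad` command-line tool wraps the same pipeline
(`sad simulate | init | train | predict | glm | evaluate | bench-resolution
| compare-glm`); run `sad --help` for details.

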
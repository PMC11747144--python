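# Methods

## Scope and input boundary

The pipeline consumes an *already normalized* beta-value matrix
(probes × samples, values in [0, 1], missing entries permitted). Raw-array
normalization (functional normalization and relatives) requires control-probe
intensities from IDAT files that a beta matrix no longer carries; it is an
upstream responsibility and deliberately out of scope. For the same reason
detection p-values are unavailable, so "poorly performing" probes are
operationalized as probes whose missing fraction exceeds a threshold
(default 0.10 per probe, 0.10 per sample). These defaults are declared
choices, not reconstructions of any particular laboratory protocol.

Matrix orientation is an explicit argument to the loader; auto-detection is
never attempted because probe and sample counts can both be large and a
silent transposition is unrecoverable downstream.

## QC filters

Probes are removed in a fixed order — unannotated → sex chromosome → SNP
overlap → missingness — and each probe is attributed to the *first* rule it
fails, making filter reports reproducible. Samples failing the missingness
threshold are removed after probes. An all-removed axis raises rather than
returning an empty matrix.

## Beta/M transforms

Statistics are computed on the M-value scale,
`M = log2(β′ / (1 − β′))` with `β′ = clip(β, ε, 1 − ε)` and default
`ε = 1e-6`. The transform is strictly increasing and antisymmetric about
β = 0.5; the inverse is `β = 2^M / (1 + 2^M)`, implemented in an
overflow-safe form. Round-tripping is exact to < 1e-9 for β in
[ε, 1 − ε].

## Batch correction

Processing batches (e.g. processing year) are adjusted with parametric
empirical-Bayes location/scale correction — the ComBat model: per probe,
standardize against the batch-size-weighted grand mean and pooled variance;
estimate per-batch location (γ) and scale (δ²); shrink them toward
batch-level priors (normal on γ, inverse-gamma on δ²) by the standard
iterative EB solution (convergence 1e-4); remove the shrunken effects and
restore the grand mean and pooled variance. The implementation agrees with
Bioconductor `sva::ComBat` to ~1e-14 on dense matrices (asserted in the
test suite via Rscript).

Choices worth knowing:

* Correction runs on the M-scale by default (variance stabilization) and is
  back-transformed; a `correction_scale: beta` switch corrects beta values
  directly.
* Missing entries are imputed with the probe mean for estimation and
  re-masked afterwards, so correction never invents values downstream.
* A single batch passes through unchanged (< 1e-8); a batch with fewer than
  two samples is an error naming the batch.
* EB shrinkage means per-probe batch means are not forced exactly to zero:
  the residual between-batch gap is of order `noise_sd·sqrt(2/n_batch)`
  (estimation noise), and the per-probe grand mean is preserved only
  approximately (tested at 0.05 on the M-scale), not to machine precision.

## Feature selection

Two stages: (1) restrict to the union of organ-specific mQTL probe sets for
the requested organs, preserving matrix order; (2) rank by per-probe sample
variance of beta values (denominator n − 1 over non-missing entries; probes
with fewer than two observations get variance 0) and keep the top K
(default 20 000). Ties break lexicographically by probe id, so selection is
deterministic and independent of row order.

`variance_scope` controls leakage: the default `training-only` recomputes
the ranking inside each training split; `full-cohort` ranks once on all
samples, which mirrors a common published protocol but is optimistic for
held-out metrics. The frozen, ordered probe list ships with the model.

## Classifier

A fully connected network — default 20 000 → 1024 → 512 → 6 — with ReLU and
0.5 dropout after each hidden layer (never after the output layer), softmax
probabilities, and cross-entropy loss, trained with mini-batches of 16 for
a fixed 50 epochs. The optimizer is Adam at 1e-3 (β₁ = 0.9, β₂ = 0.999) with
no scheduler and no weight decay — declared defaults for a small MLP, since
nothing forces a particular choice. Weight initialization is He-style
uniform fan-in scaling. All randomness (init, shuffling, dropout masks)
derives from one seeded generator, making runs bit-reproducible on a
platform. Trainable parameters number Σᵢ (dᵢ + 1)·dᵢ₊₁.

Class imbalance handling defaults to none; an `inverse-frequency` loss
weighting is available and errors if a weighted class is absent from the
training labels. Early stopping is off (fixed epochs); optional
best-epoch checkpointing by validation loss exists behind
`checkpoint_best`.

The network is small enough that a compact NumPy implementation (explicit
forward/backward passes) trains in seconds at the scales used here; the
model is frozen to float32 at the end of training so that the on-disk
format — a JSON manifest plus raw little-endian float32 arrays — round-trips
predictions bit-exactly.

Inference imputes missing *values* with per-probe means frozen from the
training data; missing *probes* are an error by default, listing up to 20
offending ids, with an explicit opt-in to substitute training means.

## Evaluation

* **Splits.** Train/validation/test sizes follow an explicit convention:
  `train = floor(f_train·n)`, `test = ceil(f_test·n)`, validation the
  remainder (509 samples at 70/15/15 gives 356/76/77). Stratified
  allocation uses largest-remainder rounding on the class × set quota
  matrix, keeping every class within about one sample of proportionality
  per set.
* **Folds.** Stratified k-fold assignment deals each class's shuffled
  members round-robin over folds ordered by current occupancy, so per-fold
  class counts differ by ≤ 1 and fold sizes stay balanced. A class with
  fewer than k members triggers a warning and lands in distinct folds.
* **Metrics.** Accuracy; top-2 accuracy (true class among the two largest
  probabilities, rank-2 ties broken by class-order position for
  determinism); macro-averaged F1 (unweighted mean over classes of
  2PR/(P + R), 0 when P + R = 0 — note a fold containing no sample of some
  class therefore contributes 0 for that class, which depresses macro-F1
  even under perfect prediction); confusion matrix with true classes as
  rows. "Average" CV metrics are arithmetic means of per-fold values; the
  best fold is the one with the lowest final validation loss.
* Per fold, feature selection, imputation means and the network are fit on
  the training folds only; the held-out fold doubles as the validation
  series for the training history.

## Synthetic cohorts

The generator draws, per probe j and sample i of organ o in batch b:

    M_ij = logit2(μ_j) + s_j·δ·1[j ∈ block(o)] + γ_b
    β_ij ~ Beta(μ′_ij·ν, (1 − μ′_ij)·ν),   μ′ = expit2(M_ij)

with baselines μ_j ~ U(0.1, 0.9), per-probe effect signs s_j ∈ {±1} fixed at
generation, disjoint mQTL blocks of 100 probes per organ, batch shifts
γ_b ~ N(0, 0.5²) (or explicitly injected values), concentration ν = 50
(typical array-scale noise), 1% uniform missingness, and 5% / 2% of probes
placed on sex chromosomes / SNP-flagged (excluded from mQTL blocks) so the
QC filters have real work. Defining effects on the M-scale and
back-transforming keeps β strictly inside (0, 1) without clipping artifacts.

The default cohort is a ~3.4× down-scaled version of a realistic six-organ
carcinoma case mix (breast 42, gyn 27, testis 26, lung 25, kidney 25,
colon 6; 151 samples, 2000 probes), keeping the full 10-fold benchmark to
roughly a minute per run on one CPU. The simulator reproduces mean
structure, batch structure and missingness but *not* genomic CpG
autocorrelation, probe-chemistry (type I/II) effects, FFPE degradation or
tumor purity variation — so passing benchmarks demonstrate that the
pipeline recovers the signal it models, not clinical-grade performance on
real arrays.

Two properties of the default conditions worth stating explicitly:

* With the organ effect removed (δ = 0), a converged classifier predicts
  the empirical class prior, so its accuracy settles at the majority-class
  fraction (breast, 42/151 ≈ 0.278) rather than the balanced-chance 1/6.
* Measured accuracy is monotone non-decreasing in δ across {0, 0.5, 1.5}
  (2-point noise allowance), checked at reduced size (5-fold, 15 epochs).

## Reproducibility

Every stochastic stage takes an explicit seed; the CLI propagates one
global seed and records config hash, seed, package versions and input
checksums in `provenance.json`. Identical config + seed reproduces CV
reports and prediction files byte-for-byte on the same platform
(floating-point reproducibility across BLAS implementations is not
guaranteed).

## Limitations

* The input boundary excludes raw-intensity QC; garbage normalization in,
  garbage out.
* The mQTL catalog is a user-supplied input; results depend entirely on its
  quality and its overlap with the array content.
* The six-class vocabulary is fixed; tumors from other organs will be
  forced into one of the six classes, with the prediction confidence as the
  only guard.
* Macro-F1 under small classes and many folds is conservative by
  construction (zero-F1 convention for empty classes).
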
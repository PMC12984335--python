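# Methods

## Problem setting

Sample-level QC for label-free quantitative proteomics treats each sample's
protein-abundance row as one observation in a very wide, noisy matrix
(hundreds of samples × thousands of proteins) and asks which rows are
technically aberrant. The package follows the dataset-cleaning
(transductive) paradigm: the detector is trained on the full cohort and
scores that same cohort, so no train/test split or anomaly labels are
involved. Evaluation is threshold-free (AUC-ROC, AUC-PR) against known
injected anomalies.

## Preprocessing

1. **Global-minimum imputation.** Every missing cell is filled with the
   smallest observed intensity anywhere in the matrix. The rationale is the
   detection-limit assumption: in LFQ data, absence usually means the signal
   fell below the instrument floor. MaxQuant encodes non-detection as `0`,
   so zeros are treated as missing by default (`zero_as_missing` toggle).
2. **Quantile normalization.** The reference distribution is the
   across-sample mean of within-sample sorted values; each sample's values
   are replaced by reference values at their within-sample ranks. Ties
   receive the mean of the reference values across their rank span, which
   makes the operation deterministic and order-invariant. After this step
   every sample shares the same value multiset (up to tie averaging).
3. **Per-protein z-score (default on).** Quantile-normalized intensities
   still span orders of magnitude across proteins; feeding them raw into a
   squared-error objective would let a handful of high-abundance proteins
   dominate both training and the anomaly score. Each protein column is
   standardized with the population-SD convention (divide by n), chosen and
   documented so unit tests can assert exact values; zero-variance columns
   map to all-zero. The z-score can be disabled (`zscore=False`), and an
   optional `log2` transform is available but off by default since the core
   pipeline is imputation + quantile normalization.

A per-protein-minimum imputation variant was considered (the imputation
could plausibly be read per-protein rather than per-dataset) but the
per-dataset global minimum is implemented as the single supported rule.

## Network

Encoder: two blocks (linear → batch norm → ReLU → dropout), widths
`FeatN → F1 → F2`. Decoder mirrors the encoder (`F2 → F1` block) with a
plain linear output layer `F1 → FeatN` — no batch norm/ReLU on the output so
reconstructions can take negative z-scored values. The MSF pathway splits
`F1` into `G` contiguous equal-width groups; each group passes through its
own `F1/G → F1/G` linear + ReLU ("subspace-specific representation"); the
concatenation `Flocal` (width `F1`) is fused with `Fglobal` through
`ReLU(BN(W[Fglobal ∥ Flocal] + b))` with output width `F2`, so the decoder
is identical across variants and ablations differ only in the pathway under
test. A `local_transform="identity"` option reduces the local pathway to
pure partition-and-concat. The CLS head is a linear softmax classifier on
`Fglobal` with one class per training sample; labels are row indices fixed
before shuffling. The losses are `L_rec` (mean over samples of the squared
error summed over proteins), `L_cls` (categorical cross-entropy), and their
unweighted sum — no tunable weighting is exposed. The cross-entropy is the
standard categorical form over the C instance classes.

The network and backprop are implemented directly in numpy (`mffae._nn`):
linear, batch-norm, ReLU and inverted-dropout layers with hand-written
backward passes and a standard Adam optimizer. A finite-difference oracle in
the test suite pins the analytic gradients to ~1e-9 relative error.

### Hyperparameters

| parameter | default | notes |
|---|---|---|
| lr | 5e-4 | Adam |
| batch_size | 16 | partial final batch kept |
| dropout | 0.2 | after ReLU in every block |
| G (groups) | 8 | requires `F1 % G == 0` |
| F1 / F2 | 512 / 64 | full-scale default |
| F1 / F2 (desk scale) | 64 / 16 | used by the bundled benchmarks |
| epochs | 100 (model default), 150 (benchmark presets) | fixed length, no early stopping |
| dtype | float64 (float32 in benchmark presets) | float32 ≈ halves training cost |

Layer widths, the optimizer, and the epoch count are design choices of this
package (the funnel keeps the bottleneck far below the input dimension);
training length is fixed rather than early-stopped so that runs are exactly
reproducible from the seed. Scoring always runs in eval mode (running
batch-norm statistics, no dropout), so single-sample inference is defined
and two scoring passes agree bit-for-bit.

### Anomaly score

`score_i = ‖x_i − x̂_i‖² / FeatN` — per-feature mean squared reconstruction
error, higher = more anomalous. Note this is the reverse sign convention of
scikit-learn's `OutlierMixin.score_samples`; the estimator documents this.

## Synthetic cohort generator

`generate_matrix` emulates the statistical shape of an LFQ DDA-MS protein
matrix: per-protein log2 means uniform over [18, 34] (a ~16-octave dynamic
range), per-sample log2 shifts (SD 0.25, loading/injection variation),
per-protein log2 noise (SD 0.5) with a shared within-block component, and
missing-at-floor censoring (the lowest `missing_rate` fraction of cells,
default 10%, is masked). Proteins are assigned round-robin to `n_blocks`
correlated blocks, mimicking co-regulated complexes and shared technical
response.

Defaults (300 samples × 2000 proteins, 8 blocks, block correlation 0.9) are
the desk-scale stand-in for a ~300-run QC cohort. The block structure was
calibrated jointly with the desk-scale architecture so that the corruption
benchmark reproduces the difficulty profile of the study design it
implements: near-chance AUC at zero corruption, a hard low-signal regime at
r ≈ 0.01, and saturation (AUC ≥ 0.9 for every variant) by r = 0.30. Two
constraints drive the choices: the latent structure dimension
(8 blocks + 1 sample shift) must fit inside the desk-scale bottleneck
(F2 = 16), and the per-block correlation must be high enough that a
150-epoch fit reaches the regime where reconstruction error is dominated by
the corruption rather than by underfitting.

**What the generator does not emulate:** heavy-tailed and protein-specific
noise, batch effects, peptide-level artifacts, run-order drift, and
realistic (non-block) correlation topology. Passing benchmarks on this
cohort therefore demonstrates that the implementation behaves correctly
under the intended signal model, not that the detector attains any
particular performance on real cohorts.

## Corruption benchmark

- **Grouping:** samples are randomly partitioned into 10 near-equal groups;
  trial *t* treats group *t mod 10* as anomalous (deterministic rotation).
- **Feature shuffle:** for each anomalous sample independently,
  `k = round(r·P)` distinct proteins (at least 1 when r > 0) are selected
  uniformly and the sample's values are permuted across those positions.
  This preserves the sample's value multiset and corrupts feature identity —
  a localized, subtle anomaly. The exact shuffle semantics are an
  interpretation; a `cross_sample` mode (replace each selected cell with the
  same protein's value from a random other sample) is provided behind a flag.
- **Injection scale:** corruption is applied to the fully preprocessed
  (model-visible, z-scored) matrix by default, so a corrupted cell is
  marginally indistinguishable from a normal one and only the broken
  correlation structure betrays it. A `quantile_scale` option injects before
  the z-score, where cross-magnitude swaps also perturb the marginal scale
  and detection becomes drastically easier.
- **Sweeps:** `coarse` = r ∈ {0, 0.01, …, 0.40} (41 values), `fine` =
  r ∈ {0.001, …, 0.020} step 0.001 (20 values), `ablation` = all four
  variants at one ratio, `stability` = training-set subsampling at
  {0.8, 0.9, 1.0} with scoring of the full set. Results are tidy CSV
  records (variant, ratio, trial, seed, auc_roc, auc_pr) aggregated as
  mean ± sample SD (n−1).
- **Seeding:** every stage seed is derived from the master seed through a
  counter-based `SeedSequence` fan-out (strings folded in via CRC32), so a
  fixed master seed reproduces the benchmark CSV bit-for-bit and any stage
  can be re-run independently.

## Metrics

AUC-ROC is the trapezoidal area (equal to the Mann–Whitney statistic with
half-credit for ties; ties are processed as one threshold). AUC-PR is
average precision (step-wise summation) rather than linearly interpolated
PR area, which is known to be optimistic. Both delegate to scikit-learn and
are pinned against brute-force oracles in the tests. KDE diagnostics use a
Gaussian kernel with Silverman's rule-of-thumb bandwidth on a 512-point grid
padded by three bandwidths.

## Differential expression and concordance

Per protein: log2 fold change is the difference of group means on log2-scale
values (the caller supplies log2 data); p-values from Welch's
unequal-variance t-test; Benjamini–Hochberg adjustment; DEP thresholds
adjusted p < 0.01 and |log2FC| > 2 (configurable). Proteins with zero
variance in both groups and equal means receive p = 1 by convention. The
choice of Welch's t-test is a package decision (standard for two-group
comparisons of log intensities) and is isolated behind
`differential_expression` so a moderated test could be substituted.

Concordance between before-QC and after-QC tables is an OLS regression
(after ~ before) on log2FC or −log10 adjusted p over the inner join of
protein IDs, plus the DEP-set overlap count and the overlapped fraction of
the before-QC set. Good QC leaves slope ≈ 1, intercept ≈ 0, R² ≈ 1 and a
near-complete overlap.

Anomaly calling from scores is deliberately a required user decision:
`top_k` (k highest scores, ties broken by score then stable sample order)
or `mad_z` (robust z > 3.5 by default, with the MAD replaced by a small
epsilon times the score range when it is zero so a lone extreme score is
still flagged). Grouped calling (e.g. tumor vs adjacent-normal analyzed
separately) is supported so biological heterogeneity is not mistaken for
technical anomaly.

## Numerical and reproducibility notes

- Parameter initialization: Kaiming-uniform per layer, each submodule on its
  own `SeedSequence` stream, so shared encoder/decoder parameters are
  identical across variants at initialization (this underpins the
  variant-nesting tests).
- Batch norm uses batch statistics in train mode (momentum 0.1, eps 1e-5,
  unbiased running variance) and running statistics in eval mode.
- `l_total == l_rec + l_cls` holds exactly (same floating-point sum) at
  every logged epoch.
- float32 training is available for throughput; scores are accumulated in
  float64. Checkpoints (`.npz` with a JSON header) restore config, instance
  labels, parameters and batch-norm statistics; a reloaded model reproduces
  scores bit-for-bit.
- Problem sizes in the bundled benchmarks (300 × 2000 cohort, 10–20 trials
  per condition, desk-scale widths, 150 epochs) are the package's chosen
  desk-scale study; the full-scale defaults (512/64) are available through
  configuration.

## Known limitations

- The shuffle semantics and injection scale of the original benchmark
  protocol are under-specified; both interpretations are implemented and the
  defaults documented above.
- Instance discrimination scales the classifier head with the cohort size
  (C = N); for very large cohorts a sampled softmax would be needed.
- The generator's block-structured covariance is idealized; real cohorts
  have richer correlation topology and heavier-tailed noise.
- No GPU path; the numpy implementation targets hundreds of samples ×
  thousands of proteins on one CPU.
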
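# mffae — autoencoder QC for label-free proteomics matrices

Technical anomalies in label-free quantitative (LFQ) proteomics are usually
*localized and subtle*: a handful of proteins in one run drift or swap
intensity while the bulk of the profile looks normal. Distance- and
density-based outlier detectors degrade badly in spaces with thousands of
proteins, so sample-level quality control (QC) of MaxQuant-style
`proteinGroups` matrices needs a detector that models both the global
structure of a cohort and fine-grained subspace patterns.

`mffae` implements a **multi-scale feature-fusion autoencoder (MFF-AE)** for
this problem, together with the full evaluation harness: preprocessing,
synthetic-cohort generation, a feature-shuffle corruption benchmark, and
downstream differential-expression concordance analysis. It is aimed at
proteomics/metabolomics analysts who have a wide samples × proteins intensity
matrix and want a reproducible, threshold-free way to rank samples by
technical abnormality.

## The model

Each sample `x ∈ R^FeatN` (its protein-abundance row) passes through a
two-block encoder (linear → batch-norm → ReLU → dropout per block):

    F1      = enc1(x)            # shallow representation, width F1
    Fglobal = enc2(F1)           # bottleneck, width F2

The multi-scale fusion (MSF) pathway partitions `F1` into `G` contiguous
subspaces, applies a small per-group linear+ReLU projection, concatenates the
results into `Flocal`, and fuses:

    Ffusion = ReLU(BN(W [Fglobal ∥ Flocal] + b))

The decoder mirrors the encoder and reconstructs `x̂` from `Ffusion`. A
class-specific identification (CLS) head — a linear softmax classifier over
`Fglobal` with **one class per training sample** (instance discrimination) —
regularizes training. The objective is the unweighted sum

    L_total = L_rec + L_cls,     L_rec = (1/N) Σ_i ‖x_i − x̂_i‖²

The classifier is used only during training. The anomaly score of a sample is
its per-protein mean squared reconstruction error in eval mode; higher means
more anomalous. Four variants isolate each component: `SAE` (plain
autoencoder), `AE_CLS` (+classifier), `AE_MSF` (+fusion), `MFF_AE` (both).

Training is transductive (dataset cleaning): the model is fitted on the full
sample set and scores that same set. Default hyperparameters: learning rate
5e-4, batch size 16, dropout 0.2, `G = 8` feature groups, Adam.

## Worked example

```python
import numpy as np
from mffae import (SyntheticSpec, generate_matrix, preprocess_pipeline,
                   MffaeDetector, LabeledScores, auc_roc,
                   assign_groups, inject_feature_shuffle)

base = generate_matrix(SyntheticSpec(n_samples=300, n_proteins=2000, seed=0))
clean, report = preprocess_pipeline(base)        # impute -> quantile norm -> z-score
print(report.n_imputed)                          # 60000 (10% missing-at-floor cells)

groups = assign_groups(300, n_groups=10, seed=1)
ds = inject_feature_shuffle(clean, np.flatnonzero(groups == 0), r=0.30, seed=2)

det = MffaeDetector(variant="MFF_AE", epochs=150, dtype="float32", seed=3)
scores = det.fit_score(ds.matrix.values)
print(round(auc_roc(LabeledScores(scores, ds.labels)), 3))   # 0.951
```

The second printed number is the AUC-ROC of the reconstruction-error ranking
against the known corrupted group: at a 30% shuffle ratio the detector
separates the 30 corrupted samples from the 270 normal ones almost perfectly.
At `r=0.01` (20 of 2000 proteins shuffled) the task becomes genuinely hard —
AUC-ROC drops toward ~0.5–0.6 and the fusion and instance-discrimination
modules are what keeps MFF-AE ahead of the plain autoencoder.

The same workflow is available from the shell:

```sh
mffae simulate --seed 0 --outdir out
mffae preprocess out/synthetic.tsv --outdir out
mffae qc out/preprocessed.tsv --seed 3 --outdir out --call mad_z
mffae benchmark --preset ablation --seed 1 --outdir out
mffae de log2_matrix.tsv groups.tsv --exclude out/flagged_samples.txt --outdir out
```

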
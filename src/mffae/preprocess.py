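"""Preprocessing pipeline: global-minimum imputation, quantile normalization,
optional log2 and per-protein z-scoring.

The two-stage pipeline (impute with the smallest observed intensity anywhere
in the matrix, then force every sample onto the across-sample mean-of-sorted
reference distribution) is the standard preparation for feeding label-free
protein quantification matrices to a reconstruction model. A per-protein
z-score is applied on top by default so that no single high-abundance protein
dominates the squared-error objective.

Transformers follow the scikit-learn estimator contract (``fit`` /
``transform`` / ``get_params``) and operate on plain 2-D arrays with NaN as
the missing sentinel; :func:`preprocess_pipeline` composes them over
:class:`~mffae.matrix.AbundanceMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import AbundanceMatrix

__all__ = [
    "PreprocessReport",
    "GlobalMinImputer",
    "QuantileNormalizer",
    "FeatureStandardizer",
    "impute_global_min",
    "quantile_normalize",
    "standardize_features",
    "preprocess_pipeline",
]


@dataclass
class PreprocessReport:
    """Provenance record of one preprocessing step or pipeline."""

    n_imputed: int = 0
    global_min: float = float("nan")
    reference_quantiles: np.ndarray | None = None
    scaling: str = "none"
    log2: bool = False
    steps: list[str] = field(default_factory=list)


class GlobalMinImputer(TransformerMixin, BaseEstimator):
    """Fill missing (NaN) cells with the global minimum observed anywhere.

    The detection-limit rationale: in LFQ data a missing intensity most often
    means the protein fell below the instrument floor, so the smallest value
    seen in the whole matrix is the least-biased stand-in.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        observed = X[~np.isnan(X)]
        if observed.size == 0:
            raise ValueError("cannot impute: every cell is missing")
        self.global_min_ = float(observed.min())
        return self

    def transform(self, X):
        check_is_fitted(self, "global_min_")
        X = np.asarray(X, dtype=float).copy()
        self.n_imputed_ = int(np.isnan(X).sum())
        X[np.isnan(X)] = self.global_min_
        return X


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile-normalize each sample (row) onto a common reference distribution.

    ``fit`` computes the reference as the across-sample mean of within-sample
    sorted values; ``transform`` replaces each row by reference values at the
    row's within-sample ranks. Tied values receive the mean of the reference
    values across their rank span, so the operation is deterministic and
    invariant to input order.
    """

    def fit(self, X, y=None):
        X = self._validate(X)
        self.reference_quantiles_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_quantiles_")
        X = self._validate(X)
        ref = self.reference_quantiles_
        if X.shape[1] != ref.shape[0]:
            raise ValueError(
                f"matrix has {X.shape[1]} proteins but the reference has {ref.shape[0]}"
            )
        # cumulative mean of the reference turns an average rank into the mean
        # of the reference values the tie block spans
        csum = np.concatenate([[0.0], np.cumsum(ref)])
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            row = X[i]
            lo = rankdata(row, method="min") - 1          # first index of tie block
            hi = rankdata(row, method="max")              # one past last index
            out[i] = (csum[hi] - csum[lo]) / (hi - lo)
        return out

    @staticmethod
    def _validate(X):
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("matrix contains missing values; impute before quantile normalization")
        return X


class FeatureStandardizer(TransformerMixin, BaseEstimator):
    """Per-protein (column) z-score with the population SD convention.

    Zero-variance columns are mapped to all-zero rather than left undefined.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("matrix contains missing values; impute before standardization")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)  # ddof=0: population SD, exact for tests
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        scale = np.where(self.scale_ == 0.0, 1.0, self.scale_)
        out = (X - self.mean_) / scale
        out[:, self.scale_ == 0.0] = 0.0
        return out


# ---------------------------------------------------------------------------
# AbundanceMatrix-level wrappers


def impute_global_min(m: AbundanceMatrix) -> tuple[AbundanceMatrix, PreprocessReport]:
    """Fill every missing cell with the matrix-wide minimum observed value."""
    imp = GlobalMinImputer().fit(m.values)
    filled = imp.transform(m.values)
    out = AbundanceMatrix(m.sample_ids, m.protein_ids, filled, np.zeros(m.shape, dtype=bool))
    report = PreprocessReport(
        n_imputed=imp.n_imputed_, global_min=imp.global_min_, steps=["impute_global_min"]
    )
    return out, report


def quantile_normalize(m: AbundanceMatrix) -> tuple[AbundanceMatrix, PreprocessReport]:
    """Force each sample's value distribution onto the mean-of-sorted reference."""
    qn = QuantileNormalizer().fit(m.values)
    out = AbundanceMatrix(m.sample_ids, m.protein_ids, qn.transform(m.values))
    report = PreprocessReport(
        reference_quantiles=qn.reference_quantiles_.copy(), steps=["quantile_normalize"]
    )
    return out, report


def standardize_features(m: AbundanceMatrix) -> tuple[AbundanceMatrix, PreprocessReport]:
    """Per-protein z-score (population SD); constant proteins become all-zero."""
    st = FeatureStandardizer().fit(m.values)
    out = AbundanceMatrix(m.sample_ids, m.protein_ids, st.transform(m.values))
    return out, PreprocessReport(scaling="zscore", steps=["standardize_features"])


def preprocess_pipeline(
    m: AbundanceMatrix, log2: bool = False, zscore: bool = True
) -> tuple[AbundanceMatrix, PreprocessReport]:
    """Default pipeline: impute -> (optional log2) -> quantile normalize -> z-score.

    ``log2`` is off by default: quantile normalization already collapses the
    dynamic range onto a shared reference, and the z-score handles scale.
    """
    out, rep = impute_global_min(m)
    steps = list(rep.steps)
    if log2:
        if (out.values <= 0).any():
            raise ValueError("log2 requires strictly positive intensities")
        out = AbundanceMatrix(out.sample_ids, out.protein_ids, np.log2(out.values))
        steps.append("log2")
    out, qrep = quantile_normalize(out)
    steps.extend(qrep.steps)
    scaling = "none"
    if zscore:
        out, _ = standardize_features(out)
        steps.append("standardize_features")
        scaling = "zscore"
    return out, PreprocessReport(
        n_imputed=rep.n_imputed,
        global_min=rep.global_min,
        reference_quantiles=qrep.reference_quantiles,
        scaling=scaling,
        log2=log2,
        steps=steps,
    )
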
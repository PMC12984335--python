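"""Differential expression and before/after-QC concordance analysis.

The biological-validation stage of sample QC: call differentially expressed
proteins (DEPs) between two sample groups, repeat after excluding flagged
anomalous samples, and quantify how much the exclusion moved the effect-size
and significance landscape. Good QC should leave slope ~ 1, intercept ~ 0
and R^2 ~ 1 in the after-vs-before regression and a near-complete overlap of
the two DEP sets — outliers removed, biology untouched.

Per protein: log2 fold change is a difference of log2-scale group means,
the p-value comes from Welch's unequal-variance t-test, multiplicity is
controlled with Benjamini-Hochberg, and a DEP is declared at adjusted
p < 0.01 and |log2FC| > 2 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import AbundanceMatrix

__all__ = [
    "DeTable",
    "ConcordanceResult",
    "differential_expression",
    "bh_adjust",
    "concordance",
    "call_anomalies",
]

DEFAULT_ADJ_P = 0.01
DEFAULT_ABS_LOG2FC = 2.0


@dataclass
class DeTable:
    protein_ids: list[str]
    log2fc: np.ndarray
    p_value: np.ndarray
    adj_p: np.ndarray
    is_dep: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "log2fc": self.log2fc,
                "p_value": self.p_value,
                "adj_p": self.adj_p,
                "is_dep": self.is_dep,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DeTable":
        return cls(
            list(df["protein_id"].astype(str)),
            df["log2fc"].to_numpy(float),
            df["p_value"].to_numpy(float),
            df["adj_p"].to_numpy(float),
            df["is_dep"].to_numpy(bool),
        )


@dataclass
class ConcordanceResult:
    slope: float
    intercept: float
    r_squared: float
    n_overlap: int
    overlap_fraction: float


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    m: AbundanceMatrix,
    group_a,
    group_b,
    adj_p_threshold: float = DEFAULT_ADJ_P,
    abs_log2fc_threshold: float = DEFAULT_ABS_LOG2FC,
) -> DeTable:
    """Per-protein Welch t-test between two sample groups on log2-scale values.

    ``group_a`` / ``group_b`` are disjoint collections of sample IDs, each of
    size >= 2. Values are assumed to already be on log2 scale, so the fold
    change is ``mean_A - mean_B``. Proteins with zero variance in both groups
    and equal means get p = 1 by convention.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    index = {s: i for i, s in enumerate(m.sample_ids)}
    missing = [s for s in group_a + group_b if s not in index]
    if missing:
        raise ValueError(f"unknown sample IDs: {missing}")
    if m.missing_mask.any():
        raise ValueError("matrix contains missing cells; impute first")
    a = m.values[[index[s] for s in group_a]]
    b = m.values[[index[s] for s in group_b]]
    log2fc = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    # degenerate proteins (zero variance in both groups): t undefined -> NaN;
    # identical means get p = 1, a true constant offset gets p -> 0
    degenerate = np.isnan(p)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.where(np.isnan(p), np.finfo(float).tiny, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    adj = bh_adjust(p)
    is_dep = (adj < adj_p_threshold) & (np.abs(log2fc) > abs_log2fc_threshold)
    return DeTable(list(m.protein_ids), log2fc, p, adj, is_dep)


def concordance(before: DeTable, after: DeTable, metric: str = "log2fc") -> ConcordanceResult:
    """OLS regression of the after-QC metric on the before-QC metric.

    ``metric`` is ``log2fc`` or ``neglog10_adj_p``. Tables are inner-joined on
    protein ID; the DEP-overlap statistics count proteins flagged in both
    tables, with the fraction taken relative to the before-QC DEP set.
    """
    if metric not in ("log2fc", "neglog10_adj_p"):
        raise ValueError("metric must be 'log2fc' or 'neglog10_adj_p'")
    bf, af = before.to_frame().set_index("protein_id"), after.to_frame().set_index("protein_id")
    shared = bf.index.intersection(af.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared proteins")
    bf, af = bf.loc[shared], af.loc[shared]
    if metric == "log2fc":
        x, y = bf["log2fc"].to_numpy(), af["log2fc"].to_numpy()
    else:
        x = -np.log10(bf["adj_p"].to_numpy())
        y = -np.log10(af["adj_p"].to_numpy())
    fit = stats.linregress(x, y)
    dep_before = set(shared[bf["is_dep"].to_numpy(bool)])
    dep_after = set(shared[af["is_dep"].to_numpy(bool)])
    n_overlap = len(dep_before & dep_after)
    frac = n_overlap / len(dep_before) if dep_before else float("nan")
    return ConcordanceResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_overlap=n_overlap,
        overlap_fraction=frac,
    )


def call_anomalies(
    scores,
    method: str = "mad_z",
    param: float = 3.5,
    sample_ids=None,
    groups=None,
):
    """Turn anomaly scores into a flagged sample set.

    ``top_k`` flags the ``param`` highest-scoring samples (ties broken by
    score, then by stable input order). ``mad_z`` flags samples whose robust
    z-score ``(score - median) / (1.4826 * MAD)`` exceeds ``param``; when the
    MAD is zero it is replaced by a small epsilon times the score range so a
    lone extreme score is still flagged. With ``groups`` given (one label per
    sample), calling runs independently within each group — the per-tissue
    workflow that keeps biological heterogeneity from masquerading as
    technical anomaly.

    Returns the flagged entries of ``sample_ids`` (indices if not given).
    """
    scores = np.asarray(scores, float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    ids = list(sample_ids) if sample_ids is not None else list(range(len(scores)))
    if len(ids) != len(scores):
        raise ValueError("sample_ids length mismatch")
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != len(scores):
            raise ValueError("groups length mismatch")
        flagged: list = []
        for g in pd.unique(groups):
            sel = np.flatnonzero(groups == g)
            flagged.extend(
                call_anomalies(scores[sel], method=method, param=param,
                               sample_ids=[ids[i] for i in sel])
            )
        return [i for i in ids if i in set(flagged)]

    if method == "top_k":
        k = int(param)
        if k <= 0:
            return []
        k = min(k, len(scores))
        # sort by (-score, stable input position): ties go to earlier samples
        order = np.lexsort((np.arange(len(scores)), -scores))
        keep = sorted(order[:k])
        return [ids[i] for i in keep]
    if method == "mad_z":
        med = np.median(scores)
        mad = np.median(np.abs(scores - med))
        if mad == 0.0:
            span = np.ptp(scores)
            mad = 1e-9 * span if span > 0 else 1e-9
        z = (scores - med) / (1.4826 * mad)
        return [ids[i] for i in np.flatnonzero(z > param)]
    raise ValueError("method must be 'top_k' or 'mad_z'")
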
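"""Synthetic proteomics matrices and the feature-shuffle corruption benchmark.

The generator emulates the statistical shape of a label-free DDA-MS protein
quantification matrix: per-protein log2 abundance means spread over orders of
magnitude, correlated protein blocks (co-regulated complexes / shared
technical response), per-sample scale shifts (loading differences), and
missing-at-floor values (detection-limit censoring of the lowest
intensities).

The benchmark follows the simulation protocol of the QC study design:
samples are split into near-equal groups, one group per trial is declared
anomalous and corrupted by shuffling a fraction ``r`` of its feature values,
a detector variant is trained transductively on the full corrupted set, and
AUC-ROC / AUC-PR are measured against the known labels. ``r`` is the
difficulty knob: the coarse sweep spans 0-40% in 1% steps, the ultra-fine
sweep 0.1%-2% in 0.1% steps.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix
from .metrics import LabeledScores, auc_pr, auc_roc
from .model import VARIANTS, MffaeDetector
from .preprocess import impute_global_min, quantile_normalize, standardize_features

__all__ = [
    "SyntheticSpec",
    "SimulationSpec",
    "CorruptedDataset",
    "BenchmarkResult",
    "generate_matrix",
    "assign_groups",
    "inject_feature_shuffle",
    "run_sweep",
    "run_stability",
    "coarse_ratios",
    "fine_ratios",
    "DESK_MODEL_PARAMS",
]

# Desk-scale model configuration used by the bundled benchmarks: the small
# layer widths with shortened fixed-length training, sized so a full ablation
# sweep runs on one CPU in minutes.
DESK_MODEL_PARAMS: dict = {"f1_dim": 64, "f2_dim": 16, "epochs": 150, "dtype": "float32"}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic abundance matrix (defaults: desk-scale stand-in
    for a ~300-sample, several-thousand-protein QC cohort)."""

    n_samples: int = 300
    n_proteins: int = 2000
    n_blocks: int = 8
    block_rho: float = 0.9
    log_mean_range: tuple[float, float] = (18.0, 34.0)
    log_sd: float = 0.5
    sample_scale_sd: float = 0.25
    missing_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_proteins, self.n_blocks) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must be in [0, 1)")


@dataclass(frozen=True)
class SimulationSpec:
    """Anomaly-injection recipe for one trial."""

    n_groups: int = 10
    anomaly_group: int = 0
    shuffle_ratio: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shuffle_ratio <= 1.0:
            raise ValueError("shuffle_ratio must be in [0, 1]")
        if not 0 <= self.anomaly_group < self.n_groups:
            raise ValueError("anomaly_group out of range")


@dataclass
class CorruptedDataset:
    matrix: AbundanceMatrix
    labels: np.ndarray
    perturbed_columns: dict[int, np.ndarray]
    spec: SimulationSpec


def generate_matrix(spec: SyntheticSpec) -> AbundanceMatrix:
    """Draw one synthetic samples x proteins abundance matrix.

    Protein ``j`` gets a log2 mean drawn uniformly from ``log_mean_range``;
    cell (i, j) is ``2 ** (mu_j + s_i + log_sd * eps_ij)`` with a shared
    within-block component (``sqrt(rho)``-weighted) inducing the block
    correlation and a per-sample shift ``s_i``. The ``missing_rate`` fraction
    of lowest-intensity cells is masked missing (missing at the floor).
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_proteins
    mu = rng.uniform(*spec.log_mean_range, size=p)
    s = rng.normal(0.0, spec.sample_scale_sd, size=n)
    block_of = np.arange(p) % spec.n_blocks  # round-robin keeps blocks near-equal
    shared = rng.normal(size=(n, spec.n_blocks))
    eps = rng.normal(size=(n, p))
    noise = np.sqrt(spec.block_rho) * shared[:, block_of] + np.sqrt(1 - spec.block_rho) * eps
    log2_vals = mu[None, :] + s[:, None] + spec.log_sd * noise
    values = np.exp2(log2_vals)

    k_missing = int(np.floor(spec.missing_rate * n * p))
    mask = np.zeros((n, p), dtype=bool)
    if k_missing > 0:
        flat = np.argpartition(values, k_missing - 1, axis=None)[:k_missing]
        mask.flat[flat] = True
    sample_ids = [f"S{i:04d}" for i in range(n)]
    protein_ids = [f"P{j:05d}" for j in range(p)]
    return AbundanceMatrix(sample_ids, protein_ids, values, mask)


def assign_groups(n_samples: int, n_groups: int, seed: int) -> np.ndarray:
    """Random partition into near-equal groups (sizes differ by at most 1)."""
    if n_groups > n_samples:
        raise ValueError("more groups than samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_samples)
    groups = np.empty(n_samples, dtype=int)
    for g, part in enumerate(np.array_split(order, n_groups)):
        groups[part] = g
    return groups


def inject_feature_shuffle(
    m: AbundanceMatrix,
    anomaly_rows,
    r: float,
    seed: int,
    mode: str = "within_sample",
    spec: SimulationSpec | None = None,
) -> CorruptedDataset:
    """Corrupt the given rows by shuffling a fraction ``r`` of their features.

    Default (``within_sample``): for each anomalous sample independently,
    ``k = round(r * n_proteins)`` (at least 1 when ``r > 0``) distinct columns
    are selected uniformly and the sample's values are permuted across those
    positions — the sample's value multiset is preserved, feature identity is
    corrupted. ``cross_sample`` instead replaces each selected cell with the
    same protein's value from a random other sample.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must be in [0, 1]")
    if mode not in ("within_sample", "cross_sample"):
        raise ValueError("mode must be 'within_sample' or 'cross_sample'")
    if m.missing_mask.any():
        raise ValueError("corrupt a preprocessed (no-missing) matrix")
    anomaly_rows = np.asarray(sorted(set(int(i) for i in np.asarray(anomaly_rows))))
    if anomaly_rows.size and (anomaly_rows.min() < 0 or anomaly_rows.max() >= m.n_samples):
        raise ValueError("anomaly row index out of range")
    rng = np.random.default_rng(seed)
    p = m.n_proteins
    k = int(round(r * p))
    if r > 0 and k == 0:
        k = 1
    values = m.values.copy()
    perturbed: dict[int, np.ndarray] = {}
    for i in anomaly_rows:
        cols = rng.choice(p, size=k, replace=False) if k else np.array([], dtype=int)
        perturbed[int(i)] = np.sort(cols)
        if k:
            if mode == "within_sample":
                values[i, cols] = values[i, cols][rng.permutation(k)]
            else:
                donors = rng.integers(0, m.n_samples - 1, size=k)
                donors[donors >= i] += 1  # never the sample itself
                values[i, cols] = m.values[donors, cols]
    labels = np.zeros(m.n_samples, dtype=int)
    labels[anomaly_rows] = 1
    out = AbundanceMatrix(m.sample_ids, m.protein_ids, values, np.zeros(m.shape, bool))
    if spec is None:
        spec = SimulationSpec(anomaly_group=0, shuffle_ratio=r, seed=seed)
    return CorruptedDataset(out, labels, perturbed, spec)


@dataclass
class BenchmarkResult:
    """Tidy per-(variant, ratio, trial) AUC records."""

    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["variant", "ratio", "trial", "seed", "auc_roc", "auc_pr"],
        )

    def aggregate(self, by=("variant", "ratio")) -> pd.DataFrame:
        """Mean and sample SD of both AUCs per cell."""
        df = self.to_frame()
        return (
            df.groupby(list(by))[["auc_roc", "auc_pr"]]
            .agg(["mean", lambda v: v.std(ddof=1)])
            .rename(columns={"<lambda_0>": "sd"})
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def coarse_ratios() -> list[float]:
    """0% to 40% in 1% steps (41 values)."""
    return [round(0.01 * i, 2) for i in range(41)]


def fine_ratios() -> list[float]:
    """Ultra-fine sweep: 0.001 to 0.020 in 0.001 steps (20 values)."""
    return [round(0.001 * i, 3) for i in range(1, 21)]


def _derive_seed(*parts) -> int:
    """Deterministic counter-based fan-out from the master seed.

    String parts are folded in via CRC32 (stable across processes, unlike
    built-in ``hash``); the result always fits in 31 bits.
    """
    key = [zlib.crc32(p.encode()) if isinstance(p, str) else int(p) for p in parts]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def _preprocess_base(base: AbundanceMatrix, inject_stage: str) -> AbundanceMatrix:
    """Bring the raw base matrix to the scale corruption is applied on.

    ``model_scale`` (default): the full pipeline — impute, quantile normalize,
    z-score — so the shuffle corrupts exactly what the model sees and a
    shuffled cell is marginally indistinguishable from a normal one (only the
    correlation structure betrays it). ``quantile_scale`` stops before the
    z-score, so cross-magnitude swaps also perturb the marginal scale.
    """
    if inject_stage not in ("model_scale", "quantile_scale"):
        raise ValueError("inject_stage must be 'model_scale' or 'quantile_scale'")
    out, _ = impute_global_min(base)
    out, _ = quantile_normalize(out)
    if inject_stage == "model_scale":
        out, _ = standardize_features(out)
    return out


def _evaluate_variant(
    corrupted: CorruptedDataset, variant: str, seed: int, model_params: dict,
    inject_stage: str,
) -> tuple[float, float]:
    if inject_stage == "model_scale":
        model_x = corrupted.matrix
    else:
        model_x, _ = standardize_features(corrupted.matrix)
    det = MffaeDetector(variant=variant, seed=seed, **model_params)
    scores = det.fit_score(model_x.values)
    ls = LabeledScores(scores, corrupted.labels)
    return auc_roc(ls), auc_pr(ls)


def run_sweep(
    base: AbundanceMatrix,
    ratios,
    n_trials: int = 10,
    variants=("MFF_AE",),
    seed: int = 0,
    n_groups: int = 10,
    model_params: dict | None = None,
    shuffle_mode: str = "within_sample",
    inject_stage: str = "model_scale",
) -> BenchmarkResult:
    """Full corruption benchmark: inject, train transductively, measure AUCs.

    Groups are assigned once from the master seed; trial ``t`` rotates the
    anomalous group to ``t mod n_groups``. Corruption is applied on the
    fully preprocessed (model-visible) scale by default — see
    ``_preprocess_base`` for the alternative. All per-trial randomness is
    derived deterministically from ``seed``.
    """
    variants = tuple(variants)
    unknown = set(variants) - set(VARIANTS)
    if unknown:
        raise ValueError(f"unknown variants {sorted(unknown)}; valid: {VARIANTS}")
    if model_params is None:
        model_params = dict(DESK_MODEL_PARAMS)
    qn = _preprocess_base(base, inject_stage)
    groups = assign_groups(qn.n_samples, n_groups, _derive_seed(seed, "groups"))
    result = BenchmarkResult()
    for ri, r in enumerate(ratios):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"ratio {r} outside [0, 1]")
        for trial in range(n_trials):
            g = trial % n_groups
            sim = SimulationSpec(
                n_groups=n_groups, anomaly_group=g, shuffle_ratio=r,
                seed=_derive_seed(seed, "inject", ri, trial),
            )
            corrupted = inject_feature_shuffle(
                qn, np.flatnonzero(groups == g), r, sim.seed, mode=shuffle_mode, spec=sim
            )
            for vi, variant in enumerate(variants):
                vseed = _derive_seed(seed, "model", ri, trial, vi)
                roc, pr = _evaluate_variant(corrupted, variant, vseed, model_params, inject_stage)
                result.records.append(
                    dict(variant=variant, ratio=r, trial=trial, seed=vseed,
                         auc_roc=roc, auc_pr=pr)
                )
    return result


def run_stability(
    base: AbundanceMatrix,
    training_ratios=(0.8, 0.9, 1.0),
    n_runs: int = 10,
    seed: int = 0,
    shuffle_ratio: float = 0.01,
    variants=("MFF_AE",),
    n_groups: int = 10,
    model_params: dict | None = None,
    inject_stage: str = "model_scale",
) -> BenchmarkResult:
    """Seed/subsample stability: train on a random subsample, score the full set.

    Each run draws a fresh model seed and (for training_ratio < 1) a fresh
    subsample; the fixed low corruption ratio probes the hard regime where
    stability differences matter. ``ratio`` in the result records the
    training ratio.
    """
    if model_params is None:
        model_params = dict(DESK_MODEL_PARAMS)
    qn = _preprocess_base(base, inject_stage)
    groups = assign_groups(qn.n_samples, n_groups, _derive_seed(seed, "groups"))
    result = BenchmarkResult()
    for run in range(n_runs):
        g = run % n_groups
        inj_seed = _derive_seed(seed, "inject", run)
        corrupted = inject_feature_shuffle(
            qn, np.flatnonzero(groups == g), shuffle_ratio, inj_seed,
            spec=SimulationSpec(n_groups=n_groups, anomaly_group=g,
                                shuffle_ratio=shuffle_ratio, seed=inj_seed),
        )
        if inject_stage == "model_scale":
            model_x = corrupted.matrix
        else:
            model_x, _ = standardize_features(corrupted.matrix)
        for ti, t_ratio in enumerate(training_ratios):
            n_sub = int(round(t_ratio * qn.n_samples))
            sub_rng = np.random.default_rng(_derive_seed(seed, "subsample", run, ti))
            idx = (np.arange(qn.n_samples) if n_sub >= qn.n_samples
                   else np.sort(sub_rng.choice(qn.n_samples, size=n_sub, replace=False)))
            for vi, variant in enumerate(variants):
                vseed = _derive_seed(seed, "model", run, ti, vi)
                det = MffaeDetector(variant=variant, seed=vseed, **model_params)
                det.fit(model_x.values[idx])
                scores = det.score_samples(model_x.values)
                ls = LabeledScores(scores, corrupted.labels)
                result.records.append(
                    dict(variant=variant, ratio=t_ratio, trial=run, seed=vseed,
                         auc_roc=auc_roc(ls), auc_pr=auc_pr(ls))
                )
    return result
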
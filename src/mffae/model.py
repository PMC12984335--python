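"""The multi-scale feature-fusion autoencoder (MFF-AE) and its ablations.

Architecture
------------
A two-block encoder maps a sample's protein profile ``x`` (``feat_n`` wide)
to a shallow representation ``F1`` (``f1_dim``) and on to a global bottleneck
``F_global`` (``f2_dim``); each block is linear -> batch norm -> ReLU ->
dropout. The multi-scale fusion (MSF) pathway partitions ``F1`` into ``G``
contiguous subspaces, passes each through its own small linear+ReLU
projection, concatenates them back into ``F_local``, and fuses

    F_fusion = ReLU(BN(W [F_global || F_local] + b))

with ``F_fusion`` sized ``f2_dim`` so the decoder is shared across variants.
The decoder mirrors the encoder (``f2_dim -> f1_dim`` block, then a plain
linear output so reconstructions can take any sign). A class-specific
identification (CLS) head — a linear classifier over ``F_global`` with one
class per training sample — supplies a self-supervised instance-discrimination
loss during training only.

Losses: ``L_rec`` is the mean over samples of the squared reconstruction
error summed over proteins; ``L_cls`` is categorical cross-entropy over the
instance labels; the training objective is the unweighted sum
``L_total = L_rec + L_cls``. The anomaly score of a sample is its per-protein
mean squared reconstruction error in eval mode.

Variants: ``SAE`` (plain autoencoder), ``AE_CLS`` (+classifier),
``AE_MSF`` (+fusion), ``MFF_AE`` (both).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, BatchNorm1d, Block, Linear, Module, ReLU, softmax
from .matrix import AbundanceMatrix

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "ForwardState",
    "LossBundle",
    "MffaeModel",
    "MffaeDetector",
    "build_model",
    "partition_groups",
    "reconstruction_loss",
    "cls_loss",
    "total_loss",
    "train",
    "score",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("SAE", "AE_CLS", "AE_MSF", "MFF_AE")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Defaults follow the published recipe: learning rate 5e-4, batch size 16,
    dropout 0.2, G = 8 feature groups. Layer widths default to a 512 -> 64
    funnel; desk-scale experiments use 64 -> 16.
    """

    feat_n: int
    f1_dim: int = 512
    f2_dim: int = 64
    groups_g: int = 8
    dropout: float = 0.2
    lr: float = 5e-4
    batch_size: int = 16
    epochs: int = 100
    seed: int = 0
    variant: str = "MFF_AE"
    local_transform: str = "linear"  # or "identity": pure partition-and-concat
    dtype: str = "float64"  # "float32" roughly halves training cost

    def __post_init__(self) -> None:
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.f1_dim % self.groups_g != 0:
            raise ValueError(
                f"f1_dim ({self.f1_dim}) must be divisible by groups_g ({self.groups_g})"
            )
        if not (0 < self.f2_dim < self.f1_dim < self.feat_n):
            raise ValueError(
                "layer widths must satisfy 0 < f2_dim < f1_dim < feat_n, got "
                f"f2={self.f2_dim}, f1={self.f1_dim}, feat_n={self.feat_n}"
            )
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.local_transform not in ("linear", "identity"):
            raise ValueError("local_transform must be 'linear' or 'identity'")

    @property
    def has_msf(self) -> bool:
        return self.variant in ("AE_MSF", "MFF_AE")

    @property
    def has_cls(self) -> bool:
        return self.variant in ("AE_CLS", "MFF_AE")


@dataclass
class ForwardState:
    """Intermediate tensors of one forward pass."""

    f1: np.ndarray
    f_global: np.ndarray
    f_local: np.ndarray | None
    f_fusion: np.ndarray | None
    recon: np.ndarray
    cls_logits: np.ndarray | None


@dataclass
class LossBundle:
    l_rec: float
    l_cls: float
    l_total: float


def partition_groups(f1: np.ndarray, g: int) -> list[np.ndarray]:
    """Split ``f1`` along features into ``g`` contiguous equal-width blocks."""
    if f1.shape[1] % g != 0:
        raise ValueError(f"feature width {f1.shape[1]} is not divisible by g={g}")
    w = f1.shape[1] // g
    return [f1[:, k * w:(k + 1) * w] for k in range(g)]


def reconstruction_loss(x: np.ndarray, recon: np.ndarray) -> float:
    """Mean over samples of the squared error summed over features."""
    x, recon = np.asarray(x, float), np.asarray(recon, float)
    if x.shape != recon.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {recon.shape}")
    return float(((x - recon) ** 2).sum(axis=1).mean())


def cls_loss(cls_logits: np.ndarray, instance_labels: np.ndarray) -> float:
    """Mean categorical cross-entropy against instance-index labels."""
    logits = np.asarray(cls_logits, float)
    labels = np.asarray(instance_labels, int)
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise ValueError("instance label out of range")
    p = softmax(logits)
    return float(-np.log(p[np.arange(len(labels)), labels] + 1e-300).mean())


def total_loss(l_rec: float, l_cls: float = 0.0) -> float:
    """Unweighted sum of the reconstruction and instance-discrimination losses."""
    return l_rec + l_cls


class MffaeModel:
    """Concrete network for one :class:`ModelConfig`.

    Submodules exist according to the variant; the classifier head is created
    lazily when the training sample IDs (hence the class count) are known.
    Parameter initialization is deterministic in ``config.seed``: each
    submodule draws from its own stream spawned from the seed, so the shared
    encoder/decoder parameters are identical across variants at init.
    """

    def __init__(self, config: ModelConfig, train_sample_ids: list[str] | None = None):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        keys = ["enc1", "enc2", "dec1", "dec_out", "local", "fusion", "cls", "train"]
        self._rngs = {k: np.random.Generator(np.random.PCG64(s))
                      for k, s in zip(keys, ss.spawn(len(keys)))}
        c = config
        self.enc1 = Block(c.feat_n, c.f1_dim, c.dropout, self._rngs["enc1"])
        self.enc2 = Block(c.f1_dim, c.f2_dim, c.dropout, self._rngs["enc2"])
        self.dec1 = Block(c.f2_dim, c.f1_dim, c.dropout, self._rngs["dec1"])
        self.dec_out = Linear(c.f1_dim, c.feat_n, self._rngs["dec_out"])

        self.local_layers: list[Module] | None = None
        self.fusion_linear: Linear | None = None
        self.fusion_bn: BatchNorm1d | None = None
        self.fusion_relu: ReLU | None = None
        if c.has_msf:
            w = c.f1_dim // c.groups_g
            if c.local_transform == "linear":
                self.local_layers = [Linear(w, w, self._rngs["local"]) for _ in range(c.groups_g)]
                self._local_relus = [ReLU() for _ in range(c.groups_g)]
            self.fusion_linear = Linear(c.f2_dim + c.f1_dim, c.f2_dim, self._rngs["fusion"])
            self.fusion_bn = BatchNorm1d(c.f2_dim)
            self.fusion_relu = ReLU()

        self.classifier: Linear | None = None
        self.train_sample_ids: list[str] | None = None
        if train_sample_ids is not None:
            self.set_train_samples(train_sample_ids)
        self.loss_history: list[LossBundle] = []
        if config.dtype == "float32":
            self._cast(np.float32)

    def _cast(self, dtype) -> None:
        for mod in self.modules():
            for k in mod.params:
                mod.params[k] = mod.params[k].astype(dtype)
                mod.grads[k] = mod.grads[k].astype(dtype)
            if isinstance(mod, BatchNorm1d):
                mod.running_mean = mod.running_mean.astype(dtype)
                mod.running_var = mod.running_var.astype(dtype)

    def set_train_samples(self, sample_ids: list[str]) -> None:
        """Fix the instance-label mapping and create the CLS head (C classes)."""
        self.train_sample_ids = list(sample_ids)
        if self.config.has_cls:
            self.classifier = Linear(
                self.config.f2_dim, len(self.train_sample_ids), self._rngs["cls"]
            )
            if self.config.dtype == "float32":
                for k in self.classifier.params:
                    self.classifier.params[k] = self.classifier.params[k].astype(np.float32)
                    self.classifier.grads[k] = self.classifier.grads[k].astype(np.float32)

    # -- forward / backward -------------------------------------------------

    def modules(self) -> list[Module]:
        mods: list[Module] = (
            self.enc1.modules() + self.enc2.modules() + self.dec1.modules() + [self.dec_out]
        )
        if self.local_layers is not None:
            mods += self.local_layers
        if self.fusion_linear is not None:
            mods += [self.fusion_linear, self.fusion_bn]
        if self.classifier is not None:
            mods.append(self.classifier)
        return mods

    def forward(self, x: np.ndarray, mode: str = "eval") -> ForwardState:
        if mode not in ("train", "eval"):
            raise ValueError("mode must be 'train' or 'eval'")
        train = mode == "train"
        x = np.asarray(x, dtype=self.config.dtype)
        if x.ndim != 2 or x.shape[1] != self.config.feat_n:
            raise ValueError(
                f"input must be (batch, {self.config.feat_n}), got {x.shape}"
            )
        c = self.config
        f1 = self.enc1.forward(x, train)
        f_global = self.enc2.forward(f1, train)

        f_local = f_fusion = None
        if c.has_msf:
            groups = partition_groups(f1, c.groups_g)
            if c.local_transform == "linear":
                outs = [
                    relu.forward(lin.forward(g, train), train)
                    for g, lin, relu in zip(groups, self.local_layers, self._local_relus)
                ]
            else:
                outs = groups
            f_local = np.concatenate(outs, axis=1)
            concat = np.concatenate([f_global, f_local], axis=1)
            f_fusion = self.fusion_relu.forward(
                self.fusion_bn.forward(self.fusion_linear.forward(concat, train), train),
                train,
            )
            latent = f_fusion
        else:
            latent = f_global

        recon = self.dec_out.forward(self.dec1.forward(latent, train), train)

        cls_logits = None
        if c.has_cls and self.classifier is not None:
            cls_logits = self.classifier.forward(f_global, train)

        return ForwardState(f1, f_global, f_local, f_fusion, recon, cls_logits)

    def backward(self, x: np.ndarray, state: ForwardState, labels: np.ndarray | None) -> None:
        """Accumulate gradients of L_total for the batch last passed forward."""
        c = self.config
        n = x.shape[0]
        g_recon = 2.0 * (state.recon - x) / n          # d L_rec / d recon
        g_latent = self.dec1.backward(self.dec_out.backward(g_recon))

        g_f1 = np.zeros_like(state.f1)
        if c.has_msf:
            g_concat = self.fusion_linear.backward(
                self.fusion_bn.backward(self.fusion_relu.backward(g_latent))
            )
            g_global = g_concat[:, : c.f2_dim].copy()
            g_local = g_concat[:, c.f2_dim:]
            w = c.f1_dim // c.groups_g
            for k in range(c.groups_g):
                gk = g_local[:, k * w:(k + 1) * w]
                if c.local_transform == "linear":
                    gk = self.local_layers[k].backward(self._local_relus[k].backward(gk))
                g_f1[:, k * w:(k + 1) * w] += gk
        else:
            g_global = g_latent

        if c.has_cls and state.cls_logits is not None:
            p = softmax(state.cls_logits)
            p[np.arange(n), labels] -= 1.0
            g_global = g_global + self.classifier.backward(p / n)

        g_f1 += self.enc2.backward(g_global)
        self.enc1.backward(g_f1)

    # -- losses --------------------------------------------------------------

    def losses(self, x: np.ndarray, state: ForwardState, labels: np.ndarray | None) -> LossBundle:
        l_rec = reconstruction_loss(x, state.recon)
        l_cls = 0.0
        if self.config.has_cls and state.cls_logits is not None:
            l_cls = cls_loss(state.cls_logits, labels)
        return LossBundle(l_rec, l_cls, total_loss(l_rec, l_cls))


def build_model(config: ModelConfig, train_sample_ids: list[str] | None = None) -> MffaeModel:
    """Construct a model with deterministic seeded initialization."""
    return MffaeModel(config, train_sample_ids)


def _as_array(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, AbundanceMatrix):
        if data.missing_mask.any():
            raise ValueError("data contains missing cells; run the preprocessing pipeline first")
        return data.values, list(data.sample_ids)
    x = np.asarray(data, float)
    if np.isnan(x).any():
        raise ValueError("data contains missing cells; run the preprocessing pipeline first")
    return x, [str(i) for i in range(x.shape[0])]


def train(model: MffaeModel, data) -> tuple[MffaeModel, list[LossBundle]]:
    """Mini-batch Adam optimization of L_total on the full sample set.

    Instance labels are assigned from row order once, before any shuffling;
    batch shuffling permutes (x, label) pairs jointly. With a fixed config
    seed the loss history is bit-reproducible.
    """
    x, sample_ids = _as_array(data)
    x = x.astype(model.config.dtype, copy=False)
    if model.train_sample_ids is None:
        model.set_train_samples(sample_ids)
    labels_all = np.arange(x.shape[0])
    opt = Adam(model.modules(), lr=model.config.lr)
    rng = model._rngs["train"]
    bs = min(model.config.batch_size, x.shape[0])
    history: list[LossBundle] = []
    for _ in range(model.config.epochs):
        order = rng.permutation(x.shape[0])
        rec_sum = cls_sum = 0.0
        for start in range(0, x.shape[0], bs):
            idx = order[start:start + bs]
            xb, lb = x[idx], labels_all[idx]
            opt.zero_grad()
            state = model.forward(xb, mode="train")
            bundle = model.losses(xb, state, lb)
            model.backward(xb, state, lb)
            opt.step()
            rec_sum += bundle.l_rec * len(idx)
            cls_sum += bundle.l_cls * len(idx)
        l_rec = rec_sum / x.shape[0]
        l_cls = cls_sum / x.shape[0]
        history.append(LossBundle(l_rec, l_cls, total_loss(l_rec, l_cls)))
    model.loss_history = history
    return model, history


def score(model: MffaeModel, data) -> np.ndarray:
    """Per-sample anomaly score: per-feature mean squared reconstruction error.

    Runs in eval mode (running batch-norm statistics, no dropout), so scoring
    is deterministic and defined for single samples.
    """
    x, _ = _as_array(data)
    x = x.astype(model.config.dtype, copy=False)
    if x.shape[1] != model.config.feat_n:
        raise ValueError(
            f"data has {x.shape[1]} proteins but the model expects {model.config.feat_n}"
        )
    state = model.forward(x, mode="eval")
    return ((x - state.recon) ** 2).mean(axis=1, dtype=np.float64)


# ---------------------------------------------------------------------------
# Checkpointing


def _collect_state(model: MffaeModel) -> dict[str, np.ndarray]:
    arrays: dict[str, np.ndarray] = {}
    for i, mod in enumerate(model.modules()):
        for k, v in mod.params.items():
            arrays[f"p{i}.{k}"] = v
        if isinstance(mod, BatchNorm1d):
            arrays[f"p{i}.running_mean"] = mod.running_mean
            arrays[f"p{i}.running_var"] = mod.running_var
    return arrays


def save_checkpoint(model: MffaeModel, path) -> None:
    """Serialize config, train sample IDs and all parameters to one file."""
    meta = {
        "config": asdict(model.config),
        "train_sample_ids": model.train_sample_ids,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **_collect_state(model))


def load_checkpoint(path) -> MffaeModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = MffaeModel(ModelConfig(**meta["config"]))
        if meta["train_sample_ids"] is not None:
            model.set_train_samples(meta["train_sample_ids"])
        state = _collect_state(model)
        for key, arr in state.items():
            arr[...] = data[key]
    return model


# ---------------------------------------------------------------------------
# scikit-learn estimator surface


class MffaeDetector(BaseEstimator):
    """Transductive anomaly detector over protein-abundance rows.

    ``fit(X)`` trains the configured variant on all rows of ``X`` (no labels);
    ``score_samples(X)`` returns the reconstruction-error anomaly score.
    Note the sign convention: **higher scores mean more anomalous**, the
    reverse of ``sklearn``'s ``OutlierMixin.score_samples``, because the raw
    per-feature mean squared reconstruction error is the quantity of record.

    Parameters mirror :class:`ModelConfig`; ``f1_dim``/``f2_dim`` default to
    the small desk-scale widths so the estimator is usable out of the box on
    matrices of a few thousand proteins.
    """

    def __init__(
        self,
        f1_dim: int = 64,
        f2_dim: int = 16,
        groups_g: int = 8,
        dropout: float = 0.2,
        lr: float = 5e-4,
        batch_size: int = 16,
        epochs: int = 100,
        seed: int = 0,
        variant: str = "MFF_AE",
        local_transform: str = "linear",
        dtype: str = "float64",
    ):
        self.f1_dim = f1_dim
        self.f2_dim = f2_dim
        self.groups_g = groups_g
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.variant = variant
        self.local_transform = local_transform
        self.dtype = dtype

    def _config(self, feat_n: int) -> ModelConfig:
        return ModelConfig(
            feat_n=feat_n,
            f1_dim=self.f1_dim,
            f2_dim=self.f2_dim,
            groups_g=self.groups_g,
            dropout=self.dropout,
            lr=self.lr,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
            variant=self.variant,
            local_transform=self.local_transform,
            dtype=self.dtype,
        )

    def fit(self, X, y=None):
        x, sample_ids = _as_array(X)
        self.model_ = build_model(self._config(x.shape[1]), sample_ids)
        _, self.loss_history_ = train(self.model_, X)
        self.n_features_in_ = x.shape[1]
        return self

    def score_samples(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return score(self.model_, X)

    def fit_score(self, X) -> np.ndarray:
        """Fit on X and score the same rows (the dataset-cleaning workflow)."""
        return self.fit(X).score_samples(X)
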
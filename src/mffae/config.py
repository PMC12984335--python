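"""Run configuration, seed fan-out and reproducibility manifests."""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, asdict, fields

import numpy as np
import yaml

__all__ = ["RunConfig", "derive_seed", "config_hash", "write_manifest"]


def derive_seed(master_seed: int, *parts) -> int:
    """Counter-based seed derivation: one master seed, independent per-stage
    streams. Strings are folded in via CRC32 so derivation is stable across
    processes; the result fits in 31 bits."""
    key = [int(master_seed)] + [
        zlib.crc32(p.encode()) if isinstance(p, str) else int(p) for p in parts
    ]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Flat configuration covering every pipeline stage.

    Unknown keys in a config file are rejected so typos fail loudly; the
    resolved config's content hash goes into every output manifest.
    """

    # preprocessing
    log2: bool = False
    zscore: bool = True
    zero_as_missing: bool = True
    orientation: str = "samples_as_rows"
    # model
    variant: str = "MFF_AE"
    f1_dim: int = 64
    f2_dim: int = 16
    groups_g: int = 8
    dropout: float = 0.2
    lr: float = 5e-4
    batch_size: int = 16
    epochs: int = 150
    dtype: str = "float32"
    # synthetic data
    n_samples: int = 300
    n_proteins: int = 2000
    n_blocks: int = 8
    block_rho: float = 0.9
    missing_rate: float = 0.10
    # benchmark
    preset: str = "ablation"
    n_trials: int = 10
    shuffle_ratio: float = 0.01
    shuffle_mode: str = "within_sample"
    # global
    seed: int = 0
    outdir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def merged(self, **overrides) -> "RunConfig":
        """Return a copy with non-None overrides applied (flags win)."""
        data = asdict(self)
        for k, v in overrides.items():
            if v is not None:
                if k not in data:
                    raise ValueError(f"unknown config key: {k}")
                data[k] = v
        return RunConfig(**data)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, cfg: RunConfig, stage: str, seeds: dict, extras: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "config": asdict(cfg),
        "config_hash": config_hash(cfg),
        "seeds": seeds,
    }
    if extras:
        manifest.update(extras)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
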
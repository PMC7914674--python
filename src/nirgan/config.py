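"""Run configuration: one record of every tunable, YAML round-trippable.

A single master seed fans out to named substreams (simulate / split / train
/ predict) so each pipeline stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .bigan import TrainConfig
from .inference import DEFAULT_REPEATS
from .synth import DEFAULT_MANUFACTURER_EFFECT, DEFAULT_NOISE_SD, DEFAULT_SCATTER_SD

__all__ = ["RunConfig", "substream_seed"]

_STAGES = ("simulate", "split", "train", "predict", "benchmark")


def substream_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) derived from the master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; known: {_STAGES}")
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass
class RunConfig:
    """All pipeline tunables with their default (published) values."""

    # wavenumber grid
    grid_start: float = 4000.0
    grid_end: float = 11995.0
    n_channels: int = 2074
    # synthetic data conditions
    manufacturer_effect: float = DEFAULT_MANUFACTURER_EFFECT
    noise_sd: float = DEFAULT_NOISE_SD
    scatter_sd: float = DEFAULT_SCATTER_SD
    # split protocol
    train_fraction: float = 0.9
    ratios: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2)
    repetitions: int = 10
    # networks and training
    latent_dim: int = 30
    e_hidden: int = 120
    g_hidden: int = 360
    c_hidden: int = 150
    d_hidden: int = 120
    dropout_rate: float = 0.0
    batch_size: int = 60
    epochs: int = 150
    pretrain_epochs: int = 300
    warmup_epochs: int = 600
    n_per_class: int = 60
    learning_rate: float = 1e-3
    sigma_floor: float = 1e-6
    # inference
    repeats: int = DEFAULT_REPEATS
    # master seed
    seed: int = 0

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            n_channels=self.n_channels,
            latent_dim=self.latent_dim,
            e_hidden=self.e_hidden,
            g_hidden=self.g_hidden,
            c_hidden=self.c_hidden,
            d_hidden=self.d_hidden,
            dropout_rate=self.dropout_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            pretrain_epochs=self.pretrain_epochs,
            warmup_epochs=self.warmup_epochs,
            n_per_class=self.n_per_class,
            learning_rate=self.learning_rate,
            sigma_floor=self.sigma_floor,
            rng_seed=substream_seed(self.seed, "train"),
        )

    def config_hash(self) -> str:
        """Short digest identifying the full configuration."""
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ratios" in raw:
            raw["ratios"] = tuple(raw["ratios"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["ratios"] = list(data["ratios"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
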
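"""Run configuration: one flat record of every tunable, YAML round-trippable."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All knobs of the three-stage training pipeline.

    Stated defaults follow the method's published settings (Adam, lr 0.001,
    weight decay 5e-4, α=10, β=1, γ=1, epochs 1000/500/300, top 15%
    annotation retention); everything the method leaves open (k, layer
    widths, HVG statistic, negative sampling) is documented here.
    """

    # preprocessing
    k_neighbors: int = 6            # hex-packed Visium neighborhood
    n_hvg: int | str = "all"        # e.g. 3000 for Visium, 5000 for seqFISH+
    normalize: bool = True          # library-size to target_sum + log1p
    target_sum: float = 1e4         # shared across ST and reference
    scale_genes: bool = True        # per-gene z-score after log1p
    # loss weights
    alpha: float = 10.0
    beta: float = 1.0
    gamma: float = 1.0
    # schedule
    epochs_vgae: int = 1000
    epochs_cgan: int = 500
    epochs_mapping: int = 300
    learning_rate: float = 1e-3          # pre-training (both stages)
    mapping_learning_rate: float = 0.1   # mapping-matrix logits
    weight_decay: float = 5e-4
    # architecture
    d_hidden: int = 256
    d_latent: int = 64
    d_disc: int = 64
    # mechanics
    seed: int = 0
    reparam_literal: bool = False
    adversarial_mode: str = "grad_reversal"   # or "label_flip"
    reg_negatives: int | str = 5              # or "all" for the exact sum
    top_fraction: float = 0.15
    # ablation toggles
    no_cyc: bool = False
    no_disc: bool = False
    no_reg: bool = False

    def __post_init__(self):
        for name in ("epochs_vgae", "epochs_cgan", "epochs_mapping"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("alpha", "beta", "gamma", "weight_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.adversarial_mode not in ("grad_reversal", "label_flip"):
            raise ValueError(f"unknown adversarial_mode {self.adversarial_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def replace(self, **kwargs) -> "RunConfig":
        d = self.to_dict()
        d.update(kwargs)
        return RunConfig.from_dict(d)
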
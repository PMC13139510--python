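"""Configuration records for the dual-branch segmentation model.

Defaults follow the published training protocol where one is stated
(Adam, initial learning rate 3e-4, weight decay 1e-4, batch 16, 200 epochs;
branch-mixing weights lambda1=0.6, lambda2=0.4; encoder split count K=4 with
K=n=2 in the channel-attention concatenation).  Everything else is this
package's own choice and is documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class DSMConfig:
    """CNN-branch deep-split block hyperparameters."""

    split_k: int = 4          # branch count of the channel-group split
    eq3_k: int = 2            # channel groups entering the saliency concat
    eq3_n: int = 2            # independent channel-gates per group
    fusion_ratio: int = 4     # FC bottleneck reduction in fusion attention


@dataclass
class MTConfig:
    """Multi-dimensional Transformer block hyperparameters."""

    reduction_R: int = 4      # key/value length reduction in efficient attention
    heads: int = 4
    window: int = 7           # spatial-attention window edge
    lambda1: float = 0.6      # weight of the spatial-attention path
    lambda2: float = 0.4      # weight of the channel-attention path
    r1: int = 8               # spatial-gate bottleneck ratio
    r2: int = 8               # channel-gate bottleneck ratio
    mlp_ratio: float = 4.0
    blocks_per_stage: int = 2


@dataclass
class LAConfig:
    """Directional interactive-attention fusion."""

    activation: str = "hardswish"   # "relu" or "hardswish"
    enabled: bool = True


@dataclass
class Toggles:
    """Ablation switches: base U-Net, +split conv, +transformer,
    +multiscale skips, +directional fusion, +cross-attention."""

    use_dsm: bool = True
    use_mt: bool = True
    use_ms_skip: bool = True
    use_la: bool = True
    use_ca: bool = True


@dataclass
class ModelConfig:
    in_channels: int = 1
    num_classes: int = 9
    widths: tuple[int, int, int] = (32, 64, 128)
    dsm: DSMConfig = field(default_factory=DSMConfig)
    mt: MTConfig = field(default_factory=MTConfig)
    la: LAConfig = field(default_factory=LAConfig)
    toggles: Toggles = field(default_factory=Toggles)
    ca_heads: int = 2
    seed: int = 0

    def __post_init__(self):
        self.widths = tuple(self.widths)
        if len(self.widths) != 3 or not (self.widths[0] < self.widths[1] < self.widths[2]):
            raise ValueError(f"widths must be 3 strictly increasing ints, got {self.widths}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


@dataclass
class OptimizerConfig:
    name: str = "adam"
    lr: float = 3e-4
    weight_decay: float = 1e-4


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    batch_size: int = 16
    epochs: int = 200
    ce_weight: float = 0.5
    dice_weight: float = 0.5
    data_dir: Optional[str] = None
    out_dir: Optional[str] = None
    seed: int = 0
    device: str = "cpu"
    deterministic: bool = True
    early_stop_dice: Optional[float] = None   # stop once val macro Dice reaches this


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


_SUBCONFIGS = {"dsm": DSMConfig, "mt": MTConfig, "la": LAConfig,
               "toggles": Toggles, "model": ModelConfig,
               "optimizer": OptimizerConfig}


def _build(cls, data):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        sub = _SUBCONFIGS.get(f.name)
        kwargs[f.name] = _build(sub, v) if sub is not None and isinstance(v, dict) else v
    return cls(**kwargs)


def config_to_dict(cfg) -> dict:
    return _to_plain(cfg)


def model_config_from_dict(d: dict) -> ModelConfig:
    return _build(ModelConfig, d)


def run_config_from_dict(d: dict) -> RunConfig:
    return _build(RunConfig, d)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return run_config_from_dict(yaml.safe_load(fh))


def save_run_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def reduced_model_config(num_classes: int = 3, in_channels: int = 1, seed: int = 0,
                         **toggle_overrides) -> ModelConfig:
    """Desk-scale preset: widths (16,32,64), 1 transformer block per stage,
    window 4, reduction 2 — sized for 64x64 images on one CPU core."""
    cfg = ModelConfig(
        in_channels=in_channels,
        num_classes=num_classes,
        widths=(16, 32, 64),
        mt=MTConfig(reduction_R=2, heads=4, window=4, blocks_per_stage=1),
        seed=seed,
    )
    for k, v in toggle_overrides.items():
        setattr(cfg.toggles, k, v)
    return cfg
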
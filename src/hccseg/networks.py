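"""Network construction, losses, and checkpointing.

This is the public surface over the :mod:`hccseg.nn` engine: configuration
dataclasses, seeded builders for the single-phase encoder-decoder (DCNN) and
the dual-phase deep fusion network (DFN), the Dice and composite losses, score
-map binarization, and weight (de)serialization with a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import DcnnNet, FusionNet, check_input_size
from .nn.losses import (CompositeLossBreakdown, binarize, composite_loss,
                        dice_loss, dice_loss_grad)

__all__ = [
    "DcnnConfig", "FusionConfig", "build_dcnn", "build_dfn",
    "dice_loss", "dice_loss_grad", "composite_loss", "CompositeLossBreakdown",
    "binarize", "save_weights", "load_weights",
]


@dataclass(frozen=True)
class DcnnConfig:
    """Architecture of one encoder-decoder sub-network.

    ``input_size`` must be divisible by 8 — the contracting path applies three
    2x2/stride-2 max pools.  ``base_channels`` is the width of the first conv
    block; widths double after each pool (base, 2*base, 4*base; 8*base at the
    two 1x1 bottleneck convs).
    """

    input_size: tuple[int, int] = (256, 256)
    base_channels: int = 32

    def __post_init__(self):
        h, w = self.input_size
        check_input_size(h, w)
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


@dataclass(frozen=True)
class FusionConfig:
    """Fusion-network settings: N = 2 sub-networks, loss weights alpha_i.

    The fusion block combines the two sub-network score maps elementwise
    (``fusion_mode='sum'``; a channel-concatenation variant is available for
    ablation) and maps the result through two 3x3 conv-BN-ReLU layers, a 1x1
    conv, and a sigmoid.
    """

    alphas: tuple[float, float] = (0.5, 0.5)
    fusion_channels: int = 8
    fusion_mode: str = "sum"
    freeze_subnets: bool = False

    def __post_init__(self):
        if len(self.alphas) != 2:
            raise ValueError("exactly two sub-networks (N = 2) are supported")
        if any(a < 0 for a in self.alphas):
            raise ValueError("loss weights alpha must be non-negative")
        if self.fusion_mode not in ("sum", "concat"):
            raise ValueError("fusion_mode must be 'sum' or 'concat'")


def build_dcnn(cfg: DcnnConfig, seed: int = 0) -> DcnnNet:
    """Instantiate a seeded single-phase network for ``cfg``."""
    return DcnnNet(base_channels=cfg.base_channels, seed=seed)


def build_dfn(cfg: FusionConfig, sub_cfg: DcnnConfig, seed: int = 0) -> FusionNet:
    """Instantiate a seeded dual-phase fusion network."""
    return FusionNet(base_channels=sub_cfg.base_channels,
                     fusion_channels=cfg.fusion_channels,
                     seed=seed, fusion_mode=cfg.fusion_mode)


def save_weights(net, path: str | Path, meta: dict | None = None) -> None:
    """Write a checkpoint (``.npz``) plus a JSON sidecar with metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **net.state_dict())
    sidecar = {"format": "hccseg-weights-v1", "class": type(net).__name__}
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_weights(net, path: str | Path) -> None:
    """Load a checkpoint written by :func:`save_weights` into ``net``."""
    path = Path(path)
    if not path.exists() and path.with_suffix(".npz").exists():
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
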
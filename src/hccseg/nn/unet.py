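"""Phase-specific encoder-decoder segmentation network.

The architecture follows the U-Net family: a contracting path of six 3x3
conv-BN-ReLU blocks with a 2x2/stride-2 max pool after every two blocks
(three pools in total), a bottleneck of two 1x1 conv blocks, and an expansive
path of three up-blocks (2x2 transposed conv, skip concatenation with the
matching encoder feature map, then two 3x3 conv blocks), ending in a 1x1 conv
and a sigmoid that yields a per-pixel tumor score map in [0, 1].

Channel widths double after every pool: ``base, 2*base, 4*base`` along the
contracting path and ``8*base`` at the bottleneck.  Input height and width
must be divisible by 8 (three pooling stages).
"""

from __future__ import annotations

import numpy as np

from .layers import (BilinearUpsample, Conv2d, ConvBlock, ConvTranspose2x2,
                     MaxPool2x2, Param, Sigmoid)

__all__ = ["DcnnNet", "AuxEncoderHead", "check_input_size"]


def check_input_size(h: int, w: int) -> None:
    if h < 8 or w < 8 or h % 8 or w % 8:
        raise ValueError(
            f"input size ({h}, {w}) must be >= 8 and divisible by 8 "
            "(three 2x2 pooling stages)")


class DcnnNet:
    """Encoder-decoder network mapping a 1-channel slice to a score map."""

    def __init__(self, base_channels: int = 32, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        c = int(base_channels)
        self.base_channels = c
        self.dtype = dtype

        self.enc = [
            ConvBlock(1, c, rng, "enc1a", dtype=dtype),
            ConvBlock(c, c, rng, "enc1b", dtype=dtype),
            ConvBlock(c, 2 * c, rng, "enc2a", dtype=dtype),
            ConvBlock(2 * c, 2 * c, rng, "enc2b", dtype=dtype),
            ConvBlock(2 * c, 4 * c, rng, "enc3a", dtype=dtype),
            ConvBlock(4 * c, 4 * c, rng, "enc3b", dtype=dtype),
        ]
        self.pools = [MaxPool2x2(), MaxPool2x2(), MaxPool2x2()]
        self.bottleneck = [
            ConvBlock(4 * c, 8 * c, rng, "bott1", kernel=1, dtype=dtype),
            ConvBlock(8 * c, 8 * c, rng, "bott2", kernel=1, dtype=dtype),
        ]
        self.ups = [
            ConvTranspose2x2(8 * c, 4 * c, rng, "up3", dtype=dtype),
            ConvTranspose2x2(4 * c, 2 * c, rng, "up2", dtype=dtype),
            ConvTranspose2x2(2 * c, c, rng, "up1", dtype=dtype),
        ]
        self.dec = [
            ConvBlock(8 * c, 4 * c, rng, "dec3a", dtype=dtype),
            ConvBlock(4 * c, 4 * c, rng, "dec3b", dtype=dtype),
            ConvBlock(4 * c, 2 * c, rng, "dec2a", dtype=dtype),
            ConvBlock(2 * c, 2 * c, rng, "dec2b", dtype=dtype),
            ConvBlock(2 * c, c, rng, "dec1a", dtype=dtype),
            ConvBlock(c, c, rng, "dec1b", dtype=dtype),
        ]
        self.head = Conv2d(c, 1, 1, rng, name="head", dtype=dtype)
        self.sigmoid = Sigmoid()

    # ----- forward / backward -------------------------------------------------

    def forward_encoder(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Contracting path only; returns the bottleneck feature map."""
        check_input_size(x.shape[2], x.shape[3])
        h = self.enc[0].forward(x, train)
        h = self.enc[1].forward(h, train)
        self._skip1 = h
        h = self.pools[0].forward(h, train)
        h = self.enc[2].forward(h, train)
        h = self.enc[3].forward(h, train)
        self._skip2 = h
        h = self.pools[1].forward(h, train)
        h = self.enc[4].forward(h, train)
        h = self.enc[5].forward(h, train)
        self._skip3 = h
        h = self.pools[2].forward(h, train)
        h = self.bottleneck[0].forward(h, train)
        h = self.bottleneck[1].forward(h, train)
        return h

    def backward_encoder(self, grad: np.ndarray) -> np.ndarray:
        """Backward through the contracting path (skip branches unused)."""
        g = self.bottleneck[1].backward(grad)
        g = self.bottleneck[0].backward(g)
        g = self.pools[2].backward(g)
        g = self.enc[5].backward(g)
        g = self.enc[4].backward(g)
        g = self.pools[1].backward(g)
        g = self.enc[3].backward(g)
        g = self.enc[2].backward(g)
        g = self.pools[0].backward(g)
        g = self.enc[1].backward(g)
        return self.enc[0].backward(g)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Full forward pass: ``(N, 1, H, W)`` input to ``(N, 1, H, W)`` scores."""
        h = self.forward_encoder(x, train)
        c = self.base_channels

        h = self.ups[0].forward(h, train)
        h = np.concatenate([self._skip3, h], axis=1)
        h = self.dec[0].forward(h, train)
        h = self.dec[1].forward(h, train)

        h = self.ups[1].forward(h, train)
        h = np.concatenate([self._skip2, h], axis=1)
        h = self.dec[2].forward(h, train)
        h = self.dec[3].forward(h, train)

        h = self.ups[2].forward(h, train)
        h = np.concatenate([self._skip1, h], axis=1)
        h = self.dec[4].forward(h, train)
        h = self.dec[5].forward(h, train)

        h = self.head.forward(h, train)
        return self.sigmoid.forward(h, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        """Backward from d(loss)/d(score map); returns d(loss)/d(input)."""
        c = self.base_channels
        g = self.sigmoid.backward(grad)
        g = self.head.backward(g)

        g = self.dec[5].backward(g)
        g = self.dec[4].backward(g)
        gskip1, g = g[:, :c], g[:, c:]
        g = self.ups[2].backward(g)

        g = self.dec[3].backward(g)
        g = self.dec[2].backward(g)
        gskip2, g = g[:, :2 * c], g[:, 2 * c:]
        g = self.ups[1].backward(g)

        g = self.dec[1].backward(g)
        g = self.dec[0].backward(g)
        gskip3, g = g[:, :4 * c], g[:, 4 * c:]
        g = self.ups[0].backward(g)

        # merge skip-branch gradients back into the contracting path
        g = self.bottleneck[1].backward(g)
        g = self.bottleneck[0].backward(g)
        g = self.pools[2].backward(g)
        g = g + gskip3
        g = self.enc[5].backward(g)
        g = self.enc[4].backward(g)
        g = self.pools[1].backward(g)
        g = g + gskip2
        g = self.enc[3].backward(g)
        g = self.enc[2].backward(g)
        g = self.pools[0].backward(g)
        g = g + gskip1
        g = self.enc[1].backward(g)
        return self.enc[0].backward(g)

    # ----- parameter access ---------------------------------------------------

    def _layers(self):
        return self.enc + self.bottleneck + self.ups + self.dec + [self.head]

    def bn_layers(self):
        return [layer.bn for layer in self._layers() if hasattr(layer, "bn")]

    def recalibrate_bn(self, x: np.ndarray, batch_size: int = 8) -> None:
        """Recompute BN running statistics exactly over a reference set.

        With only dozens of momentum updates during short trainings the
        running estimates lag the trained feature distribution badly; one
        exact pass removes the train/eval normalization mismatch.
        """
        for bn in self.bn_layers():
            bn.begin_calibration()
        for start in range(0, len(x), batch_size):
            self.forward(x[start:start + batch_size], train=True)
        for bn in self.bn_layers():
            bn.end_calibration()

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def encoder_params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.enc + self.bottleneck:
            out.extend(layer.params())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for i, layer in enumerate(self._layers()):
            bn = getattr(layer, "bn", None)
            if bn is not None:
                state[f"{bn.gamma.name}.running_mean"] = bn.running_mean.copy()
                state[f"{bn.gamma.name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for layer in self._layers():
            bn = getattr(layer, "bn", None)
            if bn is not None:
                bn.running_mean[...] = state[f"{bn.gamma.name}.running_mean"]
                bn.running_var[...] = state[f"{bn.gamma.name}.running_var"]


class AuxEncoderHead:
    """Temporary head used to pre-train the contracting path alone.

    A 1x1 conv collapses the bottleneck features to one channel, a fixed
    bilinear x8 upsample restores the input resolution, and a sigmoid yields a
    score map trainable with Dice loss.  The head is discarded after the
    encoder pre-training stage.
    """

    def __init__(self, bottleneck_channels: int, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.conv = Conv2d(bottleneck_channels, 1, 1, rng, name="aux.head", dtype=dtype)
        self.up = BilinearUpsample(8)
        self.sigmoid = Sigmoid()

    def forward(self, bottleneck: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.conv.forward(bottleneck, train)
        h = self.up.forward(h, train)
        return self.sigmoid.forward(h, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.sigmoid.backward(grad)
        g = self.up.backward(g)
        return self.conv.backward(g)

    def params(self) -> list[Param]:
        return self.conv.params()
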
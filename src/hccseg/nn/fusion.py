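"""Deep fusion network: two phase-specific sub-networks plus a fusion block.

Each MRI phase feeds its own encoder-decoder sub-network; the two score maps
``o(P_1)`` and ``o(P_2)`` are combined elementwise (sum, by default) and the
fusion block ``f`` — two 3x3 conv-BN-ReLU layers, a 1x1 conv and a sigmoid —
maps the combination to the final score map ``P_out``.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, ConvBlock, Param, Sigmoid
from .losses import CompositeLossBreakdown, composite_loss, dice_loss_grad
from .unet import DcnnNet

__all__ = ["FusionNet"]


class FusionNet:
    """Two sub-networks and a trainable fusion block (N = 2 phases)."""

    def __init__(self, base_channels: int = 32, fusion_channels: int = 8,
                 seed: int = 0, fusion_mode: str = "sum", dtype=np.float32):
        if fusion_mode not in ("sum", "concat"):
            raise ValueError("fusion_mode must be 'sum' or 'concat'")
        self.fusion_mode = fusion_mode
        self.subnets = [
            DcnnNet(base_channels, seed=seed, dtype=dtype),
            DcnnNet(base_channels, seed=seed + 1, dtype=dtype),
        ]
        rng = np.random.default_rng(seed + 2)
        c_in = 1 if fusion_mode == "sum" else 2
        k = int(fusion_channels)
        self.fusion_layers = [
            ConvBlock(c_in, k, rng, "fus1", dtype=dtype),
            ConvBlock(k, k, rng, "fus2", dtype=dtype),
        ]
        self.fusion_head = Conv2d(k, 1, 1, rng, name="fus.head", dtype=dtype)
        self.fusion_sigmoid = Sigmoid()

    # ----- forward ------------------------------------------------------------

    def _combine(self, o1: np.ndarray, o2: np.ndarray) -> np.ndarray:
        if self.fusion_mode == "sum":
            return o1 + o2
        return np.concatenate([o1, o2], axis=1)

    def forward(self, x1: np.ndarray, x2: np.ndarray, train: bool = True,
                train_subnets: bool | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(o1, o2, p_out)`` for a batch of dual-phase slices.

        ``train_subnets`` lets the fusion block train while the (frozen)
        sub-networks run in eval mode, so the fusion block sees the same
        running-statistic score maps during training as at inference.
        """
        if x1.shape != x2.shape:
            raise ValueError(f"phase shapes differ: {x1.shape} vs {x2.shape}")
        sub_train = train if train_subnets is None else train_subnets
        o1 = self.subnets[0].forward(x1, sub_train)
        o2 = self.subnets[1].forward(x2, sub_train)
        p_out = self.forward_fusion_from_submaps(o1, o2, train)
        return o1, o2, p_out

    def init_fusion_passthrough(self, s_mean: float, s_std: float,
                                logit_w: float, logit_b: float) -> None:
        """Initialize the fusion block as a calibrated pixelwise rule.

        Sets the two conv blocks to (approximate) identity on the combined
        map — center-tap convolutions, batch-norm scaled back to the data's
        own moments — and the head to the supplied logistic coefficients, so
        the block starts at ``sigmoid(w * s + b)`` and gradient descent
        refines from a sensible operating point instead of from noise.
        Only meaningful for the sum combination.
        """
        if self.fusion_mode != "sum":
            return
        k = self.fusion_layers[0].conv.c_out
        for layer in self.fusion_layers:
            w = layer.conv.w.value
            w[...] = 0.0
            kk = layer.conv.k
            center = (kk * kk) // 2
            for c in range(k):
                # channel c reads channel c's center tap (identity per channel)
                src = 0 if layer is self.fusion_layers[0] else c
                w[c, src * kk * kk + center] = 1.0
            layer.conv.b.value[...] = 0.0
            layer.bn.gamma.value[...] = max(s_std, 1e-3)
            layer.bn.beta.value[...] = s_mean
            layer.bn.running_mean[...] = s_mean
            layer.bn.running_var[...] = s_std ** 2
        hw = self.fusion_head.w.value
        hw[...] = 0.0
        hw[0, :] = logit_w / k  # average the k identical channels
        self.fusion_head.b.value[...] = logit_b

    def forward_fusion_from_submaps(self, o1: np.ndarray, o2: np.ndarray,
                                    train: bool = True) -> np.ndarray:
        """Fusion block alone on (cached) sub-network score maps."""
        h = self._combine(o1, o2)
        h = self.fusion_layers[0].forward(h, train)
        h = self.fusion_layers[1].forward(h, train)
        h = self.fusion_head.forward(h, train)
        return self.fusion_sigmoid.forward(h, train)

    def backward_fusion(self, grad_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backward through the fusion block; returns gradients w.r.t. o1, o2."""
        g = self.fusion_sigmoid.backward(grad_out)
        g = self.fusion_head.backward(g)
        g = self.fusion_layers[1].backward(g)
        g = self.fusion_layers[0].backward(g)
        if self.fusion_mode == "sum":
            return g, g
        return g[:, :1], g[:, 1:]

    def composite_backward(self, gt: np.ndarray, o1: np.ndarray, o2: np.ndarray,
                           p_out: np.ndarray, alphas: tuple[float, float],
                           smooth: float = 1.0,
                           freeze_subnets: bool = False) -> CompositeLossBreakdown:
        """Accumulate gradients of the composite loss into all parameters."""
        breakdown = composite_loss(gt, (o1, o2), p_out, alphas, smooth)
        _, g_out = dice_loss_grad(p_out, gt, smooth)
        g1f, g2f = self.backward_fusion(g_out.astype(p_out.dtype))
        if not freeze_subnets:
            _, g1d = dice_loss_grad(o1, gt, smooth)
            _, g2d = dice_loss_grad(o2, gt, smooth)
            self.subnets[0].backward(g1f + alphas[0] * g1d.astype(o1.dtype))
            self.subnets[1].backward(g2f + alphas[1] * g2d.astype(o2.dtype))
        return breakdown

    def recalibrate_fusion_bn(self, x1: np.ndarray, x2: np.ndarray,
                              batch_size: int = 8) -> None:
        """Exact BN statistics for the fusion block (sub-networks in eval)."""
        for layer in self.fusion_layers:
            layer.bn.begin_calibration()
        for start in range(0, len(x1), batch_size):
            self.forward(x1[start:start + batch_size], x2[start:start + batch_size],
                         train=True, train_subnets=False)
        for layer in self.fusion_layers:
            layer.bn.end_calibration()

    # ----- parameter access ---------------------------------------------------

    def fusion_params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.fusion_layers:
            out.extend(layer.params())
        out.extend(self.fusion_head.params())
        return out

    def params(self) -> list[Param]:
        return self.subnets[0].params() + self.subnets[1].params() + self.fusion_params()

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, net in enumerate(self.subnets):
            for k, v in net.state_dict().items():
                state[f"sub{i}.{k}"] = v
        for p in self.fusion_params():
            state[p.name] = p.value.copy()
        for layer in self.fusion_layers:
            state[f"{layer.bn.gamma.name}.running_mean"] = layer.bn.running_mean.copy()
            state[f"{layer.bn.gamma.name}.running_var"] = layer.bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, net in enumerate(self.subnets):
            sub = {k[len(f"sub{i}."):]: v for k, v in state.items()
                   if k.startswith(f"sub{i}.")}
            net.load_state_dict(sub)
        for p in self.fusion_params():
            p.value[...] = state[p.name]
        for layer in self.fusion_layers:
            layer.bn.running_mean[...] = state[f"{layer.bn.gamma.name}.running_mean"]
            layer.bn.running_var[...] = state[f"{layer.bn.gamma.name}.running_var"]
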
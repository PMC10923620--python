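"""Scikit-learn style estimators over the segmentation networks.

``DcnnSegmenter`` wraps the single-phase encoder-decoder and its three-stage
training protocol; ``FusionSegmenter`` wraps the dual-phase fusion network
and its two-subset protocol.  Both follow the estimator contract: all
hyperparameters are constructor arguments, ``fit`` returns ``self`` and sets
trailing-underscore attributes, and ``get_params``/``set_params`` make them
usable inside scikit-learn pipelines and model selection.

Inputs are image stacks, not feature matrices: ``X`` has shape
``(n_slices, H, W)`` for the single-phase model and ``(n_slices, 2, H, W)``
(phase 1, phase 2) for the fusion model; ``y`` is the binary mask stack
``(n_slices, H, W)``.  H and W must be divisible by 8.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .augment import AugmentParams
from .nn import DcnnNet, FusionNet, check_input_size
from .nn.losses import binarize
from .preprocess import SlicePair
from .training import TrainConfig, train_dcnn_staged, train_dfn

__all__ = ["DcnnSegmenter", "FusionSegmenter"]


def _validate_xy(x: np.ndarray, y: np.ndarray, dual: bool) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y)
    expected = 4 if dual else 3
    if x.ndim != expected:
        raise ValueError(f"X must be {expected}D, got shape {x.shape}")
    if dual and x.shape[1] != 2:
        raise ValueError(f"dual-phase X needs axis 1 of size 2, got {x.shape}")
    if y.shape != (x.shape[0],) + x.shape[-2:]:
        raise ValueError(f"y shape {y.shape} does not match X {x.shape}")
    if not np.all(np.isin(np.unique(y), (0, 1))):
        raise ValueError("y must be binary masks")
    check_input_size(x.shape[-2], x.shape[-1])
    return x, y.astype(np.uint8)


class DcnnSegmenter(BaseEstimator):
    """Single-phase encoder-decoder tumor segmenter.

    Parameters
    ----------
    base_channels : width of the first conv block (doubling per pool).
    optimizer, lr : optimization settings (Adam at 1e-4 by default).
    epochs : per-stage epoch budget (encoder pre-train, full, augmented).
    augment : AugmentParams for stage 3, or None to skip augmentation.
    threshold : score-map binarization threshold used by ``predict``.
    """

    def __init__(self, base_channels: int = 32, optimizer: str = "adam",
                 lr: float = 1e-4, momentum: float = 0.9, batch_size: int = 8,
                 epochs: tuple[int, int, int] = (20, 40, 40),
                 augment: AugmentParams | None = None, smooth: float = 1.0,
                 threshold: float = 0.5, random_state: int = 0):
        self.base_channels = base_channels
        self.optimizer = optimizer
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.augment = augment
        self.smooth = smooth
        self.threshold = threshold
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(optimizer=self.optimizer, base_lr=self.lr,
                           momentum=self.momentum, batch_size=self.batch_size,
                           epochs=tuple(self.epochs), smooth=self.smooth,
                           seed=self.random_state)

    def fit(self, X, y):
        x, y = _validate_xy(X, y, dual=False)
        pairs = [SlicePair(phase1_slice=x[i], phase2_slice=x[i], mask_slice=y[i],
                           case_id=str(i), slice_index=i) for i in range(len(x))]
        self.net_ = DcnnNet(self.base_channels, seed=self.random_state)
        _, self.history_ = train_dcnn_staged(self.net_, pairs, 0,
                                             self._train_config(), self.augment)
        self.input_size_ = x.shape[-2:]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel tumor probability maps, shape ``(n, H, W)``."""
        x = np.asarray(X, dtype=np.float32)
        if x.ndim != 3:
            raise ValueError(f"X must be 3D, got {x.shape}")
        return self.net_.forward(x[:, None], train=False)[:, 0]

    def predict(self, X) -> np.ndarray:
        return binarize(self.predict_proba(X), self.threshold)

    def score(self, X, y) -> float:
        """Mean hard Dice over the stack (volume-level counting)."""
        from .evaluate import evaluate_masks
        return evaluate_masks(self.predict(X), np.asarray(y)).dsc


class FusionSegmenter(BaseEstimator):
    """Dual-phase deep fusion segmenter (two sub-networks + fusion block).

    ``fit`` accepts ``groups`` (case ids per slice); the two-subset protocol
    splits cases, never slices, so pass real case ids whenever slices share
    patients.  ``alphas`` weight the two sub-network Dice losses inside the
    composite objective; the fusion Dice term always has weight 1.
    """

    def __init__(self, base_channels: int = 32, fusion_channels: int = 8,
                 fusion_mode: str = "sum", alphas: tuple[float, float] = (0.5, 0.5),
                 freeze_subnets: bool = False, optimizer: str = "adam",
                 lr: float = 1e-4, dfn_lr: float = 1e-7, momentum: float = 0.9,
                 batch_size: int = 8, epochs: tuple[int, int, int] = (20, 40, 40),
                 epochs_fusion: int = 40, augment: AugmentParams | None = None,
                 smooth: float = 1.0, threshold: float = 0.5, random_state: int = 0):
        self.base_channels = base_channels
        self.fusion_channels = fusion_channels
        self.fusion_mode = fusion_mode
        self.alphas = alphas
        self.freeze_subnets = freeze_subnets
        self.optimizer = optimizer
        self.lr = lr
        self.dfn_lr = dfn_lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.epochs_fusion = epochs_fusion
        self.augment = augment
        self.smooth = smooth
        self.threshold = threshold
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(optimizer=self.optimizer, base_lr=self.lr,
                           dfn_lr=self.dfn_lr, momentum=self.momentum,
                           batch_size=self.batch_size, epochs=tuple(self.epochs),
                           epochs_fusion=self.epochs_fusion, smooth=self.smooth,
                           seed=self.random_state)

    def fit(self, X, y, groups=None):
        x, y = _validate_xy(X, y, dual=True)
        if groups is None:
            groups = [str(i) for i in range(len(x))]
        if len(groups) != len(x):
            raise ValueError("groups must have one entry per slice")
        pairs = [SlicePair(phase1_slice=x[i, 0], phase2_slice=x[i, 1],
                           mask_slice=y[i], case_id=str(groups[i]), slice_index=i)
                 for i in range(len(x))]
        self.net_ = FusionNet(self.base_channels, self.fusion_channels,
                              seed=self.random_state, fusion_mode=self.fusion_mode)
        _, self.history_ = train_dfn(self.net_, pairs, self._train_config(),
                                     self.augment, tuple(self.alphas),
                                     self.freeze_subnets)
        self.input_size_ = x.shape[-2:]
        return self

    def _forward(self, X):
        x = np.asarray(X, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 2:
            raise ValueError(f"X must be (n, 2, H, W), got {x.shape}")
        return self.net_.forward(x[:, :1], x[:, 1:], train=False)

    def predict_proba(self, X) -> np.ndarray:
        """Fused per-pixel tumor probability maps, shape ``(n, H, W)``."""
        return self._forward(X)[2][:, 0]

    def predict_sub_maps(self, X) -> tuple[np.ndarray, np.ndarray]:
        """The two intermediate sub-network score maps."""
        o1, o2, _ = self._forward(X)
        return o1[:, 0], o2[:, 0]

    def predict(self, X) -> np.ndarray:
        return binarize(self.predict_proba(X), self.threshold)

    def score(self, X, y) -> float:
        from .evaluate import evaluate_masks
        return evaluate_masks(self.predict(X), np.asarray(y)).dsc
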
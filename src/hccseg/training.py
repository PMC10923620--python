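"""Training protocols: staged single-network training, two-subset fusion
training, and the leave-one-out cross-validation harness.

The single-phase network is trained in three stages: (1) the contracting
path alone, on non-augmented slices, through a temporary auxiliary head
(1x1 conv + bilinear x8 upsample + sigmoid) that is discarded afterwards;
(2) the entire network on the same non-augmented slices; (3) fine-tuning on
an augmented dataset.  The fusion network is trained on two disjoint,
case-level halves of the training set: the two phase-specific sub-networks
are staged-trained on one half, then the whole fusion network is trained
under the composite loss (SGD) on the other half.

Cross-validation is leave-one-case-out: each fold's model never sees its
test case, and every fold records the exact training-case ids for audit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentParams, build_augmented_dataset
from .errors import TrainingError
from .nn import SGD, Adam, AuxEncoderHead, DcnnNet, FusionNet
from .nn.losses import dice_loss_grad
from .preprocess import SlicePair

__all__ = ["TrainConfig", "EpochRecord", "TrainHistory", "train_dcnn_staged",
           "split_training_subsets", "train_dfn", "run_loocv", "FoldResult"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults follow the reference protocol: Adam at 1e-4 for the single
    network, SGD at 1e-7 for the fusion network, batch size 8.  At phantom
    scale the experiment presets raise both rates (see docs/methods.md) —
    with only dozens of gradient steps the reference rates are effectively
    zero.
    """

    optimizer: str = "adam"
    base_lr: float = 1e-4
    dfn_lr: float = 1e-7
    dfn_subnet_lr: float | None = None  # sub-network rate in the fusion phase
    momentum: float = 0.9
    batch_size: int = 8
    epochs: tuple[int, int, int] = (20, 40, 40)
    epochs_fusion: int = 40
    smooth: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.base_lr <= 0 or self.dfn_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass(frozen=True)
class EpochRecord:
    stage: str
    epoch: int
    mean_loss: float
    mean_dsc: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def losses(self, stage: str | None = None) -> list[float]:
        return [r.mean_loss for r in self.records if stage is None or r.stage == stage]

    def stages(self) -> list[str]:
        return [r.stage for r in self.records]


def _stack_phase(pairs: list[SlicePair], phase: int) -> tuple[np.ndarray, np.ndarray]:
    key = "phase1_slice" if phase == 0 else "phase2_slice"
    x = np.stack([getattr(p, key) for p in pairs]).astype(np.float32)[:, None]
    y = np.stack([p.mask_slice for p in pairs]).astype(np.float32)[:, None]
    return x, y


def _make_optimizer(cfg: TrainConfig, params, lr: float):
    if cfg.optimizer == "adam":
        return Adam(params, lr=lr)
    return SGD(params, lr=lr, momentum=cfg.momentum)


def _hard_dsc(pred: np.ndarray, target: np.ndarray) -> tuple[int, int, int]:
    p = pred >= 0.5
    g = target > 0
    return (int(np.count_nonzero(p & g)), int(np.count_nonzero(p & ~g)),
            int(np.count_nonzero(~p & g)))


def _run_stage(stage: str, forward, backward, opt_params, x: np.ndarray,
               y: np.ndarray, epochs: int, cfg: TrainConfig, lr: float,
               rng: np.random.Generator, history: TrainHistory) -> None:
    if epochs == 0:
        return
    opt = _make_optimizer(cfg, opt_params, lr)
    n = len(x)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        tp = fp = fn = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            pred = forward(xb)
            loss, grad = dice_loss_grad(pred, yb, cfg.smooth)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss in stage {stage}", history=history)
            opt.zero_grad()
            backward(grad.astype(pred.dtype))
            opt.step()
            losses.append(loss)
            a, b, c = _hard_dsc(pred, yb)
            tp, fp, fn = tp + a, fp + b, fn + c
        dsc = 2 * tp / (fp + 2 * tp + fn) if (tp + fp + fn) else 1.0
        history.records.append(EpochRecord(stage=stage, epoch=epoch,
                                           mean_loss=float(np.mean(losses)),
                                           mean_dsc=float(dsc)))


def train_dcnn_staged(net: DcnnNet, pairs: list[SlicePair], phase: int,
                      cfg: TrainConfig, aug: AugmentParams | None = None
                      ) -> tuple[dict, TrainHistory]:
    """Three-stage training of one single-phase network.

    ``phase`` selects which slice of each pair feeds the network (0 = phase
    1 / hepatobiliary-like, 1 = phase 2).  Returns the trained state dict
    and the full per-epoch history (stage tags ``encoder``, ``full``,
    ``augmented``).
    """
    if not pairs:
        raise ValueError("training dataset is empty")
    if phase not in (0, 1):
        raise ValueError("phase must be 0 or 1")
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    x, y = _stack_phase(pairs, phase)
    e1, e2, e3 = cfg.epochs

    # stage 1: contracting path through a temporary auxiliary head
    if e1 > 0:
        aux = AuxEncoderHead(8 * net.base_channels, seed=cfg.seed, dtype=net.dtype)

        def fwd1(xb):
            return aux.forward(net.forward_encoder(xb, train=True), train=True)

        def bwd1(g):
            net.backward_encoder(aux.backward(g))

        _run_stage("encoder", fwd1, bwd1, net.encoder_params() + aux.params(),
                   x, y, e1, cfg, cfg.base_lr, rng, history)
        # the auxiliary head is discarded here; only encoder weights are kept

    # stage 2: entire network, same non-augmented data
    _run_stage("full", lambda xb: net.forward(xb, train=True), net.backward,
               net.params(), x, y, e2, cfg, cfg.base_lr, rng, history)

    # stage 3: fine-tune on augmented data
    if e3 > 0 and aug is not None and aug.multiplicity >= 1:
        aug_pairs, _ = build_augmented_dataset(pairs, aug)
        xa, ya = _stack_phase(aug_pairs, phase)
        _run_stage("augmented", lambda xb: net.forward(xb, train=True), net.backward,
                   net.params(), xa, ya, e3, cfg, cfg.base_lr, rng, history)

    # short trainings leave BN running stats far from the trained feature
    # distribution; recompute them exactly on the clean training slices
    net.recalibrate_bn(x, cfg.batch_size)

    return net.state_dict(), history


def split_training_subsets(case_ids: list[str], seed: int) -> tuple[list[str], list[str]]:
    """Random case-level split into two near-equal disjoint subsets.

    With an odd count the extra case goes to subset A (which trains the
    sub-networks).  Splitting is by case, never by slice, so no patient
    contributes to both subsets.
    """
    ids = list(case_ids)
    if len(ids) < 2:
        raise ValueError("need at least two cases to split")
    if len(set(ids)) != len(ids):
        raise ValueError("case ids must be unique")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    half = (len(order) + 1) // 2
    return sorted(order[:half]), sorted(order[half:])


def train_dfn(fnet: FusionNet, pairs: list[SlicePair], cfg: TrainConfig,
              aug: AugmentParams | None = None,
              alphas: tuple[float, float] = (0.5, 0.5),
              freeze_subnets: bool = False) -> tuple[dict, TrainHistory]:
    """Two-subset fusion training.

    Subset A staged-trains sub-network 1 on phase 1 and sub-network 2 on
    phase 2; subset B then trains the fusion network under the composite
    loss with SGD.  With ``freeze_subnets`` only the fusion block updates
    in the second phase.
    """
    case_ids = sorted({p.case_id for p in pairs})
    if len(case_ids) < 2:
        raise ValueError("fusion training needs at least two cases for the subset split")
    subset_a, subset_b = split_training_subsets(case_ids, cfg.seed)
    pairs_a = [p for p in pairs if p.case_id in subset_a]
    pairs_b = [p for p in pairs if p.case_id in subset_b]

    history = TrainHistory()
    # "same training strategy" for the sub-networks means the same
    # optimization budget: subset A is roughly half the data, so epochs are
    # scaled up to give the sub-networks the same number of gradient steps a
    # model trained on the full set would receive
    scale = len(pairs) / max(1, len(pairs_a))
    sub_cfg = dataclasses.replace(
        cfg, epochs=tuple(int(np.ceil(e * scale)) for e in cfg.epochs))
    for i, phase in enumerate((0, 1)):
        _, h = train_dcnn_staged(fnet.subnets[i], pairs_a, phase, sub_cfg, aug)
        for r in h.records:
            history.records.append(EpochRecord(stage=f"subnet{i + 1}-{r.stage}",
                                               epoch=r.epoch, mean_loss=r.mean_loss,
                                               mean_dsc=r.mean_dsc))

    # the fusion block sees few cases (half the training set); augmenting
    # subset B the same way as stage 3 varies the score-map statistics it
    # must threshold, which stabilizes the learned fusion
    pairs_b_fit = pairs_b
    if aug is not None and aug.multiplicity >= 1:
        pairs_b_fit, _ = build_augmented_dataset(pairs_b, aug)
    x1, y = _stack_phase(pairs_b_fit, 0)
    x2, _ = _stack_phase(pairs_b_fit, 1)
    opts = [SGD(fnet.fusion_params(), lr=cfg.dfn_lr, momentum=cfg.momentum)]
    if not freeze_subnets:
        # sub-networks fine-tune under the composite loss at their own
        # (typically much smaller) rate; the established weights should be
        # refined, not retrained
        sub_lr = cfg.dfn_subnet_lr if cfg.dfn_subnet_lr is not None else cfg.dfn_lr
        opts.append(SGD(fnet.subnets[0].params() + fnet.subnets[1].params(),
                        lr=sub_lr, momentum=cfg.momentum))

    cached = None
    if freeze_subnets:
        # frozen sub-networks make the score maps constants: compute them
        # once in eval mode, then train the (tiny) fusion block to full
        # convergence on the cached maps
        o1_all = np.concatenate([fnet.subnets[0].forward(x1[i:i + cfg.batch_size], False)
                                 for i in range(0, len(x1), cfg.batch_size)])
        o2_all = np.concatenate([fnet.subnets[1].forward(x2[i:i + cfg.batch_size], False)
                                 for i in range(0, len(x2), cfg.batch_size)])
        cached = (o1_all, o2_all)
        if fnet.fusion_mode == "sum":
            # start the fusion block at the best calibrated pixelwise rule on
            # the combined map; SGD then refines spatial structure
            s = (o1_all + o2_all).ravel()
            labels = (y.ravel() > 0)
            if labels.any() and not labels.all():
                from sklearn.linear_model import LogisticRegression
                sub = np.random.default_rng(cfg.seed).choice(
                    len(s), size=min(len(s), 50000), replace=False)
                lr_fit = LogisticRegression(max_iter=200).fit(
                    s[sub, None].astype(np.float64), labels[sub])
                fnet.init_fusion_passthrough(float(s.mean()), float(s.std()),
                                             float(lr_fit.coef_[0, 0]),
                                             float(lr_fit.intercept_[0]))

    rng = np.random.default_rng(cfg.seed + 1)
    n = len(x1)
    decay_at = max(1, int(cfg.epochs_fusion * 2 / 3))
    for epoch in range(cfg.epochs_fusion):
        if epoch == decay_at:
            for opt in opts:
                opt.lr *= 0.2  # settle into the minimum after coarse descent
        order = rng.permutation(n)
        losses = []
        tp = fp = fn = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if cached is not None:
                o1, o2 = cached[0][idx], cached[1][idx]
                p_out = fnet.forward_fusion_from_submaps(o1, o2, train=True)
            else:
                o1, o2, p_out = fnet.forward(x1[idx], x2[idx], train=True,
                                             train_subnets=True)
            for opt in opts:
                opt.zero_grad()
            breakdown = fnet.composite_backward(y[idx], o1, o2, p_out, alphas,
                                                cfg.smooth, freeze_subnets)
            if not np.isfinite(breakdown.total):
                raise TrainingError("non-finite composite loss", history=history)
            for opt in opts:
                opt.step()
            losses.append(breakdown.total)
            a, b, c = _hard_dsc(p_out, y[idx])
            tp, fp, fn = tp + a, fp + b, fn + c
        dsc = 2 * tp / (fp + 2 * tp + fn) if (tp + fp + fn) else 1.0
        history.records.append(EpochRecord(stage="fusion", epoch=epoch,
                                           mean_loss=float(np.mean(losses)),
                                           mean_dsc=float(dsc)))

    if cached is not None:
        for layer in fnet.fusion_layers:
            layer.bn.begin_calibration()
        for i in range(0, n, cfg.batch_size):
            fnet.forward_fusion_from_submaps(cached[0][i:i + cfg.batch_size],
                                             cached[1][i:i + cfg.batch_size], True)
        for layer in fnet.fusion_layers:
            layer.bn.end_calibration()
    else:
        fnet.recalibrate_fusion_bn(x1, x2, cfg.batch_size)
        fnet.subnets[0].recalibrate_bn(x1, cfg.batch_size)
        fnet.subnets[1].recalibrate_bn(x2, cfg.batch_size)
    return fnet.state_dict(), history


@dataclass
class FoldResult:
    """One cross-validation fold: held-out case, its score, and provenance."""

    case_id: str
    metrics: object
    train_ids: list[str]
    extra: dict = field(default_factory=dict)


def run_loocv(case_ids: list[str], fit_fn, eval_fn) -> list[FoldResult]:
    """Leave-one-out cross-validation over cases.

    ``fit_fn(train_ids, fold_index)`` returns a trained model;
    ``eval_fn(model, test_id)`` returns the per-case metrics (and optionally
    a dict of extras as a second return value).  One fold per case, each
    trained strictly without its test case.
    """
    ids = list(case_ids)
    if len(ids) < 2:
        raise ValueError("cross-validation needs at least two cases")
    results = []
    for k, test_id in enumerate(ids):
        train_ids = [c for c in ids if c != test_id]
        model = fit_fn(train_ids, k)
        out = eval_fn(model, test_id)
        metrics, extra = out if isinstance(out, tuple) else (out, {})
        results.append(FoldResult(case_id=test_id, metrics=metrics,
                                  train_ids=train_ids, extra=extra))
    return results
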
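"""End-to-end phantom experiments.

Experiment 1 trains and scores the single-phase model (DCNN-F, phase 1 only)
and the dual-phase fusion model (DFN-F) on full-size slices under
leave-one-case-out cross-validation.  Experiment 2 runs the ROI-constrained
fusion model (DFN-R): per-case boxes are derived from the ground-truth
bounding box with face jitter and a margin — a deterministic stand-in for a
radiologist's rough rectangles — and the fusion network is trained and
evaluated on crops only, with predictions pasted back into the full grid.

Every artifact an experiment writes is a deterministic function of its
configuration and master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .augment import AugmentParams
from .errors import GeometryError
from .evaluate import (TTestResult, aggregate_metrics, evaluate_masks,
                       make_report, paired_t_test, render_report_text)
from .nn import DcnnNet, FusionNet
from .nn.losses import binarize
from .phantom import PhantomCase, PhantomSpec, generate_dataset
from .preprocess import (RegistrationParams, SlicePair, normalize_intensity,
                         prepare_case_slices, register_phase2_to_phase1,
                         resample_slice, resize_bilinear)
from .roi import ROIBox, crop_to_roi, jitter_box, segment_roi
from .training import (FoldResult, TrainConfig, run_loocv, train_dcnn_staged,
                       train_dfn)

__all__ = ["ExperimentConfig", "smoke_preset", "desk_preset", "prepare_cases",
           "run_experiment1", "run_experiment2", "run_all", "compare_models",
           "segment_volume_single", "write_artifacts"]

MODEL_DCNN_F = "DCNN-F"
MODEL_DFN_F = "DFN-F"
MODEL_DFN_R = "DFN-R"


@dataclass(frozen=True)
class ExperimentConfig:
    """One phantom experiment: data conditions, model roster, budgets."""

    phantom: PhantomSpec = PhantomSpec()
    n_cases: int = 8
    master_seed: int = 0
    roster: tuple[str, ...] = (MODEL_DCNN_F, MODEL_DFN_F, MODEL_DFN_R)
    train: TrainConfig = TrainConfig()
    aug: AugmentParams = AugmentParams()
    registration: RegistrationParams = RegistrationParams()
    input_size: tuple[int, int] = (64, 64)
    roi_input_size: tuple[int, int] = (24, 24)
    roi_jitter: int = 2
    roi_margin: int = 2
    threshold: float = 0.5
    alphas: tuple[float, float] = (0.5, 0.5)
    fusion_channels: int = 8
    base_channels: int = 8
    freeze_subnets: bool = True

    def __post_init__(self):
        if not self.roster:
            raise ValueError("model roster must not be empty")
        unknown = set(self.roster) - {MODEL_DCNN_F, MODEL_DFN_F, MODEL_DFN_R}
        if unknown:
            raise ValueError(f"unknown models in roster: {sorted(unknown)}")


def smoke_preset(master_seed: int = 0, confounder: str = "organ_mimic",
                 n_cases: int = 4) -> ExperimentConfig:
    """The smallest preset: minutes on one CPU, 32x32x8 volumes, 4 cases."""
    return ExperimentConfig(
        phantom=PhantomSpec(volume_shape=(32, 32, 8), liver_axes=(12.0, 10.0, 4.5),
                            lesion_radius_range=(3.0, 4.5), confounder_mode=confounder,
                            deformation_amplitude=1.5, noise_sigma=0.02),
        n_cases=n_cases, master_seed=master_seed,
        train=TrainConfig(base_lr=3e-3, dfn_lr=0.02, epochs=(6, 18, 10),
                          epochs_fusion=40, seed=master_seed),
        aug=AugmentParams(multiplicity=4, seed=master_seed),
        registration=RegistrationParams(grid_spacing=12.0, levels=2, iterations=6),
        input_size=(32, 32), roi_input_size=(24, 24), base_channels=4,
        fusion_channels=4)


def desk_preset(master_seed: int = 0, confounder: str = "organ_mimic",
                n_cases: int = 8) -> ExperimentConfig:
    """Desk-scale preset: 64x64x16 volumes, 8 cases, base 8 channels."""
    return ExperimentConfig(
        phantom=PhantomSpec(confounder_mode=confounder),
        n_cases=n_cases, master_seed=master_seed,
        train=TrainConfig(base_lr=3e-3, dfn_lr=0.02, epochs=(8, 20, 12),
                          epochs_fusion=40, seed=master_seed),
        aug=AugmentParams(multiplicity=4, seed=master_seed),
        registration=RegistrationParams(grid_spacing=16.0, levels=2, iterations=15),
        input_size=(64, 64), base_channels=8)


def _fold_seed(master_seed: int, fold: int, salt: int = 0) -> int:
    return int((master_seed * 1000003 + fold * 7919 + salt * 104729) % (2**31 - 1))


@dataclass
class PreparedCase:
    """A phantom case after inter-phase registration and slice selection."""

    case: PhantomCase
    phase2_registered: np.ndarray
    pairs: list[SlicePair]
    roi_box: ROIBox | None = None


def prepare_cases(cfg: ExperimentConfig) -> dict[str, PreparedCase]:
    """Generate, register, and slice the phantom cohort (once per run)."""
    cases, _ = generate_dataset(cfg.phantom, cfg.n_cases, cfg.master_seed)
    prepared: dict[str, PreparedCase] = {}
    for i, case in enumerate(cases):
        if cfg.phantom.deformation_amplitude > 0:
            p2, _ = register_phase2_to_phase1(case.phase2, case.phase1,
                                              cfg.registration)
        else:
            p2 = np.asarray(case.phase2, dtype=np.float64)
        pairs = prepare_case_slices(case.phase1, p2, case.gt_mask,
                                    cfg.input_size, case.case_id)
        box = None
        if case.true_roi is not None:
            rng = np.random.default_rng(_fold_seed(cfg.master_seed, i, salt=11))
            box = jitter_box(case.true_roi, cfg.roi_jitter, cfg.roi_margin,
                             case.gt_mask.shape, rng)
        prepared[case.case_id] = PreparedCase(case=case, phase2_registered=p2,
                                              pairs=pairs, roi_box=box)
    return prepared


def segment_volume_single(net: DcnnNet, phase1: np.ndarray,
                          input_size: tuple[int, int],
                          threshold: float = 0.5) -> np.ndarray:
    """Full-volume single-phase inference, slice by slice."""
    shape = phase1.shape
    out = np.empty(shape, dtype=np.uint8)
    x = np.empty((shape[2], 1) + tuple(input_size), dtype=np.float32)
    for z in range(shape[2]):
        x[z, 0] = resample_slice(normalize_intensity(phase1[:, :, z]), input_size)
    scores = net.forward(x, train=False)
    for z in range(shape[2]):
        score = resize_bilinear(scores[z, 0], shape[:2])
        out[:, :, z] = binarize(score, threshold)
    return out


def _full_box(shape: tuple[int, int, int]) -> ROIBox:
    return ROIBox(x=(0, shape[0]), y=(0, shape[1]), z=(0, shape[2]))


def _roi_slices(pc: PreparedCase, box: ROIBox, roi_input_size) -> list[SlicePair]:
    """All slices of a case's ROI crop, normalized to the ROI network grid."""
    b1 = crop_to_roi(pc.case.phase1, box)
    b2 = crop_to_roi(pc.phase2_registered, box)
    bm = crop_to_roi(pc.case.gt_mask, box)
    out = []
    for z in range(b1.shape[2]):
        out.append(SlicePair(
            phase1_slice=resample_slice(normalize_intensity(b1[:, :, z]), roi_input_size),
            phase2_slice=resample_slice(normalize_intensity(b2[:, :, z]), roi_input_size),
            mask_slice=resample_slice(bm[:, :, z], roi_input_size, is_mask=True),
            case_id=pc.case.case_id, slice_index=z))
    return out


def run_experiment1(cfg: ExperimentConfig,
                    prepared: dict[str, PreparedCase] | None = None
                    ) -> dict[str, list[FoldResult]]:
    """Full-size models under LOOCV: DCNN-F (phase 1 only) and/or DFN-F."""
    roster = [m for m in cfg.roster if m in (MODEL_DCNN_F, MODEL_DFN_F)]
    if not roster:
        raise ValueError("experiment 1 needs DCNN-F and/or DFN-F in the roster")
    prepared = prepared or prepare_cases(cfg)
    ids = sorted(prepared)
    results: dict[str, list[FoldResult]] = {}

    if MODEL_DCNN_F in roster:
        def fit_dcnn(train_ids, fold):
            pairs = [p for cid in train_ids for p in prepared[cid].pairs]
            net = DcnnNet(cfg.base_channels, seed=_fold_seed(cfg.master_seed, fold, 1))
            train_cfg = dataclasses.replace(cfg.train,
                                            seed=_fold_seed(cfg.master_seed, fold, 2))
            train_dcnn_staged(net, pairs, 0, train_cfg, cfg.aug)
            return net

        def eval_dcnn(net, cid):
            pc = prepared[cid]
            pred = segment_volume_single(net, pc.case.phase1, cfg.input_size,
                                         cfg.threshold)
            return evaluate_masks(pred, pc.case.gt_mask)

        results[MODEL_DCNN_F] = run_loocv(ids, fit_dcnn, eval_dcnn)

    if MODEL_DFN_F in roster:
        def fit_dfn(train_ids, fold):
            pairs = [p for cid in train_ids for p in prepared[cid].pairs]
            fnet = FusionNet(cfg.base_channels, cfg.fusion_channels,
                             seed=_fold_seed(cfg.master_seed, fold, 3))
            train_cfg = dataclasses.replace(cfg.train,
                                            seed=_fold_seed(cfg.master_seed, fold, 4))
            train_dfn(fnet, pairs, train_cfg, cfg.aug, cfg.alphas,
                      cfg.freeze_subnets)
            return fnet

        def eval_dfn(fnet, cid):
            pc = prepared[cid]
            pred = segment_roi(fnet, pc.case.phase1, pc.phase2_registered,
                               _full_box(pc.case.phase1.shape), cfg.input_size,
                               cfg.threshold)
            return evaluate_masks(pred, pc.case.gt_mask)

        results[MODEL_DFN_F] = run_loocv(ids, fit_dfn, eval_dfn)

    return results


def run_experiment2(cfg: ExperimentConfig,
                    prepared: dict[str, PreparedCase] | None = None
                    ) -> dict[str, list[FoldResult]]:
    """ROI-constrained fusion model (DFN-R) under LOOCV."""
    if MODEL_DFN_R not in cfg.roster:
        raise ValueError("experiment 2 needs DFN-R in the roster")
    prepared = prepared or prepare_cases(cfg)
    ids = sorted(prepared)
    for cid in ids:
        if prepared[cid].roi_box is None:
            raise GeometryError(f"case {cid} has no ROI (empty ground truth)")

    def fit_dfn_r(train_ids, fold):
        pairs = [p for cid in train_ids
                 for p in _roi_slices(prepared[cid], prepared[cid].roi_box,
                                      cfg.roi_input_size)]
        fnet = FusionNet(cfg.base_channels, cfg.fusion_channels,
                         seed=_fold_seed(cfg.master_seed, fold, 5))
        train_cfg = dataclasses.replace(cfg.train,
                                        seed=_fold_seed(cfg.master_seed, fold, 6))
        train_dfn(fnet, pairs, train_cfg, cfg.aug, cfg.alphas,
                  cfg.freeze_subnets)
        return fnet

    def eval_dfn_r(fnet, cid):
        pc = prepared[cid]
        pred = segment_roi(fnet, pc.case.phase1, pc.phase2_registered,
                           pc.roi_box, cfg.roi_input_size, cfg.threshold)
        return evaluate_masks(pred, pc.case.gt_mask), {"roi_box": pc.roi_box}

    return {MODEL_DFN_R: run_loocv(ids, fit_dfn_r, eval_dfn_r)}


def run_all(cfg: ExperimentConfig) -> dict[str, list[FoldResult]]:
    """Run every roster model on one shared prepared cohort."""
    prepared = prepare_cases(cfg)
    results: dict[str, list[FoldResult]] = {}
    if set(cfg.roster) & {MODEL_DCNN_F, MODEL_DFN_F}:
        exp1_cfg = cfg if MODEL_DFN_R not in cfg.roster else dataclasses.replace(
            cfg, roster=tuple(m for m in cfg.roster if m != MODEL_DFN_R))
        results.update(run_experiment1(exp1_cfg, prepared))
    if MODEL_DFN_R in cfg.roster:
        results.update(run_experiment2(cfg, prepared))
    return results


def compare_models(results: dict[str, list[FoldResult]],
                   baseline: str | None = None):
    """Summaries, baseline paired t-tests, and the report table.

    Per-case DSC vectors are compared with a two-sided paired t-test against
    ``baseline`` (default: the first model); the baseline row itself carries
    no p-value.  All models must cover the same case set.
    """
    if len(results) < 1:
        raise ValueError("no model results to compare")
    case_sets = {m: tuple(f.case_id for f in folds) for m, folds in results.items()}
    if len(set(case_sets.values())) != 1:
        raise ValueError(f"case sets differ between models: {case_sets}")
    models = list(results)
    baseline = baseline or models[0]
    summaries = {m: aggregate_metrics([f.metrics for f in folds])
                 for m, folds in results.items()}
    dsc = {m: [f.metrics.dsc for f in folds] for m, folds in results.items()}
    tests: dict[str, TTestResult] = {}
    if len(models) > 1:
        for m in models:
            if m != baseline and len(dsc[m]) >= 2:
                tests[m] = paired_t_test(dsc[m], dsc[baseline])
    report = make_report(summaries, tests)
    return summaries, tests, report


def write_artifacts(cfg: ExperimentConfig, results: dict[str, list[FoldResult]],
                    out_dir: str | Path) -> None:
    """Persist metrics, fold manifests, and the comparison report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics = {m: {f.case_id: {"dsc": f.metrics.dsc,
                               "precision": f.metrics.precision,
                               "recall": f.metrics.recall}
                   for f in folds}
               for m, folds in results.items()}
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    folds = {m: {f.case_id: f.train_ids for f in fr} for m, fr in results.items()}
    (out / "folds.json").write_text(json.dumps(folds, indent=2, sort_keys=True))
    (out / "config.json").write_text(json.dumps(
        {"phantom": dataclasses.asdict(cfg.phantom), "n_cases": cfg.n_cases,
         "master_seed": cfg.master_seed, "roster": list(cfg.roster)},
        indent=2, sort_keys=True))
    _, _, report = compare_models(results)
    report.to_csv(out / "report.csv", index=False)
    (out / "report.txt").write_text(render_report_text(report) + "\n")
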
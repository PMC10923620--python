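"""Preprocessing: inter-phase registration, slice selection, resampling.

The portal-venous-phase volume is registered to the hepatobiliary-phase grid
with a multiresolution B-spline free-form deformation (SimpleITK), so that
"the co-registered phase-2 slice at z" is well defined on one canonical grid.
Tumor-bearing axial slices are then selected, and every network input slice
is min-max normalized and resampled to the network grid (bilinear for images,
nearest-neighbor for masks; the target size must be divisible by 8 because
the network pools three times).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from skimage.transform import resize as _sk_resize

from .errors import RegistrationError

__all__ = ["RegistrationParams", "SlicePair", "register_phase2_to_phase1",
           "select_tumor_slices", "resample_slice", "resize_bilinear",
           "normalize_intensity", "prepare_case_slices"]


@dataclass(frozen=True)
class RegistrationParams:
    """B-spline registration settings.

    ``grid_spacing`` is the control-point spacing in voxels at the finest
    level; three image-pyramid levels (shrink 4/2/1) are used by default.
    The mean-squared intensity metric is evaluated on the full voxel grid
    (no random sampling), which makes the optimization deterministic.
    """

    grid_spacing: float = 16.0
    levels: int = 3
    iterations: int = 40
    divergence_tolerance: float = 1.05  # final metric may not exceed initial * tol


@dataclass
class SlicePair:
    """One co-registered axial slice pair with its binary mask."""

    phase1_slice: np.ndarray
    phase2_slice: np.ndarray
    mask_slice: np.ndarray
    case_id: str = ""
    slice_index: int = -1

    def __post_init__(self):
        shapes = {self.phase1_slice.shape, self.phase2_slice.shape, self.mask_slice.shape}
        if len(shapes) != 1:
            raise ValueError(f"slice pair shapes differ: {shapes}")
        vals = np.unique(self.mask_slice)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask slice must be binary")


def _to_sitk(arr: np.ndarray) -> sitk.Image:
    # package arrays are (x, y, z); SimpleITK expects (z, y, x) buffers
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0), dtype=np.float64))
    img.SetSpacing((1.0, 1.0, 1.0))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0)


def register_phase2_to_phase1(moving: np.ndarray, fixed: np.ndarray,
                              params: RegistrationParams | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Deformably register ``moving`` onto the ``fixed`` grid.

    Returns the resampled moving volume and the displacement field as an
    ``(X, Y, Z, 3)`` array in voxel units: the field maps fixed-grid
    coordinates to the moving-grid coordinates they correspond to.

    Raises :class:`RegistrationError` (with the metric trace attached) if
    the optimizer ends worse than it started.
    """
    params = params or RegistrationParams()
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if not (np.all(np.isfinite(moving)) and np.all(np.isfinite(fixed))):
        raise ValueError("registration inputs must be finite")
    if moving.shape != fixed.shape:
        raise ValueError(f"shapes differ: moving {moving.shape} vs fixed {fixed.shape}")

    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)  # deterministic metric sums
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)

    mesh = [max(1, int(round(sz / params.grid_spacing))) for sz in f_img.GetSize()]
    tx = sitk.BSplineTransformInitializer(f_img, mesh)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-7,
                             numberOfIterations=params.iterations)
    reg.SetInitialTransform(tx, inPlace=True)
    shrink = [2 ** (params.levels - 1 - i) for i in range(params.levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(0, s - 1) for s in shrink])

    trace: list[float] = []
    level_starts: list[int] = []
    reg.AddCommand(sitk.sitkIterationEvent, lambda: trace.append(reg.GetMetricValue()))
    reg.AddCommand(sitk.sitkMultiResolutionIterationEvent,
                   lambda: level_starts.append(len(trace)))
    reg.Execute(f_img, m_img)

    # metric values are only comparable within one pyramid level, so
    # divergence is judged on the finest level's trace
    final_trace = trace[level_starts[-1]:] if level_starts else trace
    if len(final_trace) >= 2 and final_trace[-1] > final_trace[0] * params.divergence_tolerance:
        raise RegistrationError(
            f"registration diverged: metric {final_trace[0]:.6g} -> {final_trace[-1]:.6g}",
            metric_trace=trace)

    # nearest-neighbor extrapolation avoids constant-fill artifacts where the
    # warp samples outside the moving volume at the boundary
    registered = sitk.Resample(m_img, f_img, tx, sitk.sitkLinear,
                               float(moving.min()), sitk.sitkFloat64, True)
    reg_arr = _from_sitk(registered)
    disp_img = sitk.TransformToDisplacementField(
        tx, sitk.sitkVectorFloat64, f_img.GetSize(), f_img.GetOrigin(),
        f_img.GetSpacing(), f_img.GetDirection())
    # (z, y, x, 3) with (x, y, z) vector components -> (x, y, z, 3)
    field = sitk.GetArrayFromImage(disp_img).transpose(2, 1, 0, 3)
    return reg_arr, field


def select_tumor_slices(phase1: np.ndarray, phase2_registered: np.ndarray,
                        mask: np.ndarray, case_id: str = "") -> list[SlicePair]:
    """Extract exactly the axial slices where the mask has foreground.

    The mask lives on the phase-1 grid; phase 2 must already be registered
    onto that grid.  Returns pairs in ascending z; an empty mask yields an
    empty list.
    """
    mask = np.asarray(mask)
    if mask.shape != phase1.shape or phase2_registered.shape != phase1.shape:
        raise ValueError("phase volumes and mask must share one grid")
    pairs = []
    for z in range(mask.shape[2]):
        if mask[:, :, z].any():
            pairs.append(SlicePair(
                phase1_slice=np.asarray(phase1[:, :, z]),
                phase2_slice=np.asarray(phase2_registered[:, :, z]),
                mask_slice=(mask[:, :, z] > 0).astype(np.uint8),
                case_id=case_id, slice_index=z))
    return pairs


def resize_bilinear(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear resize without the network-size constraint (score maps etc.)."""
    if tuple(img.shape) == tuple(target):
        return np.asarray(img).copy()
    return _sk_resize(np.asarray(img, dtype=np.float64), target, order=1,
                      mode="edge", anti_aliasing=False,
                      preserve_range=True).astype(img.dtype if
                                                  np.issubdtype(np.asarray(img).dtype, np.floating)
                                                  else np.float32)


def resample_slice(img: np.ndarray, target: tuple[int, int],
                   is_mask: bool = False) -> np.ndarray:
    """Resample a slice to the network input grid.

    Bilinear interpolation for images, nearest-neighbor for masks (values
    stay in {0, 1}).  ``target`` must be >= 8 and divisible by 8, matching
    the three pooling stages of the network.
    """
    h, w = target
    if h < 8 or w < 8 or h % 8 or w % 8:
        raise ValueError(f"target size {target} must be >= 8 and divisible by 8")
    img = np.asarray(img)
    if tuple(img.shape) == (h, w):
        return img.copy()
    if is_mask:
        out = _sk_resize(img.astype(np.float64), target, order=0, mode="edge",
                         anti_aliasing=False, preserve_range=True)
        return (out > 0.5).astype(np.uint8)
    return _sk_resize(img.astype(np.float64), target, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True).astype(np.float32)


def normalize_intensity(img: np.ndarray) -> np.ndarray:
    """Per-slice min-max scaling to [0, 1]; a constant slice maps to zeros."""
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("normalize_intensity requires finite input")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img, dtype=np.float32)
    return ((img - lo) / (hi - lo)).astype(np.float32)


def prepare_case_slices(phase1: np.ndarray, phase2_registered: np.ndarray,
                        mask: np.ndarray, input_size: tuple[int, int],
                        case_id: str = "") -> list[SlicePair]:
    """Select tumor slices, then normalize and resample them for the network."""
    pairs = select_tumor_slices(phase1, phase2_registered, mask, case_id)
    out = []
    for sp in pairs:
        out.append(SlicePair(
            phase1_slice=resample_slice(normalize_intensity(sp.phase1_slice), input_size),
            phase2_slice=resample_slice(normalize_intensity(sp.phase2_slice), input_size),
            mask_slice=resample_slice(sp.mask_slice, input_size, is_mask=True),
            case_id=sp.case_id, slice_index=sp.slice_index))
    return out
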
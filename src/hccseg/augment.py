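"""Training-set augmentation: rotation, scaling, contrast, noise, mirroring.

The five augmentation families are applied consistently to a slice pair: the
geometric transform (rotation in [-20, 20] degrees, isotropic scale in
[0.9, 1.1], optional horizontal mirror) is shared by phase 1, phase 2, and
the mask, while the photometric transforms (contrast shift in [-5, 5] on a
0-255 intensity scale, additive Gaussian noise) are drawn independently per
phase and never touch the mask.  Masks are warped with nearest-neighbor
interpolation and stay binary; pixels rotated/scaled out of canvas are
filled with 0 (the background intensity after normalization).

Every augmented pair records the draw that produced it, so any sample can be
replayed exactly from its source pair and draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import SlicePair

__all__ = ["AugmentParams", "AugmentDraw", "sample_draw", "augment_pair",
           "plan_augmentation", "build_augmented_dataset"]


@dataclass(frozen=True)
class AugmentParams:
    """Configured augmentation ranges (defaults are the standard protocol)."""

    rotation_deg: tuple[float, float] = (-20.0, 20.0)
    scale: tuple[float, float] = (0.9, 1.1)
    contrast_shift: tuple[float, float] = (-5.0, 5.0)  # additive, 0-255 scale
    contrast_mode: str = "additive"  # or "multiplicative": percent change
    noise_sigma: float = 0.01  # fraction of dynamic range
    mirror: bool = True
    multiplicity: int = 1
    include_originals: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.multiplicity < 0:
            raise ValueError("multiplicity must be >= 0")
        if self.contrast_mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown contrast_mode {self.contrast_mode!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class AugmentDraw:
    """One sampled augmentation instance (fully determines the transform)."""

    rotation_deg: float = 0.0
    scale: float = 1.0
    mirror: bool = False
    contrast1: float = 0.0
    contrast2: float = 0.0
    noise_sigma: float = 0.0
    noise_seed1: int = 0
    noise_seed2: int = 0


def sample_draw(params: AugmentParams, rng: np.random.Generator) -> AugmentDraw:
    return AugmentDraw(
        rotation_deg=float(rng.uniform(*params.rotation_deg)),
        scale=float(rng.uniform(*params.scale)),
        mirror=bool(params.mirror and rng.integers(2)),
        contrast1=float(rng.uniform(*params.contrast_shift)),
        contrast2=float(rng.uniform(*params.contrast_shift)),
        noise_sigma=params.noise_sigma,
        noise_seed1=int(rng.integers(0, 2**31 - 1)),
        noise_seed2=int(rng.integers(0, 2**31 - 1)),
    )


def _check_draw(draw: AugmentDraw, params: AugmentParams) -> None:
    lo, hi = params.rotation_deg
    if not lo <= draw.rotation_deg <= hi:
        raise ValueError(f"rotation {draw.rotation_deg} outside configured range {params.rotation_deg}")
    lo, hi = params.scale
    if not lo <= draw.scale <= hi:
        raise ValueError(f"scale {draw.scale} outside configured range {params.scale}")
    lo, hi = params.contrast_shift
    for c in (draw.contrast1, draw.contrast2):
        if not lo <= c <= hi:
            raise ValueError(f"contrast shift {c} outside configured range {params.contrast_shift}")
    if draw.mirror and not params.mirror:
        raise ValueError("mirroring drawn but disabled in params")


def _geometric(img: np.ndarray, draw: AugmentDraw, order: int) -> np.ndarray:
    out = np.asarray(img)
    if draw.mirror:
        out = out[::-1, :]
    if draw.rotation_deg == 0.0 and draw.scale == 1.0:
        return np.ascontiguousarray(out)
    theta = np.deg2rad(draw.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    # output pixel x maps to input pixel c + R/s (x - c)
    matrix = rot / draw.scale
    center = (np.asarray(out.shape) - 1) / 2.0
    offset = center - matrix @ center
    return ndimage.affine_transform(out.astype(np.float64), matrix, offset=offset,
                                    order=order, mode="constant", cval=0.0,
                                    output_shape=out.shape)


def _photometric(img: np.ndarray, contrast: float, mode: str,
                 noise_sigma: float, noise_seed: int) -> np.ndarray:
    out = np.asarray(img, dtype=np.float64)
    if mode == "additive":
        out = out + contrast / 255.0
    else:
        out = out * (1.0 + contrast / 100.0)
    if noise_sigma > 0:
        out = out + np.random.default_rng(noise_seed).normal(0.0, noise_sigma, out.shape)
    return np.clip(out, 0.0, 1.0)


def augment_pair(sp: SlicePair, draw: AugmentDraw,
                 params: AugmentParams | None = None) -> SlicePair:
    """Apply one drawn augmentation to a slice pair (replayable)."""
    if params is not None:
        _check_draw(draw, params)
    p1 = _geometric(sp.phase1_slice, draw, order=1)
    p2 = _geometric(sp.phase2_slice, draw, order=1)
    mk = _geometric(sp.mask_slice, draw, order=0)
    p1 = _photometric(p1, draw.contrast1, "additive" if params is None else params.contrast_mode,
                      draw.noise_sigma, draw.noise_seed1)
    p2 = _photometric(p2, draw.contrast2, "additive" if params is None else params.contrast_mode,
                      draw.noise_sigma, draw.noise_seed2)
    return SlicePair(phase1_slice=p1.astype(np.float32),
                     phase2_slice=p2.astype(np.float32),
                     mask_slice=(np.asarray(mk) > 0.5).astype(np.uint8),
                     case_id=sp.case_id, slice_index=sp.slice_index)


def plan_augmentation(n_pairs: int, params: AugmentParams) -> list[tuple[int, AugmentDraw]]:
    """Deterministic augmentation plan: (source index, draw) per output pair.

    The plan has ``n_pairs * multiplicity`` augmented entries (plus the
    originals, appended by :func:`build_augmented_dataset` when
    ``include_originals`` is set, which are not part of the plan).
    """
    if n_pairs < 1:
        raise ValueError("need at least one source pair")
    rng = np.random.default_rng(params.seed)
    plan = []
    for _ in range(params.multiplicity):
        for i in range(n_pairs):
            plan.append((i, sample_draw(params, rng)))
    return plan


def build_augmented_dataset(pairs: list[SlicePair], params: AugmentParams
                            ) -> tuple[list[SlicePair], list[tuple[int, AugmentDraw]]]:
    """Materialize the augmented training set.

    Output size is ``len(pairs) * multiplicity`` augmented pairs, with the
    originals appended afterwards when ``include_originals`` is true.  The
    returned plan records (source index, draw) for every augmented pair, in
    order, enabling exact replay.
    """
    if not pairs:
        raise ValueError("cannot augment an empty dataset")
    if params.multiplicity < 1:
        raise ValueError("multiplicity must be >= 1 to build an augmented dataset")
    plan = plan_augmentation(len(pairs), params)
    out = [augment_pair(pairs[i], draw, params) for i, draw in plan]
    if params.include_originals:
        out.extend(pairs)
    return out, plan
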
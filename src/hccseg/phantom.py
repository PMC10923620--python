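"""Synthetic dual-phase liver phantoms with ground truth.

The generator emulates the statistical structure the segmentation method
relies on, without attempting physical MR simulation:

* an ellipsoidal liver on a dark background, with mild smooth texture;
* lobulated lesions (ellipsoids perturbed by low-frequency radial noise)
  that are hypointense in phase 1 (hepatobiliary-like) and carry an
  independent, configurable contrast in phase 2 (portal-venous-like);
* optional confounders reproducing the two known single-phase failure
  modes: ``organ_mimic`` adds a structure whose phase-1 intensity matches
  the lesion but whose phase-2 intensity matches normal liver (so phase 1
  alone cannot separate it from tumor, phase 2 can), and
  ``unclear_boundary`` blurs the lesion rim so the intensity gradient
  across the border drops by a measurable factor;
* a smooth inter-phase misalignment built from Gaussian displacement
  bumps, with the exact ground-truth field stored for registration tests;
* additive Gaussian noise, independent per phase.

All intensities live in ``[0, 1]`` and every output is a deterministic
function of ``(spec, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import PlacementError
from .roi import ROIBox, bounding_box

__all__ = ["PhantomSpec", "PhantomCase", "generate_phantom", "generate_dataset"]

_BACKGROUND = 0.08
_LIVER = 0.60
_TEXTURE_AMP = 0.02
_EDGE_BLUR_SIGMA = 2.0  # unclear_boundary rim smoothing, voxels
_MAX_PLACEMENT_TRIES = 200


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom case.

    ``contrast_phase1``/``contrast_phase2`` are signed intensity offsets of
    the lesion against liver parenchyma (negative = hypointense).  The
    defaults encode the standard presentation: markedly hypointense in the
    hepatobiliary-like phase, mildly hypointense in the portal-venous-like
    phase.  ``deformation_amplitude`` is the maximum displacement (voxels)
    of phase 2 relative to phase 1; ``noise_sigma`` is the Gaussian noise
    standard deviation as a fraction of the [0, 1] dynamic range.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 16)
    liver_axes: tuple[float, float, float] = (24.0, 20.0, 10.0)
    n_lesions: int = 1
    lesion_radius_range: tuple[float, float] = (4.0, 7.0)
    contrast_phase1: float = -0.35
    contrast_phase2: float = -0.10
    confounder_mode: str = "none"
    deformation_amplitude: float = 2.0
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if len(self.volume_shape) != 3 or any(s < 8 for s in self.volume_shape):
            raise ValueError(f"volume_shape must be a triple >= 8, got {self.volume_shape}")
        if self.confounder_mode not in ("none", "organ_mimic", "unclear_boundary"):
            raise ValueError(f"unknown confounder_mode {self.confounder_mode!r}")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        rmin, rmax = self.lesion_radius_range
        if not 0 < rmin <= rmax:
            raise ValueError(f"bad lesion_radius_range {self.lesion_radius_range}")
        if rmax >= min(self.liver_axes[:2]):
            raise ValueError("lesion radius range does not fit inside liver axes")
        if self.noise_sigma < 0 or self.deformation_amplitude < 0:
            raise ValueError("noise_sigma and deformation_amplitude must be >= 0")


@dataclass
class PhantomCase:
    """One generated case: two phases, ground truth, and provenance."""

    phase1: np.ndarray
    phase2: np.ndarray
    gt_mask: np.ndarray
    true_roi: Optional[ROIBox]
    true_deformation: np.ndarray  # (X, Y, Z, 3) voxel displacements, fixed->moving
    manifest: dict = field(default_factory=dict)
    liver_mask: np.ndarray | None = None
    mimic_mask: np.ndarray | None = None
    phase2_aligned: np.ndarray | None = None  # phase 2 before misalignment
    case_id: str = "case"


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise, normalized to max |value| = 1."""
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.abs(n).max()
    return n / peak if peak > 0 else n


def _ellipsoid_coord(shape, center, axes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    return np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes)))


def _place_lesion(rng: np.random.Generator, spec: PhantomSpec, center_liver,
                  occupied: np.ndarray) -> tuple[np.ndarray, float]:
    """Sample one lobulated lesion mask fully inside the liver."""
    shape = spec.volume_shape
    ax, ay, az = spec.liver_axes
    rmin, rmax = spec.lesion_radius_range
    for _ in range(_MAX_PLACEMENT_TRIES):
        r = float(rng.uniform(rmin, rmax))
        rz = max(1.5, r * az / max(ax, ay) * 1.5)  # flattened like the liver
        # sample a center; accept if the perturbed lesion fits inside the liver
        u = rng.uniform(-0.6, 0.6, size=3)
        center = np.asarray(center_liver) + u * np.array([ax, ay, az])
        lesion_axes = (r, r, rz)
        margin = 1.3  # radial-perturbation + one-voxel safety factor
        shrunk = (ax - margin * r, ay - margin * r, az - margin * rz)
        if min(shrunk) <= 0:
            continue  # a lesion this large cannot fit anywhere in the liver
        fit = _ellipsoid_coord(shape, center, shrunk)
        cidx = tuple(int(np.clip(round(c), 0, s - 1)) for c, s in zip(center, shape))
        if fit[cidx] > 1.0:
            continue
        pert = _smooth_noise(rng, shape, sigma=4.0)
        dist = _ellipsoid_coord(shape, center, lesion_axes)
        mask = dist <= 1.0 + 0.2 * pert
        if mask.sum() < 4 or (mask & occupied).any():
            continue
        return mask, r
    raise PlacementError(
        f"could not place a lesion inside the liver after {_MAX_PLACEMENT_TRIES} "
        f"tries for spec {spec}")


def _invert_field(v: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """Fixed-point inverse of a displacement field: u(y) = -v(y + u(y))."""
    shape = v.shape[:3]
    grids = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                 indexing="ij"), axis=-1)
    u = np.zeros_like(v)
    for _ in range(n_iter):
        coords = (grids + u).transpose(3, 0, 1, 2)
        sampled = np.stack(
            [ndimage.map_coordinates(v[..., k], coords, order=1, mode="nearest")
             for k in range(3)], axis=-1)
        u = -sampled
    return u


def _deformation_field(rng: np.random.Generator, spec: PhantomSpec,
                       liver_mask: np.ndarray) -> np.ndarray:
    """Sum of Gaussian displacement bumps, capped at the requested amplitude.

    The smoothing sigma is kept above twice the amplitude so the field stays
    smooth and invertible in practice.
    """
    shape = spec.volume_shape
    amp = spec.deformation_amplitude
    field3 = np.zeros(shape + (3,))
    if amp == 0:
        return field3
    sigma = max(8.0, 2.5 * amp)
    centers = np.argwhere(liver_mask)
    for _ in range(3):
        c = centers[rng.integers(len(centers))]
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        d2 = _ellipsoid_coord(shape, c, (sigma, sigma, max(2.0, sigma / 3))) ** 2
        bump = np.exp(-0.5 * d2)
        field3 += bump[..., None] * direction
    peak = np.linalg.norm(field3, axis=-1).max()
    if peak > 0:
        field3 *= amp / peak
    return field3


def _warp(volume: np.ndarray, field3: np.ndarray) -> np.ndarray:
    """Sample ``volume`` at ``x + field(x)`` (pull-back warp)."""
    shape = volume.shape
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    coords = [g + field3[..., k] for k, g in enumerate(grids)]
    return ndimage.map_coordinates(volume, coords, order=1, mode="nearest")


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one dual-phase phantom case from a spec (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.volume_shape
    center = tuple((s - 1) / 2.0 for s in shape)

    liver = _ellipsoid_coord(shape, center, spec.liver_axes) <= 1.0
    texture = _TEXTURE_AMP * _smooth_noise(rng, shape, sigma=3.0)

    gt = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_lesions):
        mask, _ = _place_lesion(rng, spec, center, occupied=gt)
        gt |= mask
    gt &= liver  # belt and braces; placement already guarantees this

    mimic = None
    if spec.confounder_mode == "organ_mimic" and liver.any():
        # a structure that phase 1 cannot tell from tumor but phase 2 can
        for _ in range(_MAX_PLACEMENT_TRIES):
            mask, _ = _place_lesion(rng, spec, center, occupied=gt)
            mask &= liver
            if mask.any() and not (ndimage.binary_dilation(gt, iterations=2) & mask).any():
                mimic = mask
                break
        if mimic is None:
            raise PlacementError(f"could not place an organ mimic for spec {spec}")

    delta1 = np.where(gt, spec.contrast_phase1, 0.0)
    delta2 = np.where(gt, spec.contrast_phase2, 0.0)
    if mimic is not None:
        delta1 = delta1 + np.where(mimic, spec.contrast_phase1, 0.0)
        # phase 2: mimic stays at normal liver intensity (delta 0)
    if spec.confounder_mode == "unclear_boundary":
        delta1 = ndimage.gaussian_filter(delta1, _EDGE_BLUR_SIGMA)
        delta2 = ndimage.gaussian_filter(delta2, _EDGE_BLUR_SIGMA)

    base = np.where(liver, _LIVER + texture, _BACKGROUND)
    phase1 = base + delta1
    phase2_aligned = np.where(liver, _LIVER + texture, _BACKGROUND) + delta2

    field3 = _deformation_field(rng, spec, liver if liver.any() else np.ones(shape, bool))
    if spec.deformation_amplitude > 0:
        inv = _invert_field(field3)
        phase2 = _warp(phase2_aligned, inv)
    else:
        phase2 = phase2_aligned.copy()

    if spec.noise_sigma > 0:
        phase1 = phase1 + rng.normal(0.0, spec.noise_sigma, shape)
        phase2 = phase2 + rng.normal(0.0, spec.noise_sigma, shape)
    phase1 = np.clip(phase1, 0.0, 1.0).astype(np.float32)
    phase2 = np.clip(phase2, 0.0, 1.0).astype(np.float32)
    phase2_aligned = np.clip(phase2_aligned, 0.0, 1.0).astype(np.float32)

    gt8 = gt.astype(np.uint8)
    return PhantomCase(
        phase1=phase1,
        phase2=phase2,
        gt_mask=gt8,
        true_roi=bounding_box(gt8),
        true_deformation=field3.astype(np.float32),
        manifest={"spec": dataclasses.asdict(spec), "seed": spec.seed},
        liver_mask=liver.astype(np.uint8),
        mimic_mask=None if mimic is None else mimic.astype(np.uint8),
        phase2_aligned=phase2_aligned,
    )


def generate_dataset(spec: PhantomSpec, n_cases: int, seed: int) -> tuple[list[PhantomCase], dict]:
    """Generate ``n_cases`` phantoms with per-case seeds derived from ``seed``.

    Returns the cases and a manifest recording every derived seed, so the
    whole dataset is reproducible from ``(spec, n_cases, seed)`` alone.
    """
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    master = np.random.default_rng(seed)
    case_seeds: list[int] = []
    seen: set[int] = set()
    while len(case_seeds) < n_cases:
        s = int(master.integers(0, 2**31 - 1))
        if s not in seen:
            seen.add(s)
            case_seeds.append(s)
    cases = []
    for i, s in enumerate(case_seeds):
        case_spec = dataclasses.replace(spec, seed=s)
        case = generate_phantom(case_spec)
        case.case_id = f"case{i:03d}"
        cases.append(case)
    manifest = {
        "master_seed": int(seed),
        "n_cases": int(n_cases),
        "spec": dataclasses.asdict(spec),
        "case_seeds": {f"case{i:03d}": s for i, s in enumerate(case_seeds)},
    }
    return cases, manifest
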
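"""Radiologist ROI geometry and ROI-constrained inference.

The semiautomatic workflow has a radiologist drag three axis-aligned
rectangles — one each on the x-y, x-z, and y-z planes — around the tumor.
The 3D ROI box takes, per axis, the union of the two rectangle ranges that
constrain that axis (x from the x-y and x-z rectangles, and so on), plus a
safety margin, so that every voxel any rectangle admits is inside the box:
the costly error in this workflow is excluding tumor, not including liver.

All coordinates are 0-based voxel indices with half-open ranges ``[lo, hi)``
on the phase-1 grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GeometryError

__all__ = ["PlanarRectangle", "ROIBox", "box_from_rectangles", "bounding_box",
           "jitter_box", "crop_to_roi", "paste_into_full", "segment_roi",
           "save_roi", "load_roi"]

_PLANE_AXES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


@dataclass(frozen=True)
class PlanarRectangle:
    """A dragged rectangle on one named plane; ranges are ``[lo, hi)``."""

    plane: str
    first: tuple[int, int]
    second: tuple[int, int]

    def __post_init__(self):
        if self.plane not in _PLANE_AXES:
            raise ValueError(f"plane must be one of {sorted(_PLANE_AXES)}, got {self.plane!r}")
        for rng in (self.first, self.second):
            if rng[0] >= rng[1]:
                raise ValueError(f"empty rectangle range {rng} on plane {self.plane}")


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned 3D box on the phase-1 grid, half-open per axis."""

    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]
    margin: int = 0

    def __post_init__(self):
        for axis, rng in zip("xyz", (self.x, self.y, self.z)):
            if rng[0] >= rng[1]:
                raise GeometryError(f"degenerate ROI range on {axis}: {rng}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x[1] - self.x[0], self.y[1] - self.y[0], self.z[1] - self.z[0])

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.x), slice(*self.y), slice(*self.z))

    def contains_mask(self, mask: np.ndarray) -> bool:
        """True if every foreground voxel of ``mask`` lies inside the box."""
        idx = np.argwhere(np.asarray(mask) > 0)
        if idx.size == 0:
            return True
        lo = np.array([self.x[0], self.y[0], self.z[0]])
        hi = np.array([self.x[1], self.y[1], self.z[1]])
        return bool(np.all(idx >= lo) and np.all(idx < hi))


def _union(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
    return (min(a[0], b[0]), max(a[1], b[1]))


def box_from_rectangles(rxy: PlanarRectangle, rxz: PlanarRectangle,
                        ryz: PlanarRectangle, margin: int,
                        bounds: tuple[int, int, int]) -> ROIBox:
    """Combine the three planar rectangles into a clipped 3D box."""
    planes = (rxy.plane, rxz.plane, ryz.plane)
    if planes != ("xy", "xz", "yz"):
        raise ValueError(f"expected rectangles on planes ('xy','xz','yz'), got {planes}")
    x = _union(rxy.first, rxz.first)
    y = _union(rxy.second, ryz.first)
    z = _union(rxz.second, ryz.second)
    ranges = []
    for rng, size in zip((x, y, z), bounds):
        lo = max(0, rng[0] - margin)
        hi = min(int(size), rng[1] + margin)
        if lo >= hi:
            raise GeometryError(f"ROI range {rng} with margin {margin} is empty "
                                f"after clipping to bounds {bounds}")
        ranges.append((lo, hi))
    return ROIBox(x=ranges[0], y=ranges[1], z=ranges[2], margin=margin)


def bounding_box(mask: np.ndarray, margin: int = 0,
                 bounds: tuple[int, int, int] | None = None) -> ROIBox | None:
    """Tight bounding box of a binary mask, or ``None`` for an empty mask."""
    mask = np.asarray(mask)
    idx = np.argwhere(mask > 0)
    if idx.size == 0:
        return None
    lo = idx.min(axis=0) - margin
    hi = idx.max(axis=0) + 1 + margin
    shape = bounds if bounds is not None else mask.shape
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, shape)
    return ROIBox(x=(int(lo[0]), int(hi[0])), y=(int(lo[1]), int(hi[1])),
                  z=(int(lo[2]), int(hi[2])), margin=margin)


def jitter_box(box: ROIBox, jitter: int, margin: int,
               bounds: tuple[int, int, int], rng: np.random.Generator) -> ROIBox:
    """Perturb each box face by a uniform integer in ``[-jitter, jitter]``.

    Emulates a rough manual box; the margin is applied after jittering and
    the result is clipped to the volume bounds, never allowed to go empty.
    """
    ranges = []
    for (lo, hi), size in zip((box.x, box.y, box.z), bounds):
        jl = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        jh = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        nlo = max(0, lo + jl - margin)
        nhi = min(int(size), hi + jh + margin)
        if nlo >= nhi:  # keep at least the original extent center
            nlo, nhi = max(0, lo), min(int(size), hi)
        ranges.append((nlo, nhi))
    return ROIBox(x=ranges[0], y=ranges[1], z=ranges[2], margin=margin)


def crop_to_roi(volume: np.ndarray, box: ROIBox) -> np.ndarray:
    """Extract the block ``[x.lo:x.hi, y.lo:y.hi, z.lo:z.hi]`` (copy)."""
    volume = np.asarray(volume)
    for rng, size in zip((box.x, box.y, box.z), volume.shape):
        if rng[0] < 0 or rng[1] > size:
            raise GeometryError(f"ROI {box} exceeds volume bounds {volume.shape}")
    return volume[box.slices()].copy()


def paste_into_full(block: np.ndarray, box: ROIBox,
                    shape: tuple[int, int, int], dtype=None) -> np.ndarray:
    """Place a block back at its box position in an otherwise-zero volume."""
    if tuple(block.shape) != box.shape:
        raise GeometryError(f"block shape {block.shape} != box extents {box.shape}")
    out = np.zeros(shape, dtype=dtype or block.dtype)
    out[box.slices()] = block
    return out


def segment_roi(dfn, phase1: np.ndarray, phase2: np.ndarray, box: ROIBox,
                input_size: tuple[int, int], threshold: float = 0.5) -> np.ndarray:
    """ROI-constrained dual-phase inference, pasted back into the full grid.

    Both phase blocks are cropped to ``box``; every axial slice is intensity
    -normalized and resampled to the network input size; the fusion network
    produces a score map per slice which is resampled back to block-slice
    scale (bilinear, before thresholding), binarized, stacked, and pasted
    into a full-grid mask that is zero outside the box.
    """
    from .preprocess import normalize_intensity, resample_slice, resize_bilinear
    from .nn.losses import binarize

    if phase1.shape != phase2.shape:
        raise ValueError(f"phase shapes differ: {phase1.shape} vs {phase2.shape}")
    if box.z[1] <= box.z[0]:
        raise GeometryError("ROI box contains no slices")
    b1 = crop_to_roi(phase1, box)
    b2 = crop_to_roi(phase2, box)
    bw, bh = b1.shape[0], b1.shape[1]
    n_slices = b1.shape[2]
    x1 = np.empty((n_slices, 1) + tuple(input_size), dtype=np.float32)
    x2 = np.empty_like(x1)
    for k in range(n_slices):
        x1[k, 0] = resample_slice(normalize_intensity(b1[:, :, k]), input_size)
        x2[k, 0] = resample_slice(normalize_intensity(b2[:, :, k]), input_size)
    _, _, p_out = dfn.forward(x1, x2, train=False)
    block_mask = np.empty((bw, bh, n_slices), dtype=np.uint8)
    for k in range(n_slices):
        score = resize_bilinear(p_out[k, 0], (bw, bh))
        block_mask[:, :, k] = binarize(score, threshold)
    return paste_into_full(block_mask, box, phase1.shape, dtype=np.uint8)


def save_roi(box: ROIBox, path: str | Path) -> None:
    payload = {"coordinate_convention": "0-based half-open",
               "x": list(box.x), "y": list(box.y), "z": list(box.z),
               "margin": box.margin}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_roi(path: str | Path) -> ROIBox:
    payload = json.loads(Path(path).read_text())
    if payload.get("coordinate_convention") != "0-based half-open":
        raise ValueError(f"ROI file {path}: unknown or missing coordinate convention")
    return ROIBox(x=tuple(payload["x"]), y=tuple(payload["y"]),
                  z=tuple(payload["z"]), margin=int(payload.get("margin", 0)))
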
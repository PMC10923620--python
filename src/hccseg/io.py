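"""Volume, mask, and manifest I/O with fixed conventions.

Conventions used throughout the package:

* voxel arrays are indexed ``(x, y, z)`` at the API boundary;
* voxel indices are 0-based and ranges are half-open ``[lo, hi)``;
* volumes are written as NIfTI (``.nii``/``.nii.gz``), masks as unsigned
  8-bit with values in ``{0, 1}``; manifests are JSON.

NIfTI stores data in ``(i, j, k)`` order which nibabel exposes directly as
``(x, y, z)`` for the identity-oriented affines this package writes, so no
axis shuffling happens on disk round trips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "DatasetManifest", "CaseRecord", "read_volume",
           "write_volume", "load_manifest", "save_manifest"]

MANIFEST_FORMAT = "hccseg-manifest-v1"


@dataclass
class Volume:
    """A 3D scalar grid with physical metadata, axis order ``(x, y, z)``."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"Volume requires 3D data, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("Volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI file; raises on missing files or non-3D data."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt / unparsable
        raise OSError(f"cannot parse NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D NIfTI, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(voxels=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def write_volume(v: Volume, path: str | Path, dtype_policy: str = "float32") -> None:
    """Write a volume as NIfTI under a declared dtype policy.

    ``float32`` casts losslessly for float data; ``uint8`` is reserved for
    binary masks and validates that all values lie in ``{0, 1}``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dtype_policy == "uint8":
        vals = np.unique(v.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(
                f"uint8 policy requires a binary mask; found values {vals[:10]}")
        data = v.voxels.astype(np.uint8)
    elif dtype_policy == "float32":
        data = v.voxels.astype(np.float32)
    else:
        raise ValueError(f"unknown dtype policy {dtype_policy!r}")
    affine = np.diag(list(v.spacing) + [1.0])
    affine[:3, 3] = v.origin
    nib.save(nib.Nifti1Image(data, affine), str(path))


@dataclass
class CaseRecord:
    """Paths and provenance for one patient/phantom case."""

    case_id: str
    phase1_path: str
    phase2_path: str
    mask_path: str
    roi_path: str | None = None
    seed: int | None = None


@dataclass
class DatasetManifest:
    """The case table of a dataset; ids must be unique."""

    cases: list[CaseRecord] = field(default_factory=list)
    format_version: str = MANIFEST_FORMAT
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [c.case_id for c in self.cases]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate case ids in manifest: {dupes}")

    def case_ids(self) -> list[str]:
        return [c.case_id for c in self.cases]


def save_manifest(m: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "format_version": m.format_version,
        "meta": m.meta,
        "cases": [vars(c) for c in m.cases],
    }
    path.write_text(json.dumps(payload, indent=2))


def load_manifest(path: str | Path, check_paths: bool = True) -> DatasetManifest:
    """Load and validate a JSON manifest; optionally verify paths resolve."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"manifest {path} is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "cases" not in payload:
        raise ValueError(f"manifest {path} lacks a 'cases' list")
    required = {"case_id", "phase1_path", "phase2_path", "mask_path"}
    cases = []
    for rec in payload["cases"]:
        missing = required - set(rec)
        if missing:
            raise ValueError(f"manifest record missing fields {sorted(missing)}: {rec}")
        cases.append(CaseRecord(**rec))
    m = DatasetManifest(cases=cases,
                        format_version=payload.get("format_version", MANIFEST_FORMAT),
                        meta=payload.get("meta", {}))
    if check_paths:
        base = path.parent
        for c in m.cases:
            for p in (c.phase1_path, c.phase2_path, c.mask_path):
                candidate = Path(p)
                if not candidate.is_absolute():
                    candidate = base / candidate
                if not candidate.exists():
                    raise FileNotFoundError(
                        f"manifest {path}: case {c.case_id} references missing file {p}")
    return m
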
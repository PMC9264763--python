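"""In-memory containers for DWI data and standard-format I/O.

Volumes are stored as numpy arrays of shape ``(nx, ny, nz, n)`` and written
as uncompressed 4D NIfTI with an FSL-style ``.bval`` text sidecar (one
b-value per acquisition volume, whitespace-separated on a single line).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DwiSeries",
    "ShellAveragedDwi",
    "save_mask",
    "load_mask",
]


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class DwiSeries:
    """4D magnitude DWI series: one 3D volume per acquisition.

    Parameters
    ----------
    data
        Signal array of shape ``(nx, ny, nz, n_acquisitions)``.
    bvals
        One b-value (s/mm^2) per acquisition volume.
    voxel_size_mm
        Voxel edge lengths in mm.
    """

    data: np.ndarray
    bvals: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 5.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, acquisition)")
        if self.data.shape[3] != self.bvals.size:
            raise ValueError(
                f"acquisition count {self.data.shape[3]} does not match "
                f"b-value label count {self.bvals.size}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DWI signal contains non-finite values")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_acquisitions(self) -> int:
        return self.data.shape[3]

    def save(self, prefix: str | Path) -> list[Path]:
        """Write ``<prefix>.nii`` and ``<prefix>.bval``; return written paths."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        nii = prefix.with_suffix(".nii")
        img = nib.Nifti1Image(self.data, _affine(self.voxel_size_mm))
        nib.save(img, nii)
        bval = prefix.with_suffix(".bval")
        bval.write_text(" ".join(f"{b:g}" for b in self.bvals) + "\n")
        return [nii, bval]

    @classmethod
    def load(cls, prefix: str | Path) -> "DwiSeries":
        prefix = Path(prefix)
        img = nib.load(prefix.with_suffix(".nii"))
        bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel()
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float), bvals, vox)


@dataclass
class ShellAveragedDwi:
    """Direction-averaged DWI: one 3D volume per distinct b-value shell.

    ``norm_factor`` records the value every volume was divided by during
    normalization (``None`` before normalization).
    """

    data: np.ndarray
    bvals: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 5.0)
    norm_factor: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        if self.data.ndim != 4:
            raise ValueError("shell-averaged data must be 4D (x, y, z, shell)")
        if self.data.shape[3] != self.bvals.size:
            raise ValueError("shell count does not match b-value count")
        if np.unique(self.bvals).size != self.bvals.size:
            raise ValueError("shell b-values must be distinct")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_shells(self) -> int:
        return self.data.shape[3]

    def b0_volume(self) -> np.ndarray:
        idx = np.nonzero(self.bvals == 0.0)[0]
        if idx.size == 0:
            raise ValueError("no b = 0 shell present")
        return self.data[..., idx[0]]

    def save(self, prefix: str | Path) -> list[Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        nii = prefix.with_suffix(".nii")
        nib.save(nib.Nifti1Image(self.data, _affine(self.voxel_size_mm)), nii)
        bval = prefix.with_suffix(".bval")
        bval.write_text(" ".join(f"{b:g}" for b in self.bvals) + "\n")
        meta = prefix.with_suffix(".json")
        meta.write_text(json.dumps({"norm_factor": self.norm_factor}) + "\n")
        return [nii, bval, meta]

    @classmethod
    def load(cls, prefix: str | Path) -> "ShellAveragedDwi":
        prefix = Path(prefix)
        img = nib.load(prefix.with_suffix(".nii"))
        bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel()
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        meta_path = prefix.with_suffix(".json")
        norm = None
        if meta_path.exists():
            norm = json.loads(meta_path.read_text()).get("norm_factor")
        return cls(np.asarray(img.dataobj, dtype=float), bvals, vox, norm)


def save_mask(mask: np.ndarray, path: str | Path,
              voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 5.0)) -> Path:
    """Write a boolean mask as uint8 NIfTI (bit-exact round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size_mm))
    nib.save(img, path)
    return path


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj) > 0
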
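"""Voxel-volume containers and NIfTI + JSON-sidecar I/O.

Two thin containers are shared across the package:

* :class:`VoxelVolume` — a 3-D grid of CT numbers (HU) with spacing,
  origin and the tube label it was acquired with.
* :class:`SprVolume` — a 3-D grid of stopping-power ratios with a
  provenance label ("DECT", "SECT" or "truth").

World coordinates: the center of voxel index (i, j, k) is at
``origin + index * spacing`` (mm).  Volumes are written as .nii.gz with
a small JSON sidecar holding acquisition metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VoxelVolume", "SprVolume", "save_volume", "load_volume", "save_spr", "load_spr"]


def _check_grid(data: np.ndarray, spacing) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D grid, got shape {data.shape}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"invalid spacing {spacing}")


@dataclass
class VoxelVolume:
    """A 3-D CT-number (HU) grid with geometry and tube label."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tube: str = "120kV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        _check_grid(self.data, self.spacing)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def same_grid(self, other: "VoxelVolume | SprVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class SprVolume:
    """A 3-D stopping-power-ratio grid with provenance label."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = "truth"  # "DECT" | "SECT" | "truth"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        _check_grid(self.data, self.spacing)
        if np.any(self.data < 0):
            raise ValueError("SPR values must be >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def same_grid(self, other: "VoxelVolume | SprVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def _write_nifti(data, spacing, origin, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(spacing, origin))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def _read_nifti(path: Path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return data, spacing, origin


def save_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write a CT volume as .nii.gz plus a ``.json`` sidecar; returns the image path."""
    path = Path(path)
    _write_nifti(vol.data, vol.spacing, vol.origin, path)
    sidecar = {"tube": vol.tube, **vol.meta}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_volume(path: str | Path) -> VoxelVolume:
    path = Path(path)
    data, spacing, origin = _read_nifti(path)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    tube = meta.pop("tube", "120kV")
    return VoxelVolume(data=data, spacing=spacing, origin=origin, tube=tube, meta=meta)


def save_spr(vol: SprVolume, path: str | Path) -> Path:
    path = Path(path)
    _write_nifti(vol.data, vol.spacing, vol.origin, path)
    sidecar = {"provenance": vol.provenance, **vol.meta}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_spr(path: str | Path) -> SprVolume:
    path = Path(path)
    data, spacing, origin = _read_nifti(path)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    prov = meta.pop("provenance", "truth")
    # stored float32; tiny negative round-off is clipped on load
    return SprVolume(data=np.clip(data, 0.0, None), spacing=spacing, origin=origin,
                     provenance=prov, meta=meta)


def save_mask(mask: np.ndarray, spacing, origin, path: str | Path) -> Path:
    """Write a boolean mask as a uint8 NIfTI label map."""
    path = Path(path)
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing, origin))
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> np.ndarray:
    data, _, _ = _read_nifti(Path(path))
    return data > 0.5
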
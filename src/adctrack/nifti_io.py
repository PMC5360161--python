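"""Thin NIfTI helpers: volumes live on an RAS+ grid built from voxel spacing."""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np


def spacing_affine(voxel_spacing: tuple[float, float, float]) -> np.ndarray:
    """RAS+ affine with the given voxel spacing and origin at zero."""
    sx, sy, sz = voxel_spacing
    return np.diag([float(sx), float(sy), float(sz), 1.0])


def save_volume(
    data: np.ndarray,
    voxel_spacing: tuple[float, float, float],
    path: str | os.PathLike,
    dtype=np.float32,
) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), spacing_affine(voxel_spacing))
    img.header.set_zooms([float(s) for s in voxel_spacing])
    nib.save(img, os.fspath(path))


def save_mask(
    mask: np.ndarray,
    voxel_spacing: tuple[float, float, float],
    path: str | os.PathLike,
) -> None:
    """Binary masks are written as uint8 0/1."""
    save_volume(np.asarray(mask, dtype=bool), voxel_spacing, path, dtype=np.uint8)


def load_volume(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Return (array, voxel spacing in mm)."""
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    return data, (float(zooms[0]), float(zooms[1]), float(zooms[2]))


def load_mask(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    data, spacing = load_volume(path)
    return data > 0.5, spacing
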
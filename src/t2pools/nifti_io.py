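"""Thin NIfTI-1 helpers shared by the CLI stages."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["load_volume", "save_volume", "voxel_size_of", "save_maps"]


def load_volume(path: str | Path) -> tuple[np.ndarray, nib.Nifti1Image]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img


def voxel_size_of(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def save_volume(
    data: np.ndarray,
    path: str | Path,
    like: nib.Nifti1Image | None = None,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    if like is not None:
        affine = like.affine
    else:
        affine = np.diag(list(voxel_size) + [1.0])
    out = np.asarray(data)
    if out.dtype == bool:
        out = out.astype(np.uint8)
    nib.save(nib.Nifti1Image(out, affine), str(path))


def save_maps(
    maps: dict[str, np.ndarray],
    out_dir: str | Path,
    like: nib.Nifti1Image | None = None,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> dict[str, Path]:
    """Write one 3-D .nii.gz per named metric; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, data in maps.items():
        p = out_dir / f"{name}.nii.gz"
        save_volume(data, p, like=like, voxel_size=voxel_size)
        written[name] = p
    return written
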
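"""Lesion-aware mask construction.

Builds, from a tissue-label volume and a lesion-probability volume:
the binary lesion mask (probability strictly above threshold), its split
into T1-iso (inside the WM label) and T1-hypo (outside it) sub-volumes,
and the non-lesional WM mask (WM minus lesions, eroded to suppress
partial-volume voxels at region boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskSet",
    "LesionReport",
    "threshold_lesion_probability",
    "split_lesion_by_t1",
    "make_nonlesional_wm",
    "build_mask_set",
    "lesion_report",
]


@dataclass
class MaskSet:
    wm: np.ndarray
    lesion: np.ndarray
    lesion_t1_iso: np.ndarray
    lesion_t1_hypo: np.ndarray
    nonlesional_wm: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {
            a.shape
            for a in (
                self.wm,
                self.lesion,
                self.lesion_t1_iso,
                self.lesion_t1_hypo,
                self.nonlesional_wm,
            )
        }
        if len(shapes) != 1:
            raise ValueError("all mask volumes must share one shape")
        if np.any(self.lesion_t1_iso & self.lesion_t1_hypo):
            raise ValueError("T1 iso/hypo sub-masks must be disjoint")
        if not np.array_equal(self.lesion_t1_iso | self.lesion_t1_hypo, self.lesion):
            raise ValueError("T1 sub-masks must partition the lesion mask")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass(frozen=True)
class LesionReport:
    total_volume_mm3: float
    t1_iso_volume_mm3: float
    t1_hypo_volume_mm3: float
    t1_iso_percent: float  # NaN when total volume is zero
    t1_hypo_percent: float


def threshold_lesion_probability(prob_volume: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary lesion mask: probability strictly greater than ``threshold``.

    Ties at exactly the threshold are excluded (documented convention).
    """
    prob = np.asarray(prob_volume, dtype=float)
    if np.any(prob < 0) or np.any(prob > 1):
        raise ValueError("lesion probabilities must lie in [0, 1]")
    return prob > threshold


def split_lesion_by_t1(
    lesion: np.ndarray, tissue_labels: np.ndarray, wm_label: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Partition lesion voxels into T1-iso (WM label) and T1-hypo (non-WM)."""
    lesion = np.asarray(lesion, dtype=bool)
    tissue_labels = np.asarray(tissue_labels)
    if lesion.shape != tissue_labels.shape:
        raise ValueError("lesion and tissue-label shapes must match")
    iso = lesion & (tissue_labels == wm_label)
    hypo = lesion & (tissue_labels != wm_label)
    return iso, hypo


def _structuring_element(mode: str) -> np.ndarray:
    """Erosion element: 2-D slice-wise 3x3 square by default (voxels are
    strongly anisotropic through-plane), or 3-D 6-connected cross."""
    if mode == "2d":
        elem = np.zeros((3, 3, 3), dtype=bool)
        elem[:, :, 1] = True  # full 3x3 in-plane, no through-plane coupling
        return elem
    if mode == "3d":
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"unknown erosion mode {mode!r}; use '2d' or '3d'")


def make_nonlesional_wm(
    wm: np.ndarray,
    lesion: np.ndarray,
    erosion_px: int = 1,
    mode: str = "2d",
) -> np.ndarray:
    """Non-lesional WM: (wm AND NOT lesion), eroded ``erosion_px`` times."""
    wm = np.asarray(wm, dtype=bool)
    lesion = np.asarray(lesion, dtype=bool)
    if wm.shape != lesion.shape:
        raise ValueError("wm and lesion shapes must match")
    if erosion_px < 0:
        raise ValueError("erosion_px must be >= 0")
    out = wm & ~lesion
    if erosion_px == 0 or not out.any():
        return out
    elem = _structuring_element(mode)
    if out.ndim == 2:
        elem = elem[:, :, 1] if mode == "2d" else ndimage.generate_binary_structure(2, 1)
    return ndimage.binary_erosion(out, structure=elem, iterations=erosion_px, border_value=0)


def build_mask_set(
    tissue_labels: np.ndarray,
    lesion_prob: np.ndarray,
    voxel_size: tuple[float, float, float],
    wm_label: int = 1,
    threshold: float = 0.5,
    erosion_px: int = 1,
    erosion_mode: str = "2d",
) -> MaskSet:
    """Full mask pipeline from label and probability volumes."""
    lesion = threshold_lesion_probability(lesion_prob, threshold)
    wm = np.asarray(tissue_labels) == wm_label
    iso, hypo = split_lesion_by_t1(lesion, tissue_labels, wm_label)
    nl_wm = make_nonlesional_wm(wm, lesion, erosion_px, erosion_mode)
    return MaskSet(
        wm=wm,
        lesion=lesion,
        lesion_t1_iso=iso,
        lesion_t1_hypo=hypo,
        nonlesional_wm=nl_wm,
        voxel_size=voxel_size,
    )


def lesion_report(masks: MaskSet) -> LesionReport:
    """Lesion volumes in mm^3 and T1-iso/hypo percentage shares."""
    vv = masks.voxel_volume_mm3
    total = float(masks.lesion.sum()) * vv
    iso = float(masks.lesion_t1_iso.sum()) * vv
    hypo = float(masks.lesion_t1_hypo.sum()) * vv
    if total > 0:
        iso_pct = 100.0 * iso / total
        hypo_pct = 100.0 * hypo / total
    else:
        iso_pct = hypo_pct = float("nan")
    return LesionReport(
        total_volume_mm3=total,
        t1_iso_volume_mm3=iso,
        t1_hypo_volume_mm3=hypo,
        t1_iso_percent=iso_pct,
        t1_hypo_percent=hypo_pct,
    )
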
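"""Reduction of T2 spectra to three-pool water maps.

Spectral mass with T2 below the myelin boundary (default 40 ms) is myelin
water (Mw), mass between the two boundaries intra/extracellular water (IEw),
and mass above the free-water boundary (default 250 ms) CSF-like free water
(Fw). Fractions are normalized to unit total water per voxel. The IEw
compartment additionally gets an amplitude-weighted geometric-mean T2 map;
the Mw and Fw T2 times are deliberately not estimated because they fall at
the edges of the sampled echo range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrum_fit import T2Spectrum, VolumeFitResult

__all__ = [
    "CompartmentBoundaries",
    "CompartmentMaps",
    "compartmentalize",
    "snr_of_fit",
    "assemble_maps",
]


@dataclass(frozen=True)
class CompartmentBoundaries:
    """Window edges in ms. Mw: [grid min, mw_upper); IEw: [mw_upper,
    fw_lower]; Fw: (fw_lower, grid max]."""

    mw_upper: float = 40.0
    fw_lower: float = 250.0

    def __post_init__(self) -> None:
        if not 0 < self.mw_upper < self.fw_lower:
            raise ValueError("require 0 < mw_upper < fw_lower")


@dataclass
class CompartmentMaps:
    """Per-voxel quantitative maps; NaN where undefined, background flagged."""

    mw_frac: np.ndarray
    iew_frac: np.ndarray
    fw_frac: np.ndarray
    t2_iew: np.ndarray
    snr: np.ndarray
    flip_deg: np.ndarray
    background: np.ndarray
    boundaries: CompartmentBoundaries

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "mw": self.mw_frac,
            "iew": self.iew_frac,
            "fw": self.fw_frac,
            "t2_iew": self.t2_iew,
            "snr": self.snr,
            "flip": self.flip_deg,
        }


def _window_masks(
    grid_values: np.ndarray, boundaries: CompartmentBoundaries
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mw = grid_values < boundaries.mw_upper
    iew = (grid_values >= boundaries.mw_upper) & (grid_values <= boundaries.fw_lower)
    fw = grid_values > boundaries.fw_lower
    return mw, iew, fw


def compartmentalize(
    spectrum: T2Spectrum, boundaries: CompartmentBoundaries = CompartmentBoundaries()
) -> tuple[float, float, float, float]:
    """Split a spectrum into (mw, iew, fw) fractions and the IEw mean T2.

    Fractions are window masses over total mass; ``t2_iew`` is the
    amplitude-weighted geometric mean of grid T2 inside the IEw window.
    A zero-mass spectrum returns all NaN (background); an empty IEw window
    returns NaN for ``t2_iew`` only.
    """
    amps = spectrum.amplitudes
    total = amps.sum()
    if total <= 0:
        return float("nan"), float("nan"), float("nan"), float("nan")
    mw_m, iew_m, fw_m = _window_masks(spectrum.grid.values, boundaries)
    mw = float(amps[mw_m].sum() / total)
    iew = float(amps[iew_m].sum() / total)
    fw = float(amps[fw_m].sum() / total)
    iew_mass = amps[iew_m].sum()
    if iew_mass > 0:
        t2_iew = float(
            np.exp((amps[iew_m] * np.log(spectrum.grid.values[iew_m])).sum() / iew_mass)
        )
    else:
        t2_iew = float("nan")
    return mw, iew, fw, t2_iew


def snr_of_fit(
    spectrum: T2Spectrum, residuals: np.ndarray, ceiling: float = 1e6
) -> float:
    """Sum of spectral amplitudes over the sample std of the fit residuals.

    A perfect fit (zero residual spread) is capped at ``ceiling``; a zero
    spectrum yields 0.
    """
    residuals = np.asarray(residuals, dtype=float)
    total = spectrum.total
    if total == 0:
        return 0.0
    std = float(np.std(residuals, ddof=1)) if residuals.size > 1 else 0.0
    if std == 0:
        return ceiling
    return min(total / std, ceiling)


def assemble_maps(
    fit: VolumeFitResult,
    boundaries: CompartmentBoundaries = CompartmentBoundaries(),
) -> CompartmentMaps:
    """Vectorized per-voxel compartmentalization of a fitted volume."""
    spectra = fit.spectra  # spatial + (n_grid,)
    grid_values = fit.grid.values
    mw_m, iew_m, fw_m = _window_masks(grid_values, boundaries)

    total = spectra.sum(axis=-1)
    background = fit.background | (total <= 0)
    safe_total = np.where(total > 0, total, 1.0)

    mw = spectra[..., mw_m].sum(axis=-1) / safe_total
    iew_mass = spectra[..., iew_m].sum(axis=-1)
    iew = iew_mass / safe_total
    fw = spectra[..., fw_m].sum(axis=-1) / safe_total
    with np.errstate(invalid="ignore", divide="ignore"):
        log_num = (spectra[..., iew_m] * np.log(grid_values[iew_m])).sum(axis=-1)
        t2_iew = np.where(iew_mass > 0, np.exp(log_num / np.where(iew_mass > 0, iew_mass, 1.0)), np.nan)

    for arr in (mw, iew, fw, t2_iew):
        arr[background] = np.nan

    return CompartmentMaps(
        mw_frac=mw,
        iew_frac=iew,
        fw_frac=fw,
        t2_iew=t2_iew,
        snr=fit.snr.copy(),
        flip_deg=fit.flip_deg.copy(),
        background=background,
        boundaries=boundaries,
    )
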
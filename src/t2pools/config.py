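"""YAML-backed configuration.

One flat document groups the sequence geometry, the T2 grid, the fitting
choices, the compartment boundaries and the masking options; every value
has a default, so an empty (or absent) config is valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .compartment_maps import CompartmentBoundaries
from .sequence_model import SequenceParams, T2Grid
from .spectrum_fit import FitConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    params: SequenceParams = field(default_factory=SequenceParams)
    grid: T2Grid = field(default_factory=T2Grid.logspaced)
    fit: FitConfig = field(default_factory=FitConfig)
    boundaries: CompartmentBoundaries = field(default_factory=CompartmentBoundaries)
    wm_label: int = 1
    lesion_threshold: float = 0.5
    erosion_px: int = 1
    erosion_mode: str = "2d"


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (or defaults).

    Recognized blocks::

        sequence: {n_echoes, echo_spacing_ms, t1_assumed_ms, refocus_deg}
        grid: {t2_min_ms, t2_max_ms, n}
        fit: {chi2_window, alpha_range, alpha_coarse_n, alpha_tol_deg, snr_ceiling}
        boundaries: {mw_upper_ms, fw_lower_ms}
        masks: {wm_label, lesion_threshold, erosion_px, erosion_mode}
    """
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}

    seq = doc.get("sequence", {})
    params = SequenceParams(
        n_echoes=seq.get("n_echoes", 32),
        echo_spacing=seq.get("echo_spacing_ms", 10.0),
        t1_assumed=seq.get("t1_assumed_ms", 1000.0),
        refocus_deg=seq.get("refocus_deg", 180.0),
    )
    g = doc.get("grid", {})
    grid = T2Grid.logspaced(
        t2_min=g.get("t2_min_ms", 8.0), t2_max=g.get("t2_max_ms", 2000.0), n=g.get("n", 40)
    )
    f = doc.get("fit", {})
    fit = FitConfig(
        chi2_window=tuple(f.get("chi2_window", (1.02, 1.025))),
        alpha_range=tuple(f.get("alpha_range", (90.0, 180.0))),
        alpha_coarse_n=f.get("alpha_coarse_n", 8),
        alpha_tol_deg=f.get("alpha_tol_deg", 0.5),
        snr_ceiling=f.get("snr_ceiling", 1e6),
    )
    b = doc.get("boundaries", {})
    boundaries = CompartmentBoundaries(
        mw_upper=b.get("mw_upper_ms", 40.0), fw_lower=b.get("fw_lower_ms", 250.0)
    )
    m = doc.get("masks", {})
    return PipelineConfig(
        params=params,
        grid=grid,
        fit=fit,
        boundaries=boundaries,
        wm_label=m.get("wm_label", 1),
        lesion_threshold=m.get("lesion_threshold", 0.5),
        erosion_px=m.get("erosion_px", 1),
        erosion_mode=m.get("erosion_mode", "2d"),
    )
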
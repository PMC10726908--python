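"""Synthetic phantoms and cohorts.

Every pipeline stage is testable offline: this module generates multi-echo
phantom volumes (three-pool exponential mixtures under a spatially smooth
refocusing-angle field, with magnitude noise), the matching tissue-label and
lesion-probability volumes with known truth maps, and clinical cohorts whose
free-water summaries carry configurable monotone associations with EDSS,
age, and disease duration.

Cohort generative model (Gaussian copula on standard-normal latents):

* ``z_age`` drives age (uniform over the configured range via the probit
  transform) and, attenuated, disease duration;
* a disability latent ``d = rho_age_disability * z_age + sqrt(1-rho^2) * u``
  is thresholded to the ordinal 0.5-step EDSS scale;
* the free-water latent is ``beta_age * z_age + beta_disability * d + noise``
  (unit total variance), mapped affinely to the median-Fw scale;
* lesion volume is log-normal with a disability loading, split into T1-iso
  and T1-hypo shares around the configured hypo fraction.

With the default loadings the population rank correlation between median Fw
and EDSS is ~0.45 and the product-moment correlation with age ~0.6 (see
``CohortSpec.target_spearman_fw_edss``, frozen from a 2e6-subject run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .sequence_model import SequenceParams, epg_echo_amplitudes_paired

__all__ = [
    "PoolTruth",
    "RegionTruth",
    "LesionSpec",
    "PhantomSpec",
    "Phantom",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "generate_subject_phantom",
]

# Tissue label codes used throughout the synthetic volumes.
LABEL_BACKGROUND = 0
LABEL_WM = 1
LABEL_CSF = 2
LABEL_T1_HYPO = 3  # lesion tissue not labeled WM on T1


@dataclass(frozen=True)
class PoolTruth:
    """One water pool: fractional weight and its T2 (ms)."""

    fraction: float
    t2: float


@dataclass(frozen=True)
class RegionTruth:
    """Three-pool composition of a region; fractions must sum to 1."""

    mw: PoolTruth
    iew: PoolTruth
    fw: PoolTruth

    def __post_init__(self) -> None:
        total = self.mw.fraction + self.iew.fraction + self.fw.fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool fractions must sum to 1, got {total}")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.mw.fraction, self.iew.fraction, self.fw.fraction])

    @property
    def t2s(self) -> np.ndarray:
        return np.array([self.mw.t2, self.iew.t2, self.fw.t2])


WM_TRUTH = RegionTruth(PoolTruth(0.10, 20.0), PoolTruth(0.85, 80.0), PoolTruth(0.05, 1000.0))
CSF_TRUTH = RegionTruth(PoolTruth(0.0, 20.0), PoolTruth(0.02, 80.0), PoolTruth(0.98, 1500.0))
LESION_ISO_TRUTH = RegionTruth(PoolTruth(0.06, 20.0), PoolTruth(0.76, 90.0), PoolTruth(0.18, 1000.0))
LESION_HYPO_TRUTH = RegionTruth(PoolTruth(0.02, 20.0), PoolTruth(0.63, 100.0), PoolTruth(0.35, 1000.0))


@dataclass(frozen=True)
class LesionSpec:
    """Spherical lesion: center (voxels), nominal radius (voxels), T1 class."""

    center: tuple[float, float, float]
    radius: float
    t1_hypo: bool = False


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size: tuple[float, float, float] = (1.64, 1.64, 2.5)
    wm_margin: int = 2  # WM slab inset from the volume edge
    csf_center: tuple[float, float, float] | None = None  # default: volume center
    csf_radius: float = 4.0
    lesions: tuple[LesionSpec, ...] = (
        LesionSpec((9.0, 9.0, 3.5), 2.2, t1_hypo=False),
        LesionSpec((22.0, 21.0, 4.0), 2.6, t1_hypo=True),
    )
    wm_truth: RegionTruth = WM_TRUTH
    csf_truth: RegionTruth = CSF_TRUTH
    lesion_iso_truth: RegionTruth = LESION_ISO_TRUTH
    lesion_hypo_truth: RegionTruth = LESION_HYPO_TRUTH
    flip_range: tuple[float, float] = (150.0, 180.0)
    snr: float = 200.0  # first-echo WM signal over noise sigma; inf = noiseless
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0
    params: SequenceParams = field(default_factory=SequenceParams)

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        lo, hi = self.flip_range
        if not 0 < lo <= hi <= 180:
            raise ValueError("flip_range must satisfy 0 < low <= high <= 180")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class Phantom:
    """A generated phantom plus its exact synthesis truth."""

    echoes: np.ndarray  # (x, y, z, n_echoes)
    tissue_labels: np.ndarray  # int codes
    lesion_prob: np.ndarray  # [0, 1]
    truth_mw: np.ndarray
    truth_iew: np.ndarray
    truth_fw: np.ndarray
    truth_flip: np.ndarray
    lesion_mask: np.ndarray
    lesion_hypo_mask: np.ndarray
    spec: PhantomSpec


def _flip_field(shape: tuple[int, int, int], flip_range: tuple[float, float]) -> np.ndarray:
    """Smooth in [lo, hi]: a separable sinusoidal modulation."""
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    s = 0.5 + 0.5 * np.sin(2 * np.pi * x / nx) * np.cos(2 * np.pi * y / ny)
    s = 0.7 * s + 0.3 * (z + 0.5) / nz
    lo, hi = flip_range
    return lo + (hi - lo) * s


def _sphere_dist2(shape, center, voxel_aspect=(1.0, 1.0, 1.0)) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    return sum(((g - c) * a) ** 2 for g, c, a in zip(grids, center, voxel_aspect))


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Synthesize one phantom volume from its spec; reproducible from seed.

    Geometry: a WM slab inset from the edges, a central CSF blob, and
    spherical lesions (all inside the WM slab). The lesion-probability
    volume is a smooth Gaussian bump per lesion peaking at 0.9; the actual
    lesion extent is its supra-0.5 region, so thresholding is exercised
    nontrivially while the truth maps stay exactly consistent with the
    synthesized signal.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    m = spec.wm_margin

    wm_slab = np.zeros(shape, dtype=bool)
    wm_slab[m:-m or None, m:-m or None, :] = True

    csf_center = spec.csf_center or tuple((n - 1) / 2.0 for n in shape)
    csf = _sphere_dist2(shape, csf_center) <= spec.csf_radius**2
    wm = wm_slab & ~csf

    # Smooth lesion-probability field; lesion truth = probability > 0.5.
    prob = np.zeros(shape)
    hypo_prob = np.zeros(shape)
    for les in spec.lesions:
        d2 = _sphere_dist2(shape, les.center)
        bump = 0.9 * np.exp(-d2 / (2.0 * les.radius**2))
        prob = np.maximum(prob, bump)
        if les.t1_hypo:
            hypo_prob = np.maximum(hypo_prob, bump)
    lesion = (prob > 0.5) & wm
    prob = np.where(wm, prob, np.minimum(prob, 0.5))  # lesions only inside WM
    lesion_hypo = (hypo_prob > 0.5) & lesion
    lesion_iso = lesion & ~lesion_hypo

    labels = np.full(shape, LABEL_BACKGROUND, dtype=np.int16)
    labels[wm] = LABEL_WM
    labels[csf] = LABEL_CSF
    labels[lesion_hypo] = LABEL_T1_HYPO  # T1 hypo-intense tissue is not WM

    flip = _flip_field(shape, spec.flip_range)

    region_truth = [
        (wm & ~lesion, spec.wm_truth),
        (csf, spec.csf_truth),
        (lesion_iso, spec.lesion_iso_truth),
        (lesion_hypo, spec.lesion_hypo_truth),
    ]

    n_echoes = spec.params.n_echoes
    echoes = np.zeros(shape + (n_echoes,))
    truth_mw = np.zeros(shape)
    truth_iew = np.zeros(shape)
    truth_fw = np.zeros(shape)
    for mask, truth in region_truth:
        if not mask.any():
            continue
        alphas = flip[mask]
        sig = np.zeros((n_echoes, alphas.size))
        for frac, t2 in zip(truth.fractions, truth.t2s):
            if frac == 0:
                continue
            sig += frac * epg_echo_amplitudes_paired(
                np.full(alphas.size, t2), alphas, spec.params
            )
        echoes[mask] = sig.T
        truth_mw[mask] = truth.mw.fraction
        truth_iew[mask] = truth.iew.fraction
        truth_fw[mask] = truth.fw.fraction

    if np.isfinite(spec.snr):
        wm_only = wm & ~lesion
        first_echo_wm = float(echoes[wm_only, 0].mean()) if wm_only.any() else 1.0
        sigma = first_echo_wm / spec.snr
        if spec.noise_model == "gaussian":
            echoes = np.abs(echoes + rng.normal(0.0, sigma, echoes.shape))
        else:  # rician: modulus of a complex Gaussian around the signal
            re = echoes + rng.normal(0.0, sigma, echoes.shape)
            im = rng.normal(0.0, sigma, echoes.shape)
            echoes = np.hypot(re, im)

    flip_out = np.where(labels != LABEL_BACKGROUND, flip, np.nan)
    nan_bg = labels == LABEL_BACKGROUND
    for arr in (truth_mw, truth_iew, truth_fw):
        arr[nan_bg] = np.nan

    return Phantom(
        echoes=echoes,
        tissue_labels=labels,
        lesion_prob=prob,
        truth_mw=truth_mw,
        truth_iew=truth_iew,
        truth_fw=truth_fw,
        truth_flip=flip_out,
        lesion_mask=lesion,
        lesion_hypo_mask=lesion_hypo,
        spec=spec,
    )


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 20
    age_range: tuple[float, float] = (20.0, 62.0)
    duration_range: tuple[float, float] = (2.0, 30.0)
    edss_range: tuple[float, float] = (1.0, 4.0)
    rho_age_duration: float = 0.6
    rho_age_disability: float = 0.3
    beta_age: float = 0.50  # Fw-latent loading on the age latent
    beta_disability: float = 0.32  # Fw-latent loading on the disability latent
    fw_baseline: float = 0.045
    fw_scale: float = 0.015
    lesion_log_mean: float = 8.0  # log mm^3
    lesion_log_sigma: float = 0.5
    lesion_disability_loading: float = 0.5
    hypo_share_mean: float = 0.52  # T1-hypo share of total lesion volume
    hypo_share_kappa: float = 40.0  # beta-distribution concentration
    seed: int = 0
    #: Population Spearman(median Fw, EDSS) implied by the default loadings,
    #: measured once on 1e6 simulated subjects and frozen here.
    target_spearman_fw_edss: float = 0.447

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        for name in ("rho_age_duration", "rho_age_disability"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise ValueError(f"{name} must lie in (-1, 1)")
        resid = (
            1.0
            - self.beta_age**2
            - self.beta_disability**2
            - 2.0 * self.rho_age_disability * self.beta_age * self.beta_disability
        )
        if resid < 0:
            raise ValueError(
                "infeasible effect sizes: beta_age/beta_disability imply a "
                "latent variance above 1; reduce the loadings"
            )


def _edss_from_latent(d: np.ndarray, edss_range: tuple[float, float]) -> np.ndarray:
    lo, hi = edss_range
    cont = lo + (hi - lo) * _sps.norm.cdf(d)
    return np.clip(np.round(cont * 2.0) / 2.0, lo, hi)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Fast-path cohort: clinical covariates plus per-subject WM summaries.

    Returns one row per subject with the columns the correlation battery
    expects (subject_id, edss, duration_years, age_years, lesion volumes,
    median/mean of the four WM metrics). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    z_age = rng.standard_normal(n)
    u_dis = rng.standard_normal(n)
    eps_fw = rng.standard_normal(n)
    eps_dur = rng.standard_normal(n)

    a_lo, a_hi = spec.age_range
    age = a_lo + (a_hi - a_lo) * _sps.norm.cdf(z_age)

    rad = spec.rho_age_duration
    z_dur = rad * z_age + np.sqrt(1.0 - rad**2) * eps_dur
    d_lo, d_hi = spec.duration_range
    duration = d_lo + (d_hi - d_lo) * _sps.norm.cdf(z_dur)

    rho = spec.rho_age_disability
    d_lat = rho * z_age + np.sqrt(1.0 - rho**2) * u_dis
    edss = _edss_from_latent(d_lat, spec.edss_range)

    resid_var = (
        1.0
        - spec.beta_age**2
        - spec.beta_disability**2
        - 2.0 * rho * spec.beta_age * spec.beta_disability
    )
    fw_lat = (
        spec.beta_age * z_age
        + spec.beta_disability * d_lat
        + np.sqrt(max(resid_var, 0.0)) * eps_fw
    )
    median_fw = np.clip(spec.fw_baseline + spec.fw_scale * fw_lat, 1e-4, 0.5)

    log_vol = (
        spec.lesion_log_mean
        + spec.lesion_disability_loading * d_lat
        + spec.lesion_log_sigma * rng.standard_normal(n)
    )
    lesion_total = np.exp(log_vol)
    kappa = spec.hypo_share_kappa
    share = rng.beta(spec.hypo_share_mean * kappa, (1.0 - spec.hypo_share_mean) * kappa, n)
    lesion_hypo = share * lesion_total
    lesion_iso = lesion_total - lesion_hypo

    # Remaining WM metrics carry no built-in clinical association.
    median_mw = np.clip(rng.normal(0.10, 0.008, n), 0.0, 1.0)
    median_iew = np.clip(1.0 - median_mw - median_fw, 0.0, 1.0)
    median_t2_iew = rng.normal(80.0, 4.0, n)
    mean_jitter = rng.normal(0.0, 0.002, (4, n))

    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "edss": edss,
            "duration_years": duration,
            "age_years": age,
            "lesion_total_mm3": lesion_total,
            "lesion_t1_iso_mm3": lesion_iso,
            "lesion_t1_hypo_mm3": lesion_hypo,
            "median_mw_frac": median_mw,
            "median_iew_frac": median_iew,
            "median_fw_frac": median_fw,
            "median_t2_iew": median_t2_iew,
            "mean_mw_frac": np.clip(median_mw + mean_jitter[0], 0.0, 1.0),
            "mean_iew_frac": np.clip(median_iew + mean_jitter[1], 0.0, 1.0),
            "mean_fw_frac": np.clip(median_fw + mean_jitter[2], 1e-4, 1.0),
            "mean_t2_iew": median_t2_iew + mean_jitter[3] * 100.0,
        }
    )


def generate_subject_phantom(
    row: pd.Series | dict,
    shape: tuple[int, int, int] = (16, 16, 4),
    snr: float = 200.0,
    seed: int = 0,
) -> Phantom:
    """Full-path subject: a phantom whose WM free-water truth equals the
    subject's generated median Fw (myelin pool held at its default), with
    lesion radii scaled to the subject's generated lesion volume."""
    fw = float(row["median_fw_frac"])
    mw = 0.10
    wm_truth = RegionTruth(
        PoolTruth(mw, 20.0), PoolTruth(1.0 - mw - fw, 80.0), PoolTruth(fw, 1000.0)
    )
    rel = float(row.get("lesion_total_mm3", 3000.0)) / 3000.0
    scale = float(np.clip(rel ** (1.0 / 3.0), 0.75, 1.4))
    spec = PhantomSpec(
        shape=shape,
        csf_radius=2.2,
        lesions=(
            LesionSpec((4.0, 4.0, 1.5), 1.4 * scale, t1_hypo=False),
            LesionSpec((11.0, 11.0, 2.0), 1.6 * scale, t1_hypo=True),
        ),
        wm_truth=wm_truth,
        snr=snr,
        seed=seed,
    )
    return generate_phantom(spec)
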
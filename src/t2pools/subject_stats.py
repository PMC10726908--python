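"""Per-subject summaries and the cohort correlation battery.

Each subject's compartment maps are summarized (median and mean of the
three pool fractions and the IEw T2) over the eroded non-lesional WM mask,
merged with the clinical record, and the cohort table is pushed through the
correlation battery: rank correlation of every WM parameter with EDSS,
product-moment correlation with disease duration, age, and T1 lesion load,
rank correlations of lesion volumes with EDSS, and two-predictor OLS models
of EDSS on lesion volume plus each WM parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _sps

from .compartment_maps import CompartmentMaps
from .segmentation_masks import MaskSet, lesion_report

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectSummary",
    "summarize_subject",
    "spearman",
    "pearson",
    "bivariate_edss_model",
    "correlation_battery",
    "WM_PARAMETERS",
]

#: The eight WM parameters reported per subject: {median, mean} x 4 metrics.
WM_PARAMETERS = tuple(
    f"{stat}_{metric}"
    for stat in ("median", "mean")
    for metric in ("mw_frac", "iew_frac", "fw_frac", "t2_iew")
)

LESION_VOLUMES = ("lesion_total_mm3", "lesion_t1_iso_mm3", "lesion_t1_hypo_mm3")


@dataclass(frozen=True)
class SubjectSummary:
    subject_id: str
    median_mw_frac: float
    median_iew_frac: float
    median_fw_frac: float
    median_t2_iew: float
    mean_mw_frac: float
    mean_iew_frac: float
    mean_fw_frac: float
    mean_t2_iew: float
    lesion_total_mm3: float
    lesion_t1_iso_mm3: float
    lesion_t1_hypo_mm3: float
    edss: float
    duration_years: float
    age_years: float


def summarize_subject(
    maps: CompartmentMaps,
    masks: MaskSet,
    clinical: dict,
) -> SubjectSummary:
    """Median/mean of each WM metric over in-mask non-background voxels.

    ``clinical`` must provide subject_id, edss, duration_years, age_years.
    Voxels with undefined IEw T2 are excluded from its summary only.
    """
    mask = np.asarray(masks.nonlesional_wm, dtype=bool)
    if mask.shape != maps.background.shape:
        raise ValueError("mask shape must match map shape")
    valid = mask & ~maps.background
    if not valid.any():
        raise ValueError("empty summary mask: no valid in-mask voxels")

    values: dict[str, float] = {}
    for name, arr in (
        ("mw_frac", maps.mw_frac),
        ("iew_frac", maps.iew_frac),
        ("fw_frac", maps.fw_frac),
        ("t2_iew", maps.t2_iew),
    ):
        sel = arr[valid]
        sel = sel[np.isfinite(sel)]
        if sel.size == 0:
            logger.warning("all-%s values undefined in mask; summary flagged missing", name)
            values[f"median_{name}"] = float("nan")
            values[f"mean_{name}"] = float("nan")
        else:
            values[f"median_{name}"] = float(np.median(sel))
            values[f"mean_{name}"] = float(np.mean(sel))

    report = lesion_report(masks)
    return SubjectSummary(
        subject_id=str(clinical["subject_id"]),
        lesion_total_mm3=report.total_volume_mm3,
        lesion_t1_iso_mm3=report.t1_iso_volume_mm3,
        lesion_t1_hypo_mm3=report.t1_hypo_volume_mm3,
        edss=float(clinical["edss"]),
        duration_years=float(clinical["duration_years"]),
        age_years=float(clinical["age_years"]),
        **values,
    )


def _t_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation via the t approximation, n-2 df."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * _sps.t.sf(abs(t), n - 2))


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    return r, _t_pvalue(r, n)


def _midranks(v: np.ndarray) -> np.ndarray:
    return _sps.rankdata(v, method="average")


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected (midrank) rank correlation; p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    return pearson(_midranks(x), _midranks(y))


@dataclass(frozen=True)
class BivariateResult:
    wm_parameter: str
    coef_lesion: float
    coef_wm: float
    p_lesion: float
    p_wm: float
    model_p: float
    r2: float
    n: int
    collinear: bool = False


def bivariate_edss_model(edss, lesion_volume, wm_parameter, name: str = "wm") -> BivariateResult:
    """OLS of EDSS on standardized (lesion volume, WM parameter) predictors.

    Coefficient p-values come from the per-coefficient t statistics and the
    model p-value from the overall F test. Near-collinear predictors
    (|r| > 0.999) are flagged and the coefficients suppressed.
    """
    edss = np.asarray(edss, dtype=float)
    lesion_volume = np.asarray(lesion_volume, dtype=float)
    wm_parameter = np.asarray(wm_parameter, dtype=float)
    n = edss.size
    if n <= 3:
        raise ValueError("need more than 3 observations")

    degenerate = lesion_volume.std(ddof=1) == 0 or wm_parameter.std(ddof=1) == 0
    if not degenerate:
        r_pred, _ = pearson(lesion_volume, wm_parameter)
        degenerate = np.isfinite(r_pred) and abs(r_pred) > 0.999
    if degenerate:
        return BivariateResult(name, *(float("nan"),) * 6, n=n, collinear=True)

    def standardize(v: np.ndarray) -> np.ndarray:
        s = v.std(ddof=1)
        return (v - v.mean()) / s if s > 0 else v - v.mean()

    X = sm.add_constant(np.column_stack([standardize(lesion_volume), standardize(wm_parameter)]))
    fit = sm.OLS(edss, X).fit()
    return BivariateResult(
        wm_parameter=name,
        coef_lesion=float(fit.params[1]),
        coef_wm=float(fit.params[2]),
        p_lesion=float(fit.pvalues[1]),
        p_wm=float(fit.pvalues[2]),
        model_p=float(fit.f_pvalue),
        r2=float(fit.rsquared),
        n=n,
    )


def correlation_battery(
    cohort: pd.DataFrame,
    lesion_load_column: str = "lesion_t1_hypo_mm3",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full correlation battery on a cohort summary table.

    Returns ``(wm_correlations, lesion_correlations, bivariate_models)``:

    * one row per WM parameter (8) x covariate (EDSS by rank correlation;
      duration, age and T1 lesion load by product-moment correlation);
    * one rank-correlation row per lesion volume (total, T1-iso, T1-hypo)
      against EDSS;
    * one two-predictor OLS model per WM parameter, pairing it with the
      total lesion volume to predict EDSS.

    Rows with missing fields are excluded pairwise and logged.
    """
    if isinstance(cohort, (list, tuple)):
        cohort = pd.DataFrame([asdict(s) for s in cohort])
    if len(cohort) < 3:
        raise ValueError("need at least 3 subjects")

    covariates = [
        ("edss", "spearman"),
        ("duration_years", "pearson"),
        ("age_years", "pearson"),
        (lesion_load_column, "pearson"),
    ]

    def _pairwise(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
        sub = cohort[[a, b]].dropna()
        if len(sub) < len(cohort):
            logger.info("excluded %d rows with missing %s/%s", len(cohort) - len(sub), a, b)
        return sub[a].to_numpy(float), sub[b].to_numpy(float)

    wm_rows = []
    for param in WM_PARAMETERS:
        for cov, method in covariates:
            x, y = _pairwise(param, cov)
            r, p = (spearman if method == "spearman" else pearson)(x, y)
            wm_rows.append(
                {
                    "parameter": param,
                    "covariate": cov,
                    "method": method,
                    "r": r,
                    "p": p,
                    "n": x.size,
                }
            )

    lesion_rows = []
    for vol in LESION_VOLUMES:
        x, y = _pairwise(vol, "edss")
        r, p = spearman(x, y)
        lesion_rows.append(
            {"parameter": vol, "covariate": "edss", "method": "spearman", "r": r, "p": p, "n": x.size}
        )

    biv_rows = []
    for param in WM_PARAMETERS:
        sub = cohort[["edss", "lesion_total_mm3", param]].dropna()
        if len(sub) <= 3:
            logger.warning("too few subjects for the bivariate model of %s", param)
            biv_rows.append(asdict(BivariateResult(param, *(float("nan"),) * 6, n=len(sub))))
            continue
        res = bivariate_edss_model(
            sub["edss"].to_numpy(float),
            sub["lesion_total_mm3"].to_numpy(float),
            sub[param].to_numpy(float),
            name=param,
        )
        biv_rows.append(asdict(res))

    return pd.DataFrame(wm_rows), pd.DataFrame(lesion_rows), pd.DataFrame(biv_rows)
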
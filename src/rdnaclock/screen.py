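"""Per-locus age screening: OLS regression, Holm correction, saturation ages."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylation import MethylationMatrix


@dataclass
class LocusRegressionResult:
    locus_id: str
    slope: float  # percent per month
    intercept: float  # percent at age 0
    r_squared: float
    p_raw: float
    p_adjusted: float  # filled by screen_all
    direction: str  # hyper | hypo | flat
    saturation_age: float  # months, +inf for flat loci


def fit_locus(meth: np.ndarray, ages: np.ndarray, locus_id: str = "") -> LocusRegressionResult:
    """OLS of percent methylation on age for one locus.

    Two-sided slope p-value from the t distribution with n-2 df. Constant
    methylation gives slope 0, R^2 0, p 1; constant ages are a degenerate
    design and raise.
    """
    meth = np.asarray(meth, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if meth.shape != ages.shape or meth.ndim != 1:
        raise ValueError("meth and ages must be 1-D vectors of equal length")
    if len(meth) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(ages) == 0:
        raise ValueError("degenerate design: ages are all equal")
    if np.ptp(meth) == 0:
        result = LocusRegressionResult(
            locus_id=locus_id,
            slope=0.0,
            intercept=float(meth[0]),
            r_squared=0.0,
            p_raw=1.0,
            p_adjusted=math.nan,
            direction="flat",
            saturation_age=math.inf,
        )
        return result
    fit = stats.linregress(ages, meth)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue**2)
    direction = "hyper" if slope > 0 else ("hypo" if slope < 0 else "flat")
    result = LocusRegressionResult(
        locus_id=locus_id,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        p_raw=float(fit.pvalue),
        p_adjusted=math.nan,
        direction=direction,
        saturation_age=math.nan,
    )
    result.saturation_age = saturation_age(result)
    return result


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    Sorted ascending, p_(i) is multiplied by (m - i + 1), a running maximum is
    enforced and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="holm")
    return adjusted


def saturation_age(result: LocusRegressionResult) -> float:
    """Extrapolated age (months from hatching) at which the fitted line hits
    0% or 100% methylation; +inf for a flat locus, 0 if the intercept already
    lies outside [0, 100]."""
    a, b = result.intercept, result.slope
    if b == 0:
        return math.inf
    if a < 0 or a > 100:
        return 0.0
    if b > 0:
        return (100.0 - a) / b
    return -a / b


@dataclass
class ScreenSummary:
    n_loci: int
    n_significant: int
    alpha: float
    mean_saturation_age: float
    min_saturation_age: float
    max_saturation_age: float
    mean_saturation_age_excl_extreme: float
    min_saturation_age_excl_extreme: float
    max_saturation_age_excl_extreme: float


def screen_all(
    matrix: MethylationMatrix,
    ages: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, ScreenSummary]:
    """Regress every locus on age, Holm-adjust, and summarise saturation.

    Returns results ordered by (region, position) plus a summary giving the
    Holm-significant count and the mean/min/max saturation age over the
    significant loci, both including and excluding the single largest
    saturation age (the extreme-locus-removed variant).
    """
    if isinstance(ages, pd.Series):
        ages = ages.loc[matrix.samples].to_numpy(dtype=float)
    else:
        ages = np.asarray(ages, dtype=float)
    rows = []
    for locus in matrix.locus_ids:
        res = fit_locus(matrix.values[locus].to_numpy(dtype=float), ages, locus_id=locus)
        rows.append(res)
    p_adj = holm_adjust([r.p_raw for r in rows])
    for r, pa in zip(rows, p_adj):
        r.p_adjusted = float(pa)
    frame = pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in rows],
            "region": matrix.loci["region"].to_numpy(),
            "position": matrix.loci["position"].to_numpy(),
            "slope": [r.slope for r in rows],
            "intercept": [r.intercept for r in rows],
            "r_squared": [r.r_squared for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_adjusted": [r.p_adjusted for r in rows],
            "direction": [r.direction for r in rows],
            "saturation_age": [r.saturation_age for r in rows],
        }
    )
    sig = frame[frame["p_adjusted"] < alpha]
    sat = sig["saturation_age"].to_numpy(dtype=float)
    sat = sat[np.isfinite(sat)]

    def _stats(values: np.ndarray) -> tuple[float, float, float]:
        if values.size == 0:
            return (math.nan, math.nan, math.nan)
        return (float(values.mean()), float(values.min()), float(values.max()))

    mean_all, min_all, max_all = _stats(sat)
    if sat.size > 1:
        trimmed = np.delete(sat, int(np.argmax(sat)))
    else:
        trimmed = np.array([])
    mean_tr, min_tr, max_tr = _stats(trimmed)
    summary = ScreenSummary(
        n_loci=len(frame),
        n_significant=int(len(sig)),
        alpha=alpha,
        mean_saturation_age=mean_all,
        min_saturation_age=min_all,
        max_saturation_age=max_all,
        mean_saturation_age_excl_extreme=mean_tr,
        min_saturation_age_excl_extreme=min_tr,
        max_saturation_age_excl_extreme=max_tr,
    )
    return frame, summary


def write_screen_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Export in a Gene/Position table layout plus saturation columns."""
    out = frame.rename(
        columns={
            "region": "Gene",
            "position": "Position",
            "slope": "coefficient",
            "r_squared": "R2",
            "p_adjusted": "Adjusted_p",
        }
    )[
        [
            "Gene",
            "Position",
            "coefficient",
            "intercept",
            "R2",
            "p_raw",
            "Adjusted_p",
            "direction",
            "saturation_age",
        ]
    ]
    out.to_csv(path, index=False, float_format="%.10g")
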
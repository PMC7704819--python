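"""Segmentation accuracy, agreement, reproducibility and group statistics.

Covers the four evaluation routes used for automated muscle segmentation:

* volumetric Dice overlap between manual and automated masks;
* percent differences in ROI volume and differences in mean fat fraction
  (percentage points), with repeated scans of a thigh averaged before any
  cohort-level mean so repeated subjects are not over-weighted;
* test-retest reproducibility of meanFF via the intraclass correlation
  coefficient, by default ICC(2,1) — two-way random effects, absolute
  agreement, single measure — with the classical ANOVA mean-squares
  estimate and F-distribution 95% confidence bounds (McGraw & Wong);
* a one-tailed two-sample Welch t-test (unequal variances) for group
  comparisons of meanFF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import fat_fraction_map, roi_stats
from .volumes import FatWaterVolume, MuscleLabelVolume, ROI_LABELS, check_same_grid

__all__ = [
    "IccResult",
    "WelchResult",
    "EvalReport",
    "dice",
    "percent_volume_diff",
    "icc_meanff",
    "welch_t_one_tailed",
    "evaluate_testset",
]

log = logging.getLogger(__name__)


def dice(a: MuscleLabelVolume, b: MuscleLabelVolume, roi: int) -> float:
    """Volumetric Dice 2|A∩B| / (|A|+|B|) of one ROI's 3D voxel sets.

    Both-empty masks return 1.0 (vacuous perfect agreement, logged); an
    empty-vs-nonempty pair returns 0.0.
    """
    check_same_grid(a, b)
    ma, mb = a.roi_mask(roi), b.roi_mask(roi)
    na, nb = int(ma.sum()), int(mb.sum())
    if na == 0 and nb == 0:
        log.info("dice: ROI %d empty in both volumes; returning 1.0", roi)
        return 1.0
    inter = int((ma & mb).sum())
    return 2.0 * inter / (na + nb)


def percent_volume_diff(manual_mm3: float, auto_mm3: float) -> float:
    """Signed percent volume difference (auto - manual) / manual * 100."""
    if manual_mm3 == 0:
        warnings.warn("percent_volume_diff undefined for zero manual volume")
        return float("nan")
    return (auto_mm3 - manual_mm3) / manual_mm3 * 100.0


@dataclass
class IccResult:
    icc_estimate: float
    ci95_low: float
    ci95_high: float
    model_descriptor: str
    n_subjects: int
    n_repeats: int
    degenerate: bool = False


def _anova_mean_squares(x: np.ndarray) -> Tuple[float, float, float]:
    """Two-way (subjects x repeats) ANOVA mean squares (MSR, MSC, MSE)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_meanff(
    table: np.ndarray | pd.DataFrame, model: str = "icc2", alpha: float = 0.05
) -> IccResult:
    """Single-measure ICC of a complete subjects x repeats table.

    ``model``: "icc2" = ICC(2,1), two-way random effects, absolute
    agreement (default — repositioned repeat scans are a random factor and
    reproducibility means absolute agreement); "icc3" = ICC(3,1), two-way
    mixed, consistency. 95% confidence bounds from the standard
    F-distribution formulas.

    A table with zero total variance is degenerate (no between-subject
    variance to attribute) and returns a flagged NaN result; perfect
    repeatability with subject differences returns exactly 1.0.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be 2D (subjects x repeats)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 repeats, got {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("incomplete table: all cells must be finite")
    desc = {
        "icc2": "ICC(2,1) two-way random, absolute agreement, single measure",
        "icc3": "ICC(3,1) two-way mixed, consistency, single measure",
    }
    if model not in desc:
        raise ValueError("model must be 'icc2' or 'icc3'")
    if np.ptp(x) == 0:
        return IccResult(float("nan"), float("nan"), float("nan"), desc[model], n, k, True)
    msr, msc, mse = _anova_mean_squares(x)

    if model == "icc3":
        est = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:
            return IccResult(1.0, 1.0, 1.0, desc[model], n, k)
        f_obs = msr / mse
        d1, d2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, d1, d2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, d2, d1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return IccResult(float(est), float(lo), float(hi), desc[model], n, k)

    est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse == 0 and msc == 0:
        return IccResult(1.0, 1.0, 1.0, desc[model], n, k)
    a = (k * est) / (n * (1 - est)) if est < 1 else np.inf
    b = 1 + (k * est * (n - 1)) / (n * (1 - est)) if est < 1 else np.inf
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return IccResult(float(est), float(lo), float(hi), desc[model], n, k)


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    flagged: bool = False


def welch_t_one_tailed(
    group_a: Sequence[float], group_b: Sequence[float], direction: str = "greater"
) -> WelchResult:
    """One-tailed two-sample t-test assuming unequal variances (Welch).

    ``direction`` is the alternative for group_a relative to group_b:
    "greater" tests mean(a) > mean(b), "less" tests mean(a) < mean(b)
    (e.g. pass the abnormal group as ``group_a`` with "greater" to test
    for elevated meanFF). Identical groups give p = 0.5. Two zero-variance
    groups with equal means have no defined statistic and return a flagged
    NaN result.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(float("nan"), float("nan"), float("nan"), True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, equal_var=False, alternative=direction)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


@dataclass
class EvalReport:
    """Per-scan, per-thigh (repeat-averaged) and cohort-level evaluation."""

    per_scan: pd.DataFrame
    per_thigh: pd.DataFrame
    summary: Dict[str, float]


def evaluate_testset(
    pairs: Sequence[Tuple[MuscleLabelVolume, MuscleLabelVolume, FatWaterVolume, str, int]]
) -> EvalReport:
    """Evaluate (manual, auto, volume, thigh_id, repeat_id) test pairs.

    ``thigh_id`` identifies one thigh (include the side in the id for
    bilateral subjects). Repeated scans of a thigh are averaged first;
    cohort means — of Dice, of |percent volume difference| and of |meanFF
    difference| — are taken over the per-thigh rows, so thighs scanned
    several times carry the same weight as thighs scanned once.
    """
    if not pairs:
        raise ValueError("empty test set")
    rows: List[dict] = []
    for manual, auto, vol, thigh_id, repeat_id in pairs:
        ffmap = fat_fraction_map(vol)
        for roi in ROI_LABELS:
            sm = roi_stats(ffmap, manual, roi)
            sa = roi_stats(ffmap, auto, roi)
            rows.append(
                {
                    "thigh_id": thigh_id,
                    "repeat_id": repeat_id,
                    "roi": roi,
                    "dice": dice(manual, auto, roi),
                    "manual_volume_mm3": sm.volume_mm3,
                    "auto_volume_mm3": sa.volume_mm3,
                    "pct_volume_diff": percent_volume_diff(sm.volume_mm3, sa.volume_mm3),
                    "manual_meanff": sm.mean_ff_percent,
                    "auto_meanff": sa.mean_ff_percent,
                    "meanff_diff_pp": sa.mean_ff_percent - sm.mean_ff_percent,
                }
            )
    per_scan = pd.DataFrame(rows)
    value_cols = [
        "dice",
        "manual_volume_mm3",
        "auto_volume_mm3",
        "pct_volume_diff",
        "manual_meanff",
        "auto_meanff",
        "meanff_diff_pp",
    ]
    per_thigh = (
        per_scan.groupby(["thigh_id", "roi"], as_index=False)[value_cols].mean()
    )
    summary = {
        "mean_dice": float(per_thigh["dice"].mean()),
        "mean_abs_pct_volume_diff": float(per_thigh["pct_volume_diff"].abs().mean()),
        "mean_abs_meanff_diff_pp": float(per_thigh["meanff_diff_pp"].abs().mean()),
        "n_thighs": int(per_thigh["thigh_id"].nunique()),
        "n_scans": int(per_scan.groupby(["thigh_id", "repeat_id"]).ngroups),
    }
    return EvalReport(per_scan, per_thigh, summary)
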
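"""Cohort-level statistics: group comparisons and MCHART correlations.

Per-subject shape results are assembled into two tables. The demographic
table reports group mean +/- SD for each ONL parameter with a two-group
parametric comparison (Welch's t by default). The correlation table reports
Pearson correlations of the metamorphopsia anisotropy score MH/MV against
each ONL shape parameter, both for all ERM eyes and for the subset whose
major axis lies within a window (default +/-10 degrees) of horizontal —
where the MCHART's horizontal/vertical decomposition aligns with the
deformation axes.

MH/MV uses the chart's zero-substitution rule: a score of 0 (no detected
distortion) is recorded as 0.05 before forming the ratio, keeping the
ratio finite and defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ellipse_fit import ShapeParams
from .errors import ParameterError, StatisticsError
from .surface_io import SubjectMeta

logger = logging.getLogger(__name__)

ALPHA = 0.05
ZERO_SUBSTITUTE = 0.05

SHAPE_VARIABLES = ["onl_height_um", "axis_deg", "circularity", "area_ratio", "axis_ratio"]


@dataclass
class SubjectRecord:
    """Everything cohort statistics need about one analyzed eye."""

    meta: SubjectMeta
    shape: ShapeParams
    onl_height_um: float
    level_um: float

    @property
    def mh_mv(self) -> float:
        return mh_mv_ratio(self.meta.mh, self.meta.mv)

    def value(self, variable: str) -> float:
        if variable == "onl_height_um":
            return self.onl_height_um
        if variable == "level_um":
            return self.level_um
        return getattr(self.shape, variable)


def mh_mv_ratio(mh: float, mv: float) -> float:
    """MH/MV with 0 recorded as 0.05 in either score."""
    if not (0.0 <= mh <= 2.0 and 0.0 <= mv <= 2.0):
        raise ParameterError(f"MCHART scores must lie in [0, 2], got mh={mh}, mv={mv}")
    mh = mh if mh > 0 else ZERO_SUBSTITUTE
    mv = mv if mv > 0 else ZERO_SUBSTITUTE
    return mh / mv


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("pearson needs two equal-length 1-D vectors")
    if x.size < 3:
        raise StatisticsError(f"need n >= 3 for a correlation, got n={x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatisticsError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def two_group_compare(a, b, variant: str = "welch"):
    """Group means, SDs (n-1 denominator) and a two-sided two-sample t-test.

    ``variant`` selects Welch's unequal-variance test (default) or the
    pooled-variance Student test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatisticsError("each group needs n >= 2")
    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    if sd_a == 0 and sd_b == 0:
        raise StatisticsError("both groups have zero variance; t-test degenerate")
    if variant not in ("welch", "student"):
        raise ParameterError(f"unknown t-test variant {variant!r}")
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return (float(a.mean()), float(sd_a), float(b.mean()), float(sd_b),
            float(t), float(p))


def _group_values(records, group, variable):
    return np.array([r.value(variable) for r in records if r.meta.group == group])


def table1_summary(records: list[SubjectRecord], t_variant: str = "welch") -> pd.DataFrame:
    """Per-group mean +/- SD of the ONL parameters with comparison p-values.

    Rows cover the ONL parameters plus logMAR acuity and, for the ERM group
    only, the raw MCHART scores. Missing comparison columns (single-group
    input, degenerate variance) are left as NaN.
    """
    groups_present = {r.meta.group for r in records}
    if not groups_present:
        raise StatisticsError("no records")
    rows = []
    variables = [("logmar_va", lambda r: r.meta.logmar_va)] + [
        (v, (lambda r, v=v: r.value(v))) for v in SHAPE_VARIABLES
    ]
    for name, getter in variables:
        erm = np.array([getter(r) for r in records if r.meta.group == "ERM"])
        ctl = np.array([getter(r) for r in records if r.meta.group == "control"])
        row = {"variable": name,
               "erm_n": erm.size, "control_n": ctl.size,
               "erm_mean": erm.mean() if erm.size else np.nan,
               "erm_sd": erm.std(ddof=1) if erm.size > 1 else np.nan,
               "control_mean": ctl.mean() if ctl.size else np.nan,
               "control_sd": ctl.std(ddof=1) if ctl.size > 1 else np.nan,
               "t": np.nan, "p": np.nan}
        if erm.size >= 2 and ctl.size >= 2:
            try:
                *_, t, p = two_group_compare(erm, ctl, variant=t_variant)
                row["t"], row["p"] = t, p
            except StatisticsError as exc:
                logger.warning("comparison for %s skipped: %s", name, exc)
        rows.append(row)
    for name in ("mh", "mv"):
        vals = np.array([getattr(r.meta, name) for r in records if r.meta.group == "ERM"])
        rows.append({"variable": name,
                     "erm_n": vals.size, "control_n": 0,
                     "erm_mean": vals.mean() if vals.size else np.nan,
                     "erm_sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
                     "control_mean": np.nan, "control_sd": np.nan,
                     "t": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def table2_correlations(
    records: list[SubjectRecord],
    axis_window_deg: float = 10.0,
    variables=tuple(SHAPE_VARIABLES),
) -> pd.DataFrame:
    """Pearson correlation of MH/MV with each shape parameter, in ERM eyes.

    Two subsets are reported: all ERM eyes, and those whose (laterality-
    adjusted) major-axis angle lies within ``axis_window_deg`` of
    horizontal. A subset smaller than 3, or a constant variable, yields NaN
    correlation entries with a logged warning rather than an error.
    """
    erm = [r for r in records if r.meta.group == "ERM"]
    if len(erm) < 3:
        raise StatisticsError(f"need >= 3 ERM records, got {len(erm)}")
    subsets = {
        "all": erm,
        "axis_within_window": [r for r in erm if abs(r.shape.axis_deg) <= axis_window_deg],
    }
    rows = []
    for subset_name, subset in subsets.items():
        if len(subset) < 3:
            logger.warning("subset %s has n=%d < 3; correlations skipped",
                           subset_name, len(subset))
            continue
        ratio = np.array([r.mh_mv for r in subset])
        for var in variables:
            vals = np.array([r.value(var) for r in subset])
            row = {"variable": var, "subset": subset_name, "n": len(subset),
                   "r": np.nan, "p": np.nan, "significant": False}
            try:
                r, p = pearson(ratio, vals)
                row.update(r=r, p=p, significant=bool(p < ALPHA))
            except StatisticsError as exc:
                logger.warning("correlation mh_mv~%s (%s) undefined: %s",
                               var, subset_name, exc)
            rows.append(row)
    return pd.DataFrame(rows)
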
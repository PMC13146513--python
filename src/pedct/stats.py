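"""Normative summaries, stratified group tests and age-response fits.

The cohort is stratified at 24 months (young < 24, old >= 24).  Continuous
summaries are median and IQR (25th/75th percentiles, linear interpolation
between order statistics).  Two-group comparisons are gated on normality:
Shapiro-Wilk at alpha = 0.05 in each group; if both pass, a Welch unpaired
t-test, otherwise a two-sided Mann-Whitney U test; p-values are
Bonferroni-adjusted by the family size and capped at 1.

Age-response fits: power curves ``y = a x**b`` are fit by ordinary least
squares of ln(y) on ln(x), with R² reported on the log scale (the
spreadsheet-trendline convention); linear fits are OLS on the original
scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import AGE_BOUNDARY_MONTHS, GROUP_OLD, GROUP_YOUNG
from .gwr import FORMULAS
from .regions import DOT_SUMMARY_REGIONS, ROI_REGIONS

SHAPIRO_ALPHA = 0.05

#: Bonferroni family sizes: the row counts of the reported summary blocks.
FAMILY_ROI = len(ROI_REGIONS)  # 14
FAMILY_DOT = len(DOT_SUMMARY_REGIONS)  # 9
FAMILY_GWR = len(FORMULAS)  # 12

#: regions with a power-law age trend (fit on log-log scale)
POWER_FIT_REGIONS = ("parenchyma_SL1", "parenchyma_SL2", "CN", "GM_SL1", "GM_SL2")
#: regions with a (near-flat) linear age trend
LINEAR_FIT_REGIONS = ("PT", "TM", "WM_SL1", "WM_SL2")


class StatsError(RuntimeError):
    pass


def stratify(ages_months) -> np.ndarray:
    """Group label per age: young (< 24 months) or old (>= 24 months)."""
    ages = np.asarray(ages_months, dtype=float)
    if np.any(ages <= 0):
        raise StatsError("ages must be positive")
    return np.where(ages < AGE_BOUNDARY_MONTHS, GROUP_YOUNG, GROUP_OLD)


def summarize(values) -> tuple[float, float, float]:
    """(median, 25th percentile, 75th percentile) with linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatsError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    n_young: int
    n_old: int
    median_young: float
    iqr_young: tuple[float, float]
    median_old: float
    iqr_old: tuple[float, float]
    test_used: str  # "t_test" or "mann_whitney"
    p_raw: float
    p_adjusted: float
    family_size: int


def compare_groups(young, old, family_size: int, variable: str = "") -> GroupComparison:
    """Normality-gated two-group test with Bonferroni adjustment."""
    y, o = np.asarray(young, float), np.asarray(old, float)
    if y.size < 3 or o.size < 3:
        raise StatsError("each group needs n >= 3")
    if family_size < 1:
        raise StatsError("family_size must be >= 1")

    def _normal(x):
        if np.ptp(x) == 0:  # Shapiro undefined on constant data
            return False
        return sps.shapiro(x).pvalue > SHAPIRO_ALPHA

    if _normal(y) and _normal(o):
        test_used = "t_test"
        p_raw = float(sps.ttest_ind(y, o, equal_var=False).pvalue)
    else:
        test_used = "mann_whitney"
        p_raw = float(sps.mannwhitneyu(y, o, alternative="two-sided").pvalue)

    med_y, q1y, q3y = summarize(y)
    med_o, q1o, q3o = summarize(o)
    return GroupComparison(
        variable=variable,
        n_young=y.size,
        n_old=o.size,
        median_young=med_y,
        iqr_young=(q1y, q3y),
        median_old=med_o,
        iqr_old=(q1o, q3o),
        test_used=test_used,
        p_raw=p_raw,
        p_adjusted=min(1.0, p_raw * family_size),
        family_size=family_size,
    )


@dataclass(frozen=True)
class CurveFit:
    form: str  # "power" or "linear"
    a: float  # power coefficient, or linear slope's intercept partner (unused)
    b: float  # exponent (power) or slope in HU/month (linear)
    intercept: float
    r_squared: float
    n: int

    def predict(self, age_months):
        x = np.asarray(age_months, dtype=float)
        if self.form == "power":
            return self.a * x**self.b
        return self.b * x + self.intercept


def fit_power_curve(ages_months, values) -> CurveFit:
    """Fit ``y = a x**b`` by OLS of ln(y) on ln(x); R² on the log scale."""
    x, y = np.asarray(ages_months, float), np.asarray(values, float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need >= 3 paired observations")
    if np.any(x <= 0) or np.any(y <= 0):
        raise StatsError("power fit requires positive ages and values")
    ly = np.log(y)
    if np.ptp(ly) == 0:
        warnings.warn("zero-variance response: exponent 0, R^2 defined as 0", stacklevel=2)
        return CurveFit("power", a=float(y[0]), b=0.0, intercept=0.0, r_squared=0.0, n=x.size)
    res = sps.linregress(np.log(x), ly)
    return CurveFit(
        "power",
        a=float(np.exp(res.intercept)),
        b=float(res.slope),
        intercept=0.0,
        r_squared=float(res.rvalue**2),
        n=x.size,
    )


def fit_linear(ages_months, values) -> CurveFit:
    """OLS linear fit on the original scale."""
    x, y = np.asarray(ages_months, float), np.asarray(values, float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise StatsError("degenerate fit: all ages identical")
    if np.ptp(y) == 0:
        warnings.warn("zero-variance response: slope 0, R^2 defined as 0", stacklevel=2)
        return CurveFit("linear", a=0.0, b=0.0, intercept=float(y[0]), r_squared=0.0, n=x.size)
    res = sps.linregress(x, y)
    return CurveFit(
        "linear",
        a=0.0,
        b=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=x.size,
    )


def _comparison_rows(values_by_var, family_size):
    rows = []
    for var, (young, old) in values_by_var.items():
        c = compare_groups(young, old, family_size, variable=var)
        rows.append(
            {
                "variable": c.variable,
                "n_young": c.n_young,
                "n_old": c.n_old,
                "median_young": c.median_young,
                "iqr_young_low": c.iqr_young[0],
                "iqr_young_high": c.iqr_young[1],
                "median_old": c.median_old,
                "iqr_old_low": c.iqr_old[0],
                "iqr_old_high": c.iqr_old[1],
                "test_used": c.test_used,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
            }
        )
    return pd.DataFrame(rows)


def normative_report(
    cohort: pd.DataFrame,
    hu: pd.DataFrame,
    gwr: pd.DataFrame,
    family_roi: int = FAMILY_ROI,
    family_dot: int = FAMILY_DOT,
    family_gwr: int = FAMILY_GWR,
) -> dict[str, pd.DataFrame]:
    """Normative report bundle.

    Inputs: tidy cohort (``subject_id, age_months, group``), HU measurements
    (``subject_id, method, region, hu``; both methods) and GWR values
    (``subject_id, formula_id, value``).  Returns three frames:

    * ``hu_summary`` — per method x region: group medians/IQRs and the
      adjusted group-difference p (families: 14 ROI rows, 9 DOT rows);
    * ``gwr_summary`` — the 12 formulas, same layout (family 12);
    * ``curve_fits`` — age-response fits (power for parenchyma/CN/cortical
      gray on ROI resp. DOT values, linear for PT/TM/WM) with R².
    """
    groups = cohort.set_index("subject_id")["group"]
    ages = cohort.set_index("subject_id")["age_months"]
    if not {GROUP_YOUNG, GROUP_OLD} <= set(groups):
        raise StatsError("both age strata are required for the normative report")

    def _split(frame, value_col, key_col, keys, method=None):
        out = {}
        sub = frame if method is None else frame[frame["method"] == method]
        for key in keys:
            v = sub[sub[key_col] == key]
            g = groups.loc[v["subject_id"]].to_numpy()
            vals = v[value_col].to_numpy()
            out[key] = (vals[g == GROUP_YOUNG], vals[g == GROUP_OLD])
        return out

    roi = _comparison_rows(_split(hu, "hu", "region", ROI_REGIONS, "ROI"), family_roi)
    roi.insert(0, "method", "ROI")
    dot = _comparison_rows(_split(hu, "hu", "region", DOT_SUMMARY_REGIONS, "DOT"), family_dot)
    dot.insert(0, "method", "DOT")
    hu_summary = pd.concat([roi, dot], ignore_index=True)

    gwr_summary = _comparison_rows(
        _split(gwr, "value", "formula_id", list(FORMULAS)), family_gwr
    )

    fit_rows = []
    for region in POWER_FIT_REGIONS + LINEAR_FIT_REGIONS:
        method = "ROI" if region in set(ROI_REGIONS) else "DOT"
        v = hu[(hu["method"] == method) & (hu["region"] == region)]
        if v.empty:
            continue
        x = ages.loc[v["subject_id"]].to_numpy()
        y = v["hu"].to_numpy()
        fit = (
            fit_power_curve(x, y) if region in POWER_FIT_REGIONS else fit_linear(x, y)
        )
        fit_rows.append(
            {
                "region": region,
                "method": method,
                "form": fit.form,
                "a": fit.a,
                "b": fit.b,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n": fit.n,
            }
        )
    return {
        "hu_summary": hu_summary,
        "gwr_summary": gwr_summary,
        "curve_fits": pd.DataFrame(fit_rows),
    }
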
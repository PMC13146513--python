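"""Method and rater agreement.

* Bland-Altman analysis of ROI-vs-DOT paired HU measurements: differences
  are DOT minus ROI; bias is their mean; limits of agreement are
  bias +/- 1.96 * sample SD (n-1 denominator).  The 1.96 multiplier is part
  of the protocol, not a parameter.
* Intra-rater agreement via the intraclass correlation coefficient,
  two-way random effects, absolute agreement, single measures — ICC(2,1) —
  on a complete subjects x sessions rating matrix.  Re-reads of a fixed
  scan are simulated as the original measurement plus Gaussian re-read
  noise on a randomly selected fraction of subjects.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
import pingouin as pg

from .measure import METHOD_DOT, RegionHUTable
from .regions import DOT_SUMMARY_REGIONS, SliceID, get_region, regions_for_slice

LOA_MULTIPLIER = 1.96

#: regions compared between the ROI and DOT methods
AGREEMENT_REGIONS: tuple[str, ...] = ("CN", "PT", "TM", "ventricle_SL1", "ventricle_SL2")


class AgreementError(RuntimeError):
    pass


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired per-subject HU for one region under two methods (ROI, DOT)."""

    region: str
    subject_ids: tuple[str, ...]
    values_roi: np.ndarray
    values_dot: np.ndarray

    def __post_init__(self):
        get_region(self.region)
        a, b = np.asarray(self.values_roi, float), np.asarray(self.values_dot, float)
        if len(self.subject_ids) != a.size or a.size != b.size:
            raise AgreementError("paired lists must have equal length")
        if a.size < 2:
            raise AgreementError("need at least 2 pairs")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise AgreementError("non-finite paired values")
        object.__setattr__(self, "values_roi", a)
        object.__setattr__(self, "values_dot", b)


@dataclass(frozen=True)
class BlandAltmanResult:
    region: str
    n: int
    bias: float  # mean of DOT - ROI differences, HU
    sd_diff: float  # sample SD (n-1), HU
    loa_lower: float
    loa_upper: float
    diff_range: tuple[float, float]
    means: np.ndarray  # per-pair (ROI + DOT)/2, for plotting
    diffs: np.ndarray


def loa_from_summary(bias: float, sd_diff: float) -> tuple[float, float]:
    """Limits of agreement from a reported bias and difference SD."""
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    return bias - LOA_MULTIPLIER * sd_diff, bias + LOA_MULTIPLIER * sd_diff


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman statistics for one region's ROI/DOT pairs."""
    diffs = pairs.values_dot - pairs.values_roi
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lo, hi = loa_from_summary(bias, sd)
    return BlandAltmanResult(
        region=pairs.region,
        n=diffs.size,
        bias=bias,
        sd_diff=sd,
        loa_lower=lo,
        loa_upper=hi,
        diff_range=(float(diffs.min()), float(diffs.max())),
        means=(pairs.values_roi + pairs.values_dot) / 2.0,
        diffs=diffs,
    )


def paired_from_frames(hu: pd.DataFrame, region: str) -> PairedMeasurements:
    """Build pairs for one region from a tidy ``subject_id,method,region,hu`` table."""
    sub = hu[hu["region"] == region].pivot(index="subject_id", columns="method", values="hu")
    for col in ("ROI", "DOT"):
        if col not in sub or sub[col].isna().any():
            raise AgreementError(f"region {region!r}: missing {col} measurements")
    sub = sub.sort_index()
    return PairedMeasurements(
        region=region,
        subject_ids=tuple(sub.index),
        values_roi=sub["ROI"].to_numpy(),
        values_dot=sub["DOT"].to_numpy(),
    )


def agreement_table(hu: pd.DataFrame, regions=AGREEMENT_REGIONS) -> pd.DataFrame:
    """Per-region Bland-Altman summary (bias, SD, LoA, difference range)."""
    rows = []
    for region in regions:
        res = bland_altman(paired_from_frames(hu, region))
        rows.append(
            {
                "region": region,
                "n": res.n,
                "bias": res.bias,
                "sd": res.sd_diff,
                "loa_lower": res.loa_lower,
                "loa_upper": res.loa_upper,
                "diff_min": res.diff_range[0],
                "diff_max": res.diff_range[1],
            }
        )
    return pd.DataFrame(rows)


def icc_single_rater(ratings: np.ndarray, form: str = "ICC2") -> float:
    """ICC of a complete subjects x sessions matrix.

    ``form`` is a pingouin ICC type label; the default ICC2 is the two-way
    random-effects, absolute-agreement, single-measures coefficient.
    """
    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise AgreementError("ratings must be a matrix with >= 2 subjects and >= 2 sessions")
    if not np.isfinite(mat).all():
        raise AgreementError("ratings matrix must be complete (no missing values)")
    n, k = mat.shape
    long = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": mat.ravel(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        # degenerate matrices (e.g. identical sessions) produce undefined
        # F statistics inside pingouin; the ICC point estimate is still valid
        icc = pg.intraclass_corr(long, targets="targets", raters="raters", ratings="ratings")
    # conventional Shrout-Fleiss names -> pingouin's McGraw-Wong labels
    aliases = {
        "ICC1": "ICC(1,1)",
        "ICC2": "ICC(A,1)",
        "ICC3": "ICC(C,1)",
        "ICC1k": "ICC(1,k)",
        "ICC2k": "ICC(A,k)",
        "ICC3k": "ICC(C,k)",
    }
    label = aliases.get(form, form)
    row = icc[icc["Type"] == label]
    if row.empty:
        raise AgreementError(f"unknown ICC form {form!r}")
    return float(row["ICC"].iloc[0])


def simulate_rereads(
    tables: list[RegionHUTable],
    fraction: float = 0.1,
    reread_noise_sd: float = 0.5,
    seed: int | None = None,
    slice_id: SliceID | str = SliceID.SL1,
) -> tuple[np.ndarray, list[str]]:
    """Simulated intra-rater re-measurement of a fraction of the cohort.

    Selects ceil(fraction * n) subjects; each selected subject's per-region
    measurements on ``slice_id`` are duplicated with added Gaussian re-read
    noise.  Returns a ((subjects x regions) x 2 sessions) matrix plus the
    selected subject ids; same seed -> same selection and noise.
    """
    if not 0 < fraction <= 1:
        raise AgreementError("fraction must be in (0, 1]")
    if not tables:
        raise AgreementError("no measurement tables given")
    rng = np.random.default_rng(seed)
    n_sel = ceil(fraction * len(tables))
    idx = rng.choice(len(tables), size=n_sel, replace=False)
    idx.sort()
    sl = SliceID(slice_id)
    slice_regions = {r.name for r in regions_for_slice(sl)}
    region_order = [
        r
        for r in DOT_SUMMARY_REGIONS
        if r in slice_regions
    ] if tables[0].method == METHOD_DOT else sorted(
        r for r in tables[0].values if r in slice_regions
    )
    rows, selected = [], []
    for i in idx:
        table = tables[i]
        selected.append(table.subject_id)
        for region in region_order:
            if region not in table:
                raise AgreementError(f"{table.subject_id}: region {region!r} missing")
            first = table[region]
            second = first + (rng.normal(0.0, reread_noise_sd) if reread_noise_sd else 0.0)
            rows.append((first, second))
    if not rows:
        raise AgreementError("empty re-read selection")
    return np.asarray(rows, dtype=float), selected
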
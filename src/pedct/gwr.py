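"""Gray-white matter ratio (GWR) formulas.

Twelve formulas from the adult and pediatric literature, adapted to the
two-slice protocol.  The normalization convention is mean-over-mean:
``(CN + PT)/WM-SL1`` is read as mean(CN, PT) / WM-SL1, so every formula
yields a dimensionless ratio near 1.2-1.4 in normal brain (a literal
sum reading would give ~2.5, incompatible with any reported normal value;
the multi-region source formulas this dozen derives from average their
region lists explicitly).

``average2`` is a composite: the arithmetic mean of the bg1 and cortical
sub-ratios, computed per subject.

A table lacking a direct ``WM_SL1`` entry resolves it as the mean of the
anterior (frontal periventricular) and posterior (PLIC) probe sites.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measure import RegionHUTable


class GWRError(RuntimeError):
    """A formula could not be evaluated on the given table."""


@dataclass(frozen=True)
class GWRFormula:
    formula_id: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    composite_of: tuple[str, str] | None = None
    description: str = ""


def _f(fid, num, den, desc):
    return GWRFormula(fid, tuple(num), tuple(den), description=desc)


#: The 12-formula registry, in reporting order.
FORMULAS: dict[str, GWRFormula] = {
    f.formula_id: f
    for f in [
        _f("bg1", ["CN", "PT"], ["WM_SL1"], "basal ganglia without thalamus / SL1 WM"),
        _f("bg2", ["CN", "PT", "TM"], ["WM_SL1"], "basal ganglia with thalamus / SL1 WM"),
        _f("cortical", ["GM_SL1", "GM_SL2"], ["WM_SL1", "WM_SL2"], "cortical gray / white, both slices"),
        _f("average1", ["CN", "PT", "GM_SL1", "GM_SL2"], ["WM_SL1", "WM_SL2"], "deep nuclei + cortical gray / total white"),
        GWRFormula("average2", (), (), composite_of=("bg1", "cortical"), description="mean of bg1 and cortical sub-ratios"),
        _f("si_CN_PLIC", ["CN"], ["WM_SL1_posterior"], "caudate / posterior limb of internal capsule"),
        _f("si_PT_PLIC", ["PT"], ["WM_SL1_posterior"], "putamen / posterior limb of internal capsule"),
        _f("si_CN_WMfr1", ["CN"], ["WM_SL1_anterior"], "caudate / frontal periventricular WM"),
        _f("si_PT_WMfr1", ["PT"], ["WM_SL1_anterior"], "putamen / frontal periventricular WM"),
        _f("si_CN_WM2", ["CN"], ["WM_SL2"], "caudate / SL2 deep WM"),
        _f("si_PT_WM2", ["PT"], ["WM_SL2"], "putamen / SL2 deep WM"),
        _f("si_TM_WM2", ["TM"], ["WM_SL2"], "thalamus / SL2 deep WM"),
    ]
}


@dataclass(frozen=True)
class GWRRecord:
    subject_id: str
    formula_id: str
    value: float
    method: str  # measurement table the ratio came from (ROI or DOT)
    flagged: bool = False  # value < 1: unexpected for normal brain


def _region_value(table: RegionHUTable, region: str, formula_id: str) -> float:
    if region in table:
        return table[region]
    if region == "WM_SL1" and "WM_SL1_anterior" in table and "WM_SL1_posterior" in table:
        return (table["WM_SL1_anterior"] + table["WM_SL1_posterior"]) / 2.0
    raise GWRError(f"formula {formula_id!r}: region {region!r} missing from table")


def average_composite(bg1_value: float, cortical_value: float) -> float:
    """The averaging composite: mean of the bg1 and cortical sub-ratios."""
    return (bg1_value + cortical_value) / 2.0


def compute_gwr(table: RegionHUTable, formula_id: str) -> GWRRecord:
    """Evaluate one formula on a subject's measured table."""
    try:
        formula = FORMULAS[formula_id]
    except KeyError:
        raise GWRError(f"unknown formula {formula_id!r}") from None
    if formula.composite_of is not None:
        parts = [compute_gwr(table, fid).value for fid in formula.composite_of]
        value = average_composite(*parts)
    else:
        num = float(np.mean([_region_value(table, r, formula_id) for r in formula.numerator]))
        den = float(np.mean([_region_value(table, r, formula_id) for r in formula.denominator]))
        if den <= 0:
            raise GWRError(f"formula {formula_id!r}: non-positive denominator mean {den}")
        value = num / den
    flagged = value < 1.0
    if flagged:
        warnings.warn(
            f"{table.subject_id}/{formula_id}: GWR {value:.3f} < 1 (unexpected in normal brain)",
            stacklevel=2,
        )
    return GWRRecord(table.subject_id, formula_id, value, table.method, flagged)


def compute_all(table: RegionHUTable) -> list[GWRRecord]:
    """All 12 formulas in registry order; per-formula failures aggregated."""
    records, failures = [], []
    for fid in FORMULAS:
        try:
            records.append(compute_gwr(table, fid))
        except GWRError as exc:
            failures.append(str(exc))
    if failures:
        raise GWRError("; ".join(failures))
    return records


def gwr_frame(records: list[GWRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "formula_id": [r.formula_id for r in records],
            "value": [r.value for r in records],
            "method": [r.method for r in records],
        }
    )


def registry_dump() -> dict:
    """JSON-ready description of every formula's regions."""
    return {
        fid: {
            "numerator": list(f.numerator),
            "denominator": list(f.denominator),
            "composite_of": list(f.composite_of) if f.composite_of else None,
            "description": f.description,
        }
        for fid, f in FORMULAS.items()
    }
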
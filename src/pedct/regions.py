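"""Region registry for the two analysis slices.

Measurements are taken on two axial slices: SL1 at the basal-ganglia level
(third ventricle visible) and SL2 at the supraventricular level (ventricle
bodies first visible from the vertex).  Bilateral structures carry left/right
sublabels in the phantom label maps and are averaged across sides before any
downstream use.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class SliceID(str, Enum):
    SL1 = "SL1"
    SL2 = "SL2"


class Laterality(str, Enum):
    BILATERAL = "bilateral"
    MIDLINE = "midline"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class Region:
    """A named measurement region tied to exactly one slice."""

    name: str
    slice_id: SliceID
    laterality: Laterality
    #: regions measured only by the circular-dot probe
    dot_target: bool = False
    #: regions traced as segmented ROIs
    roi_target: bool = False


def _r(name, sl, lat, dot=False, roi=False):
    return Region(name, sl, lat, dot_target=dot, roi_target=roi)


#: The full registry.  ``WM_SL1`` is a derived region (mean of the anterior
#: and posterior white-matter probe sites) and has no pixels of its own.
REGIONS: dict[str, Region] = {
    r.name: r
    for r in [
        _r("parenchyma_SL1", SliceID.SL1, Laterality.MIDLINE, roi=True),
        _r("parenchyma_SL2", SliceID.SL2, Laterality.MIDLINE, roi=True),
        _r("ventricle_SL1", SliceID.SL1, Laterality.MIDLINE, dot=True, roi=True),
        _r("ventricle_SL2", SliceID.SL2, Laterality.MIDLINE, dot=True, roi=True),
        _r("CN", SliceID.SL1, Laterality.BILATERAL, dot=True, roi=True),
        _r("PT", SliceID.SL1, Laterality.BILATERAL, dot=True, roi=True),
        _r("TM", SliceID.SL1, Laterality.BILATERAL, dot=True, roi=True),
        _r("GM_SL1", SliceID.SL1, Laterality.BILATERAL, dot=True),
        _r("GM_SL2", SliceID.SL2, Laterality.BILATERAL, dot=True),
        _r("WM_SL1", SliceID.SL1, Laterality.BILATERAL),
        _r("WM_SL1_anterior", SliceID.SL1, Laterality.BILATERAL, dot=True),
        _r("WM_SL1_posterior", SliceID.SL1, Laterality.BILATERAL, dot=True),
        _r("WM_SL2", SliceID.SL2, Laterality.BILATERAL, dot=True),
        _r("frontal_SL1", SliceID.SL1, Laterality.BILATERAL, roi=True),
        _r("temporal_SL1", SliceID.SL1, Laterality.BILATERAL, roi=True),
        _r("parietal_SL1", SliceID.SL1, Laterality.BILATERAL, roi=True),
        _r("occipital_SL1", SliceID.SL1, Laterality.BILATERAL, roi=True),
        _r("frontal_SL2", SliceID.SL2, Laterality.BILATERAL, roi=True),
        _r("parietal_SL2", SliceID.SL2, Laterality.BILATERAL, roi=True),
        _r("occipital_SL2", SliceID.SL2, Laterality.BILATERAL, roi=True),
    ]
}

#: Regions whose mean HU is drawn by the cohort generator (everything with
#: its own pixels; excludes the derived WM_SL1).
GENERATIVE_REGIONS: tuple[str, ...] = tuple(
    n for n in REGIONS if n != "WM_SL1"
)

#: ROI-method regions, in the tracing order of the protocol (parenchyma,
#: ventricles, then lobes and deep nuclei).  14 rows.
ROI_REGIONS: tuple[str, ...] = (
    "parenchyma_SL1",
    "parenchyma_SL2",
    "frontal_SL1",
    "temporal_SL1",
    "parietal_SL1",
    "occipital_SL1",
    "frontal_SL2",
    "parietal_SL2",
    "occipital_SL2",
    "CN",
    "PT",
    "TM",
    "ventricle_SL1",
    "ventricle_SL2",
)

#: DOT-method probe targets (per measured site; WM_SL1 is derived later).
DOT_REGIONS: tuple[str, ...] = (
    "CN",
    "PT",
    "TM",
    "GM_SL1",
    "WM_SL1_anterior",
    "WM_SL1_posterior",
    "GM_SL2",
    "WM_SL2",
    "ventricle_SL1",
    "ventricle_SL2",
)

#: DOT summary rows as reported (anterior/posterior WM merged). 9 rows.
DOT_SUMMARY_REGIONS: tuple[str, ...] = (
    "GM_SL1",
    "GM_SL2",
    "WM_SL1",
    "WM_SL2",
    "CN",
    "PT",
    "TM",
    "ventricle_SL1",
    "ventricle_SL2",
)


class RegionError(KeyError):
    """Unknown or unregistered region."""


def get_region(name: str) -> Region:
    try:
        return REGIONS[name]
    except KeyError:
        raise RegionError(f"unknown region {name!r}") from None


def regions_for_slice(slice_id: SliceID | str) -> list[Region]:
    sl = SliceID(slice_id)
    return [r for r in REGIONS.values() if r.slice_id == sl]
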
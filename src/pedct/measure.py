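"""ROI and circular-DOT Hounsfield-unit measurement.

Two measurement protocols are supported on a labelled slice:

* **ROI** — the arithmetic mean of all pixels carrying a region's label
  (the whole-parenchyma ROI uses the union of tissue labels, ventricles
  excluded, emulating bone removal followed by whole-brain delineation).
* **DOT** — the mean within a small circular probe (diameter 2.4-2.8 mm,
  default 2.6 mm) placed wholly inside a structure.  A probe pixel belongs
  to the dot iff its center lies within diameter/2 of the dot center
  (pixel-center-in-circle; row-major, 0-based indices, no partial-volume
  weighting).

Bilateral structures are measured per side and averaged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, hypot

import numpy as np
import pandas as pd

from .phantom import SlicePhantom
from .regions import (
    DOT_REGIONS,
    REGIONS,
    ROI_REGIONS,
    Laterality,
    Side,
    SliceID,
    get_region,
)

DEFAULT_DOT_DIAMETER_MM = 2.6
DOT_DIAMETER_RANGE_MM = (2.4, 2.8)

METHOD_ROI = "ROI"
METHOD_DOT = "DOT"


class MeasurementError(RuntimeError):
    """A region could not be measured (empty label, missing side, ...)."""


class ContaminationError(MeasurementError):
    """A dot overlaps pixels outside its target region (mis-placement)."""


@dataclass(frozen=True)
class DotSpec:
    """A circular probe: center in pixel coordinates, diameter in mm."""

    center: tuple[float, float]  # (row, col), pixel-center grid
    diameter_mm: float
    target_region: str
    side: Side | None = None

    def __post_init__(self):
        lo, hi = DOT_DIAMETER_RANGE_MM
        if not lo <= self.diameter_mm <= hi:
            raise ValueError(f"dot diameter must be in [{lo}, {hi}] mm")
        get_region(self.target_region)


def roi_mean_hu(
    phantom: SlicePhantom, region: str, side: Side | str | None = None
) -> float:
    """Mean HU over all pixels carrying ``region``'s label.

    Bilateral regions: pass ``side`` for a per-side mean, or leave ``None``
    to average the two side means.  The whole-parenchyma region is measured
    over the union of tissue labels.
    """
    reg = get_region(region)
    if region.startswith("parenchyma"):
        mask = phantom.tissue_mask()
        if not mask.any():
            raise MeasurementError(f"empty label for region {region!r}")
        return float(phantom.image[mask].mean())
    if reg.laterality is Laterality.BILATERAL and side is None:
        return bilateral_average(
            roi_mean_hu(phantom, region, Side.LEFT),
            roi_mean_hu(phantom, region, Side.RIGHT),
        )
    mask = phantom.mask(region, side)
    if not mask.any():
        raise MeasurementError(f"empty label for region {region!r} (side={side})")
    return float(phantom.image[mask].mean())


def dot_mask(
    center: tuple[float, float],
    diameter_mm: float,
    pixel_spacing: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices whose centers lie within diameter/2 (mm) of ``center``.

    Deterministic and independent of traversal order.  Raises ``ValueError``
    if the circle extends beyond the image or if no pixel center falls
    inside it (degenerate spacing).
    """
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be > 0")
    radius_px = (diameter_mm / 2.0) / pixel_spacing
    r0, c0 = center
    if (
        r0 - radius_px < -0.5
        or c0 - radius_px < -0.5
        or r0 + radius_px > shape[0] - 0.5
        or c0 + radius_px > shape[1] - 0.5
    ):
        raise ValueError("dot extends outside the image")
    rlo, rhi = ceil(r0 - radius_px), int(np.floor(r0 + radius_px))
    clo, chi = ceil(c0 - radius_px), int(np.floor(c0 + radius_px))
    rr, cc = np.mgrid[rlo : rhi + 1, clo : chi + 1]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    rr, cc = rr[inside], cc[inside]
    if rr.size == 0:
        raise ValueError(
            "no pixel center inside the dot (pixel spacing too coarse for this diameter)"
        )
    return rr, cc


def dot_mean_hu(phantom: SlicePhantom, dot: DotSpec) -> float:
    """Mean HU over the dot's pixels; errors if the dot leaves its target label."""
    rr, cc = dot_mask(dot.center, dot.diameter_mm, phantom.pixel_spacing, phantom.labels.shape)
    codes = phantom.codes_for(dot.target_region, dot.side)
    hit = phantom.labels[rr, cc]
    if not np.isin(hit, codes).all():
        bad = sorted(set(int(v) for v in hit) - set(codes))
        raise ContaminationError(
            f"dot for {dot.target_region!r} (side={dot.side}) overlaps label(s) {bad}"
        )
    return float(phantom.image[rr, cc].mean())


def bilateral_average(left: float, right: float) -> float:
    """Average the two sides of a bilateral structure."""
    if not (np.isfinite(left) and np.isfinite(right)):
        raise MeasurementError("bilateral average requires both sides finite")
    return (left + right) / 2.0


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    rr, cc = np.nonzero(mask)
    return float(rr.mean()), float(cc.mean())


def default_dot_plan(
    phantoms: dict[SliceID, SlicePhantom],
    diameter_mm: float = DEFAULT_DOT_DIAMETER_MM,
) -> list[DotSpec]:
    """One dot per DOT target site, centered on the label centroid."""
    plan: list[DotSpec] = []
    for name in DOT_REGIONS:
        reg = REGIONS[name]
        ph = phantoms[reg.slice_id]
        if reg.laterality is Laterality.BILATERAL:
            for side in (Side.LEFT, Side.RIGHT):
                plan.append(
                    DotSpec(_centroid(ph.mask(name, side)), diameter_mm, name, side)
                )
        else:
            plan.append(DotSpec(_centroid(ph.mask(name)), diameter_mm, name))
    return plan


@dataclass
class RegionHUTable:
    """Per-subject measured HU per region for one method, sides averaged."""

    subject_id: str
    method: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in (METHOD_ROI, METHOD_DOT):
            raise ValueError("method must be 'ROI' or 'DOT'")
        for region, hu in self.values.items():
            get_region(region)
            if not np.isfinite(hu):
                raise ValueError(f"non-finite HU for region {region!r}")

    def __getitem__(self, region: str) -> float:
        return self.values[region]

    def __contains__(self, region: str) -> bool:
        return region in self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "method": self.method,
                "region": list(self.values),
                "hu": list(self.values.values()),
            }
        )


def measure_subject(
    phantoms: dict[SliceID, SlicePhantom],
    method: str,
    dot_plan: list[DotSpec] | None = None,
) -> RegionHUTable:
    """Measure every region of a subject's two slices with one method.

    DOT tables additionally carry the derived ``WM_SL1`` entry (mean of the
    anterior and posterior probe sites), the value generic formulas use.
    Missing/failed regions are reported in a single aggregated error.
    """
    if SliceID.SL1 not in phantoms or SliceID.SL2 not in phantoms:
        raise MeasurementError("both SL1 and SL2 phantoms are required")
    subject_id = phantoms[SliceID.SL1].subject_id or "unknown"
    values: dict[str, float] = {}
    failures: list[str] = []

    if method == METHOD_ROI:
        for name in ROI_REGIONS:
            try:
                values[name] = roi_mean_hu(phantoms[REGIONS[name].slice_id], name)
            except (MeasurementError, KeyError) as exc:
                failures.append(f"{name}: {exc}")
    elif method == METHOD_DOT:
        plan = dot_plan if dot_plan is not None else default_dot_plan(phantoms)
        per_site: dict[tuple[str, Side | None], float] = {}
        for dot in plan:
            ph = phantoms[REGIONS[dot.target_region].slice_id]
            try:
                per_site[(dot.target_region, dot.side)] = dot_mean_hu(ph, dot)
            except (MeasurementError, ValueError) as exc:
                failures.append(f"{dot.target_region}: {exc}")
        for name in DOT_REGIONS:
            reg = REGIONS[name]
            try:
                if reg.laterality is Laterality.BILATERAL:
                    values[name] = bilateral_average(
                        per_site[(name, Side.LEFT)], per_site[(name, Side.RIGHT)]
                    )
                else:
                    values[name] = per_site[(name, None)]
            except KeyError:
                failures.append(f"{name}: no dot measurement")
        if "WM_SL1_anterior" in values and "WM_SL1_posterior" in values:
            values["WM_SL1"] = bilateral_average(
                values["WM_SL1_anterior"], values["WM_SL1_posterior"]
            )
    else:
        raise ValueError("method must be 'ROI' or 'DOT'")

    if failures:
        raise MeasurementError(
            f"{len(failures)} region(s) could not be measured: " + "; ".join(failures)
        )
    return RegionHUTable(subject_id=subject_id, method=method, values=values)
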
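"""Schematic 2D slice phantoms.

Each phantom is a HU image plus a co-registered integer label map on an
isotropic pixel grid.  The geometry is deliberately schematic — an elliptical
brain ("parenchyma") with elliptical sub-patches for ventricles, deep nuclei,
white-matter probe sites, cortical gray patches and lobar ROIs, mirrored
about the midline for bilateral structures.  The downstream arithmetic is
geometry-agnostic; what matters is that every region has a clean label and a
known generating mean.

The whole-parenchyma ROI is measured over the union of all tissue labels
(everything except background and ventricle).  So that a noiseless phantom
round-trips exactly, the generic "filler" tissue value is solved such that
the area-weighted union mean equals the subject's parenchyma true mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as _ellipse

from .cohort import SubjectRecord
from .regions import REGIONS, Laterality, Side, SliceID

DEFAULT_GRID = 256
DEFAULT_PIXEL_SPACING_MM = 0.5

#: label code of generic parenchymal tissue not assigned to a sub-region
FILLER_CODE = 1


class GeometryError(ValueError):
    """Phantom geometry violates containment or disjointness."""


# Canonical patch layout on a 256x256 grid: region -> (center_row,
# |col offset from midline| (0 = midline), row_radius, col_radius).
# Anterior structures are at low row indices.  Bilateral patches are
# mirrored about the midline column 127.5.
_BRAIN = (127.5, 0.0, 112.0, 92.0)

_LAYOUT: dict[SliceID, dict[str, tuple[float, float, float, float]]] = {
    SliceID.SL1: {
        "ventricle_SL1": (127.5, 0.0, 20.0, 5.0),
        "GM_SL1": (45.0, 28.0, 10.0, 12.0),
        "frontal_SL1": (70.0, 45.0, 12.0, 16.0),
        "WM_SL1_anterior": (88.0, 14.0, 8.0, 7.0),
        "CN": (106.0, 20.0, 9.0, 6.0),
        "PT": (127.5, 38.0, 9.0, 6.0),
        "temporal_SL1": (127.5, 70.0, 14.0, 12.0),
        "WM_SL1_posterior": (148.0, 20.0, 7.0, 6.0),
        "TM": (170.0, 16.0, 11.0, 9.0),
        "parietal_SL1": (172.0, 52.0, 14.0, 14.0),
        "occipital_SL1": (212.0, 22.0, 10.0, 14.0),
    },
    SliceID.SL2: {
        "ventricle_SL2": (127.5, 0.0, 24.0, 6.0),
        "GM_SL2": (50.0, 26.0, 10.0, 12.0),
        "frontal_SL2": (80.0, 48.0, 14.0, 16.0),
        "WM_SL2": (100.0, 18.0, 9.0, 8.0),
        "parietal_SL2": (160.0, 55.0, 16.0, 15.0),
        "occipital_SL2": (210.0, 24.0, 11.0, 15.0),
    },
}


def label_scheme(slice_id: SliceID | str) -> dict[str, int | tuple[int, int]]:
    """Region -> label code (midline) or (left, right) codes (bilateral).

    Code 0 is background (bone-stripped), 1 the parenchymal filler tissue.
    Codes are deterministic: layout order, bilateral pairs consecutive.
    """
    sl = SliceID(slice_id)
    scheme: dict[str, int | tuple[int, int]] = {"parenchyma_" + sl.value: FILLER_CODE}
    code = 2
    for name in _LAYOUT[sl]:
        if REGIONS[name].laterality is Laterality.BILATERAL:
            scheme[name] = (code, code + 1)
            code += 2
        else:
            scheme[name] = code
            code += 1
    return scheme


@dataclass
class SlicePhantom:
    """A 2D HU image with a co-registered label map for one slice."""

    slice_id: SliceID
    image: np.ndarray
    labels: np.ndarray
    pixel_spacing: float  # mm, isotropic
    label_map: dict[str, int | tuple[int, int]] = field(default_factory=dict)
    subject_id: str | None = None

    def __post_init__(self):
        self.slice_id = SliceID(self.slice_id)
        if self.image.shape != self.labels.shape:
            raise GeometryError("image and labels must have identical shape")
        if self.pixel_spacing <= 0:
            raise GeometryError("pixel_spacing must be > 0")
        if not self.label_map:
            self.label_map = label_scheme(self.slice_id)

    def codes_for(self, region: str, side: Side | str | None = None) -> tuple[int, ...]:
        """Label code(s) selecting ``region`` (optionally one side)."""
        entry = self.label_map[region]
        if isinstance(entry, tuple):
            if side is None:
                return entry
            return (entry[0] if Side(side) is Side.LEFT else entry[1],)
        if side is not None:
            raise GeometryError(f"{region} is a midline region; no sides")
        return (entry,)

    def mask(self, region: str, side: Side | str | None = None) -> np.ndarray:
        return np.isin(self.labels, self.codes_for(region, side))

    def tissue_mask(self) -> np.ndarray:
        """All brain-tissue pixels: labelled, and not ventricle."""
        vent = "ventricle_" + self.slice_id.value
        out = self.labels > 0
        if vent in self.label_map:
            out &= ~self.mask(vent)
        return out


def _patch(center_r, center_c, r_rad, c_rad, scale, shape):
    rr, cc = _ellipse(center_r * scale, center_c * scale, r_rad * scale, c_rad * scale, shape=shape)
    return rr, cc


def render_phantom(
    subject: SubjectRecord,
    slice_id: SliceID | str,
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM,
    noise_sd_voxel: float = 3.0,
    seed: int | None = None,
    grid: int = DEFAULT_GRID,
) -> SlicePhantom:
    """Render one subject's slice phantom.

    Every labelled patch is filled with the subject's true regional mean; the
    filler value is solved so the tissue-union mean equals the parenchyma
    true mean; i.i.d. Gaussian voxel noise (SD ``noise_sd_voxel`` HU) is then
    added to all labelled pixels.  Background (bone-stripped) stays 0.
    """
    sl = SliceID(slice_id)
    if pixel_spacing <= 0:
        raise GeometryError("pixel_spacing must be > 0")
    if grid < 64:
        raise GeometryError("grid too small for the canonical layout")
    scale = grid / DEFAULT_GRID
    shape = (grid, grid)
    mid = (grid - 1) / 2.0

    labels = np.zeros(shape, dtype=np.int16)
    br, bc = _patch(*_unpack_midline(_BRAIN), scale, shape)
    labels[br, bc] = FILLER_CODE

    scheme = label_scheme(sl)
    for name, (cr, off, rrad, crad) in _LAYOUT[sl].items():
        entry = scheme[name]
        if isinstance(entry, tuple):
            centers = [(cr, 127.5 - off, entry[0]), (cr, 127.5 + off, entry[1])]
        else:
            centers = [(cr, 127.5, entry)]
        for pr, pc, code in centers:
            rr, cc = _patch(pr, pc, rrad, crad, scale, shape)
            if rr.size == 0:
                raise GeometryError(f"{name}: empty patch at this grid size")
            if np.any(labels[rr, cc] != FILLER_CODE):
                raise GeometryError(f"{name}: patch leaves brain or overlaps another patch")
            labels[rr, cc] = code

    # fill HU values
    image = np.zeros(shape, dtype=np.float64)
    means = subject.true_region_mean
    sub_sum = 0.0
    sub_n = 0
    for name in _LAYOUT[sl]:
        entry = scheme[name]
        codes = entry if isinstance(entry, tuple) else (entry,)
        for code in codes:
            m = labels == code
            image[m] = means[name]
            if name != "ventricle_" + sl.value:
                sub_sum += means[name] * int(m.sum())
                sub_n += int(m.sum())

    parenchyma_mean = means["parenchyma_" + sl.value]
    filler = labels == FILLER_CODE
    n_filler = int(filler.sum())
    n_tissue = sub_n + n_filler
    # solve filler HU so mean over the tissue union equals the parenchyma mean
    image[filler] = (parenchyma_mean * n_tissue - sub_sum) / n_filler

    if noise_sd_voxel:
        rng = np.random.default_rng(seed)
        lab = labels > 0
        image[lab] += rng.normal(0.0, noise_sd_voxel, size=int(lab.sum()))

    return SlicePhantom(
        slice_id=sl,
        image=image,
        labels=labels,
        pixel_spacing=pixel_spacing,
        label_map=scheme,
        subject_id=subject.subject_id,
    )


def _unpack_midline(spec):
    cr, off, rrad, crad = spec
    return cr, 127.5 + off, rrad, crad


def render_subject(
    subject: SubjectRecord,
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM,
    noise_sd_voxel: float = 3.0,
    seed: int | None = None,
    grid: int = DEFAULT_GRID,
) -> dict[SliceID, SlicePhantom]:
    """Render both analysis slices for one subject (independent noise)."""
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    return {
        SliceID.SL1: render_phantom(subject, SliceID.SL1, pixel_spacing, noise_sd_voxel, s1, grid),
        SliceID.SL2: render_phantom(subject, SliceID.SL2, pixel_spacing, noise_sd_voxel, s2, grid),
    }
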
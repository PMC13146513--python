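"""Phantom rendering and ROI/DOT measurement: round-trips, masks, oracles."""
import numpy as np
import pytest

from pedct import (
    CohortConfig,
    DotSpec,
    bilateral_average,
    dot_mask,
    dot_mean_hu,
    measure_subject,
    render_phantom,
    render_subject,
    roi_mean_hu,
    sample_cohort,
)
from pedct.measure import ContaminationError, MeasurementError, default_dot_plan
from pedct.phantom import GeometryError, SlicePhantom, label_scheme
from pedct.regions import DOT_REGIONS, REGIONS, ROI_REGIONS, Laterality, Side, SliceID


# ---------------------------------------------------------------- phantoms
def test_noiseless_round_trip_all_regions(noiseless_subject, noiseless_phantoms, noiseless_tables):
    """Generator -> measurement recovers every true regional mean exactly."""
    for method in ("ROI", "DOT"):
        table = noiseless_tables[method]
        for region, hu in table.values.items():
            if region == "WM_SL1":  # derived from the two probe sites
                expected = bilateral_average(
                    noiseless_subject.true_region_mean["WM_SL1_anterior"],
                    noiseless_subject.true_region_mean["WM_SL1_posterior"],
                )
            else:
                expected = noiseless_subject.true_region_mean[region]
            assert hu == pytest.approx(expected, abs=1e-9), (method, region)


def test_label_masks_disjoint_and_inside_brain(noiseless_phantoms):
    for ph in noiseless_phantoms.values():
        seen = np.zeros_like(ph.labels, dtype=bool)
        for region in ph.label_map:
            if region.startswith("parenchyma"):
                continue
            m = ph.mask(region)
            assert m.any(), region
            assert not (m & seen).any(), f"{region} overlaps another patch"
            seen |= m
        # every sub-patch lies inside the labelled brain
        assert ((ph.labels > 0) | ~seen).all()


def test_bilateral_patches_have_both_sides(noiseless_phantoms):
    for ph in noiseless_phantoms.values():
        for region, entry in ph.label_map.items():
            if REGIONS[region].laterality is Laterality.BILATERAL:
                assert ph.mask(region, Side.LEFT).sum() >= 1
                assert ph.mask(region, Side.RIGHT).sum() >= 1


def test_slice_label_sets():
    sl1 = set(label_scheme(SliceID.SL1))
    assert {"CN", "PT", "TM", "ventricle_SL1", "GM_SL1", "WM_SL1_anterior", "WM_SL1_posterior"} <= sl1
    sl2 = set(label_scheme(SliceID.SL2))
    assert {"GM_SL2", "WM_SL2", "ventricle_SL2"} <= sl2


def test_render_rejects_bad_spacing(noiseless_subject):
    with pytest.raises(GeometryError):
        render_phantom(noiseless_subject, SliceID.SL1, pixel_spacing=0.0, noise_sd_voxel=0.0)


def test_render_deterministic(noiseless_subject):
    a = render_phantom(noiseless_subject, SliceID.SL1, noise_sd_voxel=3.0, seed=9)
    b = render_phantom(noiseless_subject, SliceID.SL1, noise_sd_voxel=3.0, seed=9)
    assert np.array_equal(a.image, b.image)


# ---------------------------------------------------------------- ROI means
def test_roi_mean_matches_double_loop_oracle(noiseless_subject):
    ph = render_phantom(noiseless_subject, SliceID.SL1, noise_sd_voxel=2.0, seed=3, grid=64)
    for region in ("CN", "TM"):
        for side in (Side.LEFT, Side.RIGHT):
            total, count = 0.0, 0
            codes = ph.codes_for(region, side)
            for r in range(ph.labels.shape[0]):
                for c in range(ph.labels.shape[1]):
                    if ph.labels[r, c] in codes:
                        total += ph.image[r, c]
                        count += 1
            assert roi_mean_hu(ph, region, side) == pytest.approx(total / count)


def test_roi_mean_of_uniform_image():
    labels = np.zeros((32, 32), dtype=np.int16)
    scheme = label_scheme(SliceID.SL1)
    labels[10:20, 10:20] = scheme["CN"][0]
    labels[10:20, 21:31] = scheme["CN"][1]
    ph = SlicePhantom(SliceID.SL1, np.full((32, 32), 30.0), labels, 0.5)
    assert roi_mean_hu(ph, "CN") == 30.0


def test_roi_two_pixel_hand_mean():
    labels = np.zeros((8, 8), dtype=np.int16)
    code = label_scheme(SliceID.SL1)["ventricle_SL1"]
    labels[2, 2] = code
    labels[2, 3] = code
    image = np.zeros((8, 8))
    image[2, 2], image[2, 3] = 29.0, 31.0
    ph = SlicePhantom(SliceID.SL1, image, labels, 0.5)
    assert roi_mean_hu(ph, "ventricle_SL1") == 30.0


def test_roi_empty_label_errors(noiseless_phantoms):
    ph = noiseless_phantoms[SliceID.SL1]
    blank = SlicePhantom(SliceID.SL1, ph.image.copy(), np.zeros_like(ph.labels), 0.5)
    with pytest.raises(MeasurementError, match="CN"):
        roi_mean_hu(blank, "CN")


# ---------------------------------------------------------------- dot masks
@pytest.mark.parametrize("diameter,spacing,center", [
    (2.4, 0.5, (32.0, 32.0)),
    (2.8, 0.5, (31.6, 32.3)),
    (2.6, 0.25, (60.0, 60.5)),
])
def test_dot_mask_matches_exhaustive_enumeration(diameter, spacing, center):
    shape = (128, 128)
    rr, cc = dot_mask(center, diameter, spacing, shape)
    got = set(zip(rr.tolist(), cc.tolist()))
    radius_mm = diameter / 2.0
    expected = {
        (r, c)
        for r in range(shape[0])
        for c in range(shape[1])
        if spacing * np.hypot(r - center[0], c - center[1]) <= radius_mm
    }
    assert got == expected and got


def test_dot_mask_contains_center_pixel():
    rr, cc = dot_mask((10.0, 10.0), 2.4, 2.0, (32, 32))
    assert (10, 10) in set(zip(rr.tolist(), cc.tolist()))


def test_dot_mask_degenerate_spacing_errors():
    # spacing coarser than the dot and center between pixel centers
    with pytest.raises(ValueError, match="no pixel center"):
        dot_mask((10.5, 10.5), 2.4, 2.8, (32, 32))


def test_dot_mask_outside_image_errors():
    with pytest.raises(ValueError, match="outside"):
        dot_mask((0.0, 0.0), 2.8, 0.5, (64, 64))


def test_dot_diameter_range_enforced():
    with pytest.raises(ValueError):
        DotSpec((10.0, 10.0), 3.5, "CN", Side.LEFT)


# ---------------------------------------------------------------- dot means
def test_dot_mean_in_uniform_region():
    labels = np.zeros((64, 64), dtype=np.int16)
    scheme = label_scheme(SliceID.SL1)
    code_l, code_r = scheme["PT"]
    labels[20:40, 10:30] = code_l
    labels[20:40, 34:54] = code_r
    image = np.where(labels > 0, 24.0, 0.0)
    ph = SlicePhantom(SliceID.SL1, image, labels, 0.5)
    dot = DotSpec((30.0, 20.0), 2.6, "PT", Side.LEFT)
    assert dot_mean_hu(ph, dot) == 24.0


def test_dot_equals_roi_on_noiseless_phantom(noiseless_phantoms):
    ph = noiseless_phantoms[SliceID.SL1]
    for dot in default_dot_plan(noiseless_phantoms):
        if dot.target_region in ("CN", "PT", "TM") and REGIONS[dot.target_region].slice_id == SliceID.SL1:
            assert dot_mean_hu(ph, dot) == pytest.approx(
                roi_mean_hu(ph, dot.target_region, dot.side), abs=1e-9
            )


def test_dot_contamination_error(noiseless_phantoms):
    ph = noiseless_phantoms[SliceID.SL1]
    # a dot centered on the midline ventricle but targeting CN must fail
    rr, cc = np.nonzero(ph.mask("ventricle_SL1"))
    bad = DotSpec((float(rr.mean()), float(cc.mean())), 2.6, "CN", Side.LEFT)
    with pytest.raises(ContaminationError):
        dot_mean_hu(ph, bad)


def test_dot_vs_roi_bias_near_zero_across_noisy_subjects():
    """Monte-Carlo: DOT - ROI differences center on zero for deep nuclei."""
    subs = sample_cohort(CohortConfig(n_young=4, n_old=4, seed=21))
    diffs = []
    for i, s in enumerate(subs):
        phantoms = render_subject(s, noise_sd_voxel=3.0, seed=100 + i)
        t_roi = measure_subject(phantoms, "ROI")
        t_dot = measure_subject(phantoms, "DOT")
        for region in ("CN", "PT", "TM"):
            diffs.append(t_dot[region] - t_roi[region])
    assert abs(np.mean(diffs)) < 1.0  # small relative to the 3-HU voxel noise


# ---------------------------------------------------------------- assembly
def test_bilateral_average_examples():
    assert bilateral_average(30.0, 32.0) == 31.0
    assert bilateral_average(5.5, 5.5) == 5.5
    assert bilateral_average(29.3, 30.1) == pytest.approx(29.7)
    with pytest.raises(MeasurementError):
        bilateral_average(30.0, float("nan"))


def test_measured_region_sets(noiseless_tables):
    assert set(noiseless_tables["ROI"].values) == set(ROI_REGIONS)
    assert set(noiseless_tables["DOT"].values) == set(DOT_REGIONS) | {"WM_SL1"}


def test_measure_requires_both_slices(noiseless_phantoms):
    with pytest.raises(MeasurementError, match="SL2"):
        measure_subject({SliceID.SL1: noiseless_phantoms[SliceID.SL1]}, "ROI")
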
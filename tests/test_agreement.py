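"""Bland-Altman and intraclass-correlation agreement statistics."""
import numpy as np
import pytest

from pedct import (
    CohortConfig,
    PairedMeasurements,
    bland_altman,
    icc_single_rater,
    loa_from_summary,
    measure_subject,
    render_subject,
    sample_cohort,
    simulate_rereads,
)
from pedct.agreement import AgreementError


def _pairs(a, b, region="CN"):
    ids = tuple(f"S{i:03d}" for i in range(len(a)))
    return PairedMeasurements(region, ids, np.asarray(a, float), np.asarray(b, float))


# ------------------------------------------------------------ Bland-Altman
def test_hand_computed_example():
    res = bland_altman(_pairs([10, 20, 30], [11, 19, 33]))
    assert res.bias == pytest.approx(1.0)
    assert res.sd_diff == pytest.approx(2.0)
    assert res.loa_lower == pytest.approx(-2.92)
    assert res.loa_upper == pytest.approx(4.92)
    assert res.diff_range == (-1.0, 3.0)


def test_perfect_agreement():
    res = bland_altman(_pairs([10, 20, 30], [10, 20, 30]))
    assert res.bias == 0 and res.sd_diff == 0
    assert res.loa_lower == 0 and res.loa_upper == 0


def test_matches_naive_two_pass_oracle():
    rng = np.random.default_rng(5)
    for n in range(2, 11):
        a, b = rng.normal(30, 2, n), rng.normal(29, 2, n)
        res = bland_altman(_pairs(a, b))
        diffs = [bi - ai for ai, bi in zip(a, b)]
        mean = sum(diffs) / n
        sd = (sum((d - mean) ** 2 for d in diffs) / (n - 1)) ** 0.5
        assert res.bias == pytest.approx(mean)
        assert res.sd_diff == pytest.approx(sd)
        assert res.loa_upper == pytest.approx(mean + 1.96 * sd)


def test_sign_convention_dot_minus_roi():
    a = np.array([10.0, 20.0, 30.0])
    base = bland_altman(_pairs(a, a + 1.0))
    shifted = bland_altman(_pairs(a, a + 1.0 + 2.5))
    assert shifted.bias == pytest.approx(base.bias + 2.5)


def test_insufficient_pairs_rejected():
    with pytest.raises(AgreementError):
        _pairs([10.0], [11.0])


@pytest.mark.parametrize(
    "bias, sd, which, expected",
    [
        (-1.39, 1.27, 0, -3.88),  # putamen, lower limit
        (-0.76, 1.37, 1, 1.93),  # thalamus, upper limit
        (7.98, 2.98, 0, 2.14),  # ventricle SL1, lower limit
        (4.85, 2.87, 0, -0.78),  # ventricle SL2, lower limit
        (0.0, 1.0, 0, -1.96),
        (0.0, 1.0, 1, 1.96),
    ],
)
def test_loa_reconstruction_from_reported_summaries(bias, sd, which, expected):
    assert round(loa_from_summary(bias, sd)[which], 2) == expected


def test_loa_negative_sd_rejected():
    with pytest.raises(ValueError):
        loa_from_summary(0.0, -1.0)


# ----------------------------------------------------------------- ICC
def _icc2_anova_oracle(mat):
    """ICC(2,1) from two-way ANOVA mean squares, computed by hand."""
    mat = np.asarray(mat, float)
    n, k = mat.shape
    grand = mat.mean()
    row_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((mat - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_identical_columns_is_one():
    mat = np.array([[1.0, 1.0], [3.0, 3.0], [5.0, 5.0]])
    assert icc_single_rater(mat) == pytest.approx(1.0)


def test_icc_matches_anova_mean_squares_oracle():
    mats = [
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        np.array([[9.0, 2.0], [6.0, 1.0], [8.0, 4.0], [7.0, 1.0], [10.0, 5.0]]),
        np.random.default_rng(8).normal(30, 3, (12, 3)),
    ]
    for mat in mats:
        assert icc_single_rater(mat) == pytest.approx(_icc2_anova_oracle(mat), abs=1e-9)


def test_icc_invariance_under_affine_rescaling():
    rng = np.random.default_rng(3)
    mat = rng.normal(25, 4, (10, 2))
    base = icc_single_rater(mat)
    assert icc_single_rater(mat + 100.0) == pytest.approx(base, abs=1e-9)
    assert icc_single_rater(mat * 3.0) == pytest.approx(base, abs=1e-9)


def test_icc_rejects_incomplete_matrix():
    mat = np.array([[1.0, 2.0], [3.0, np.nan]])
    with pytest.raises(AgreementError):
        icc_single_rater(mat)


# ------------------------------------------------------------- re-reads
@pytest.fixture(scope="module")
def small_dot_tables():
    subs = sample_cohort(CohortConfig(n_young=3, n_old=3, seed=17))
    tables = []
    for i, s in enumerate(subs):
        tables.append(measure_subject(render_subject(s, seed=50 + i), "DOT"))
    return tables


def test_reread_selection_count():
    """10% of the default 42-subject cohort selects 5 subjects (ceiling)."""
    from pedct.measure import RegionHUTable
    from pedct.regions import DOT_REGIONS

    subs = sample_cohort(CohortConfig(seed=19))
    tables = []
    for s in subs:
        values = {r: s.true_region_mean[r] for r in DOT_REGIONS}
        values["WM_SL1"] = (values["WM_SL1_anterior"] + values["WM_SL1_posterior"]) / 2
        tables.append(RegionHUTable(subject_id=s.subject_id, method="DOT", values=values))
    _, ids = simulate_rereads(tables, fraction=0.1, seed=6)
    assert len(ids) == 5
    assert len(set(ids)) == 5


def test_reread_same_seed_same_matrix(small_dot_tables):
    m1, ids1 = simulate_rereads(small_dot_tables, fraction=0.5, seed=4)
    m2, ids2 = simulate_rereads(small_dot_tables, fraction=0.5, seed=4)
    assert ids1 == ids2
    assert np.array_equal(m1, m2)


def test_reread_zero_noise_gives_icc_one(small_dot_tables):
    mat, _ = simulate_rereads(small_dot_tables, fraction=1.0, reread_noise_sd=0.0, seed=1)
    assert np.array_equal(mat[:, 0], mat[:, 1])
    assert icc_single_rater(mat) == pytest.approx(1.0)


def test_reread_small_noise_gives_high_icc(small_dot_tables):
    """Re-read noise well below the between-region spread keeps ICC >= 0.9."""
    mat, ids = simulate_rereads(small_dot_tables, fraction=1.0, reread_noise_sd=0.5, seed=2)
    assert len(ids) == 6
    assert icc_single_rater(mat) >= 0.9


def test_reread_fraction_validated(small_dot_tables):
    with pytest.raises(AgreementError):
        simulate_rereads(small_dot_tables, fraction=0.0, seed=1)
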
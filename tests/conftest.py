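import pytest

from pedct import CohortConfig, measure_subject, render_subject, sample_cohort


@pytest.fixture(scope="session")
def noiseless_subject():
    cfg = CohortConfig(noise_sd_between=0.0, noise_sd_voxel=0.0, seed=7)
    return sample_cohort(cfg)[0]


@pytest.fixture(scope="session")
def noiseless_phantoms(noiseless_subject):
    return render_subject(noiseless_subject, noise_sd_voxel=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_tables(noiseless_phantoms):
    return {
        "ROI": measure_subject(noiseless_phantoms, "ROI"),
        "DOT": measure_subject(noiseless_phantoms, "DOT"),
    }


@pytest.fixture(scope="session")
def default_cohort():
    return sample_cohort(CohortConfig(seed=11))
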
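"""Synthetic cohort sampling.

Emulates a normal-control cohort of pediatric head CTs: a young stratum
(< 24 months) and an old stratum (>= 24 months, up to 18 years), with ages
drawn log-uniformly within each stratum to reproduce the strong right skew
of clinically acquired normal scans (infants are heavily over-represented
because normal CTs are rarely obtained in older children).  Each subject
carries a "true" mean HU per region: the regional age curve evaluated at the
subject's age plus an independent Gaussian between-subject deviation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import regional_mean_curve
from .regions import GENERATIVE_REGIONS

#: Age boundary between the strata, months (2 years).
AGE_BOUNDARY_MONTHS = 24.0

GROUP_YOUNG = "young"
GROUP_OLD = "old"


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_young: int = 18
    n_old: int = 24
    age_range_young: tuple[float, float] = (1.0, 24.0)
    age_range_old: tuple[float, float] = (24.0, 216.0)
    noise_sd_between: float = 1.0  # HU, between-subject SD of regional means
    noise_sd_voxel: float = 3.0  # HU, voxel noise in rendered phantoms
    seed: int = 0

    def __post_init__(self):
        if self.n_young < 0 or self.n_old < 0:
            raise ValueError("stratum sizes must be >= 0")
        for lo, hi in (self.age_range_young, self.age_range_old):
            if not (0 < lo < hi):
                raise ValueError("age ranges must be positive and increasing")
        if self.age_range_young[1] > AGE_BOUNDARY_MONTHS:
            raise ValueError("young age range must end at or below 24 months")
        if self.age_range_old[0] < AGE_BOUNDARY_MONTHS:
            raise ValueError("old age range must start at or above 24 months")
        if self.noise_sd_between < 0 or self.noise_sd_voxel < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic subject: age, stratum and per-region true mean HU."""

    subject_id: str
    age_months: float
    group: str
    true_region_mean: dict[str, float] = field(repr=False)

    def __post_init__(self):
        if self.age_months <= 0:
            raise ValueError("age_months must be > 0")
        expected = GROUP_YOUNG if self.age_months < AGE_BOUNDARY_MONTHS else GROUP_OLD
        if self.group != expected:
            raise ValueError(
                f"group {self.group!r} inconsistent with age {self.age_months} months"
            )
        missing = set(GENERATIVE_REGIONS) - set(self.true_region_mean)
        if missing:
            raise ValueError(f"missing true means for regions: {sorted(missing)}")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def sample_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw a seeded cohort; identical config (incl. seed) -> identical cohort.

    Subjects are ordered youngest-first within young then old strata by draw
    order; ids are ``S001`` onward.
    """
    rng = np.random.default_rng(config.seed)
    ages_young = _log_uniform(rng, *config.age_range_young, config.n_young)
    # keep strictly below the boundary (log-uniform can hit the upper edge)
    ages_young = np.minimum(ages_young, np.nextafter(AGE_BOUNDARY_MONTHS, 0.0))
    ages_old = _log_uniform(rng, *config.age_range_old, config.n_old)

    subjects: list[SubjectRecord] = []
    all_ages = np.concatenate([ages_young, ages_old])
    groups = [GROUP_YOUNG] * config.n_young + [GROUP_OLD] * config.n_old
    for i, (age, group) in enumerate(zip(all_ages, groups), start=1):
        means = {}
        for region in GENERATIVE_REGIONS:
            dev = rng.normal(0.0, config.noise_sd_between) if config.noise_sd_between else 0.0
            means[region] = regional_mean_curve(region, float(age)) + dev
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i:03d}",
                age_months=float(age),
                group=group,
                true_region_mean=means,
            )
        )
    return subjects


def cohort_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Tidy subject table (``subject_id, age_months, group``)."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age_months": [s.age_months for s in subjects],
            "group": [s.group for s in subjects],
        }
    )


def true_mean_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Long-format table of the generating true means (one row per region)."""
    rows = [
        {"subject_id": s.subject_id, "region": r, "hu": m}
        for s in subjects
        for r, m in s.true_region_mean.items()
    ]
    return pd.DataFrame(rows)
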
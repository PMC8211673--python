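import numpy as np
import pytest

from gutdrift.core import (
    CompositionProfile,
    LongitudinalCohort,
    SampleRecord,
    SubjectCovariates,
)

FAMILIES = ("Ruminococcaceae", "Bacteroidaceae", "Bifidobacteriaceae")


def make_profile(values, families=FAMILIES):
    return CompositionProfile(families, np.asarray(values, dtype=float))


def make_cohort(rows, covariates=None):
    """rows: iterable of (subject_id, year_index, abundances)."""
    samples = [
        SampleRecord(
            sample_id=f"{subject}.y{year}",
            subject_id=subject,
            year_index=year,
            profile=make_profile(values),
        )
        for subject, year, values in rows
    ]
    return LongitudinalCohort(samples, covariates)


@pytest.fixture
def tiny_cohort():
    """3 subjects over 2 waves; subject c drifts a lot, a barely moves."""
    return make_cohort(
        [
            ("a", 1, (0.6, 0.3, 0.1)),
            ("a", 2, (0.58, 0.32, 0.1)),
            ("b", 1, (0.2, 0.5, 0.3)),
            ("b", 2, (0.25, 0.45, 0.3)),
            ("c", 1, (0.7, 0.2, 0.1)),
            ("c", 2, (0.05, 0.15, 0.8)),
        ],
        covariates={
            "a": SubjectCovariates(age=70, sex="female", bmi=22.0, smoker=False,
                                   alcohol=False,
                                   lcs_intake_days_per_week={"10y": 5.0}),
            "b": SubjectCovariates(age=75, sex="male", bmi=24.0, smoker=True,
                                   alcohol=True,
                                   lcs_intake_days_per_week={"10y": 1.0}),
            "c": SubjectCovariates(age=80, sex="male", bmi=21.0, smoker=False,
                                   alcohol=True,
                                   lcs_intake_days_per_week={"10y": 0.0}),
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_profiles(rng, n, d=6):
    """n random simplex points, some with structural zeros."""
    raw = rng.dirichlet(np.full(d, 0.5), size=n)
    return raw / raw.sum(axis=1, keepdims=True)
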
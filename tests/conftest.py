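import numpy as np
import pytest

from icdpred import (
    Cohort,
    CohortConfig,
    MedicationInterval,
    Standardizer,
    SubjectRecord,
    Visit,
    baseline_means,
    build_observations,
    generate_cohort,
    impute,
)


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = generate_cohort(CohortConfig(n_subjects=60, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def small_obs(small_cohort):
    cohort, _ = small_cohort
    return build_observations(impute(cohort, baseline_means(cohort)))


@pytest.fixture(scope="session")
def std_obs(small_obs):
    return Standardizer().fit_transform(small_obs)


def make_visit(time, icd=0, on_da=0, dose=0.0, **scales):
    defaults = dict(anxiety=5.0, depression=3.0, rem=2.0, updrs3=20.0)
    defaults.update(scales)
    return Visit(
        time_years=time,
        icd=icd,
        on_dopamine_agonist=on_da,
        da_daily_dose=dose,
        **defaults,
    )


def make_subject(subject_id="X1", visit_specs=((0.0, 0), (1.0, 0)),
                 medication=(), n_snps=2, sex=1, age=60.0):
    visits = [make_visit(t, icd) for t, icd in visit_specs]
    return SubjectRecord(
        subject_id=subject_id,
        age_baseline=age,
        sex=sex,
        genotype=np.zeros(n_snps) + 1.0,
        visits=visits,
        medication=list(medication),
    )


@pytest.fixture
def tiny_cohort():
    """Three hand-built subjects with 2-4 visits each."""
    s1 = make_subject("X1", ((0.0, 0), (1.0, 0), (2.0, 1)))
    s2 = make_subject(
        "X2",
        ((0.0, 0), (0.9, 1)),
        medication=[MedicationInterval("dopamine_agonist", 0.0, 0.9, 100.0)],
    )
    s3 = make_subject("X3", ((0.0, 1), (1.1, 1), (2.0, 1), (3.2, 0)))
    return Cohort([s1, s2, s3])
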
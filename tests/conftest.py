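import pytest

from platedesign import Cohort, CovariateSpec, Sample, generate_case_study_cohort


def make_cohort(counts_by_covariate: dict[str, dict[str, int]]) -> Cohort:
    """Build a cohort with given per-covariate category counts.

    Covariate columns are generated independently (repeat-then-zip), so the
    marginals are exact while the joint distribution is arbitrary.
    """
    n = sum(next(iter(counts_by_covariate.values())).values())
    columns = {}
    for name, counts in counts_by_covariate.items():
        assert sum(counts.values()) == n
        columns[name] = [lab for lab, c in counts.items() for _ in range(c)]
    samples = [
        Sample(
            sample_id=f"S{i:04d}",
            covariates={name: columns[name][i] for name in counts_by_covariate},
        )
        for i in range(n)
    ]
    specs = [
        CovariateSpec(name, tuple(counts)) for name, counts in counts_by_covariate.items()
    ]
    return Cohort(samples, specs)


@pytest.fixture
def gender_cohort() -> Cohort:
    """The 50-male / 55-female worked example."""
    return make_cohort({"gender": {"Male": 50, "Female": 55}})


@pytest.fixture(scope="session")
def case_cohort() -> Cohort:
    """The built-in 1300-sample demonstration cohort, seed 1."""
    return generate_case_study_cohort(1)
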
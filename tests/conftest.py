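import pytest

from mrsynthct import phantom, stats_report


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def case0(default_spec):
    return phantom.generate_case(default_spec, 0)


@pytest.fixture(scope="session")
def noise_free_case(default_spec):
    return phantom.generate_case(phantom.noise_free(default_spec), 0)


@pytest.fixture(scope="session")
def study_report(default_spec):
    """Full 20-case phantom study, shared by the cohort-level tests."""
    return stats_report.run_study(default_spec, n_cases=20)
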
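import pytest
from hypothesis import HealthCheck, settings

import cxcl13index as cx

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_records():
    return cx.reference_cohort()


@pytest.fixture(scope="session")
def reference_strata(reference_records):
    return cx.stratify_cohort(reference_records)


@pytest.fixture(scope="session")
def default_cohort():
    """A study-sized synthetic cohort at the default configuration."""
    return cx.generate(cx.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def xl_config():
    """Default generating parameters scaled to 10,000 patients per group."""
    cfg = cx.SimulationConfig(seed=0)
    return cfg.model_copy(
        update={
            "high": cfg.high.model_copy(update={"n": 10_000}),
            "low": cfg.low.model_copy(update={"n": 10_000}),
            "indeterminate": cfg.indeterminate.model_copy(update={"n": 0}),
        }
    )


@pytest.fixture(scope="session")
def xl_cohort(xl_config):
    return cx.generate(xl_config)
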
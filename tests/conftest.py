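import pytest
from hypothesis import HealthCheck, settings

import tilemark as tm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across test modules."""
    return tm.simulate_study(seed=11)


@pytest.fixture(scope="session")
def scored(study):
    return tm.score_track(study.track)


@pytest.fixture(scope="session")
def regions(scored):
    return tm.call_regions(scored)


@pytest.fixture(scope="session")
def calls(study, regions, scored):
    return tm.build_target_calls(
        study.features, regions, scored, [study.reference_targets], spec=study.spec
    )
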
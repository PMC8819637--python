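import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profile():
    """Mean staff-time profile of the costed program."""
    from prepcost import reference

    return reference.STAFF_MINUTES


@pytest.fixture(scope="session")
def all_reports():
    """One cost report per (scenario, model) from the built-in specs."""
    from prepcost.scenarios import run_all

    return {(r.scenario_id.value, r.model): r for r in run_all()}
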
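import pytest

from nsclc_cea import builtin_scenario, builtin_scenarios


@pytest.fixture(scope="session")
def scenarios():
    """All three bundled PD-L1 strata (session-cached; treat as read-only)."""
    return builtin_scenarios()


@pytest.fixture()
def ge50():
    """Fresh PD-L1 >=50% scenario, safe to mutate."""
    return builtin_scenario("pdl1_ge50")


@pytest.fixture()
def lt1():
    """Fresh PD-L1 <1% scenario, safe to mutate."""
    return builtin_scenario("pdl1_lt1")
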
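import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def table1():
    from plastedit import load_table1_fixture

    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_panel():
    from plastedit import panel_from_table1

    return panel_from_table1()


@pytest.fixture()
def toy_reference():
    from plastedit import Reference

    # 60 nt with a deliberately mixed composition
    return Reference(
        "toy",
        "ATGGCATCATTGGATCATCGATCGTACGTAGCATGCATCGATTCGATCGGATCCATGTAA",
    )
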
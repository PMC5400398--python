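import pytest

from hbcorridor import (
    DEFAULT_PANEL, MutationSite, SitePanel, generate_landscape_fixture,
)

# distinct ancestral/derived letters per site so toy labels decode unambiguously
_ANC = "ACDEFG"
_DER = "VWYKLM"


def make_toy_panel(n: int) -> SitePanel:
    return SitePanel(tuple(
        MutationSite(i + 1, _ANC[i], _DER[i], label=f"{_ANC[i]}{i + 1}{_DER[i]}")
        for i in range(n)
    ))


@pytest.fixture
def panel() -> SitePanel:
    return DEFAULT_PANEL


@pytest.fixture(scope="session")
def default_fixture():
    return generate_landscape_fixture()


@pytest.fixture(scope="session")
def kcl_ihp_records(default_fixture):
    return default_fixture.records_for("KCl_IHP")
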
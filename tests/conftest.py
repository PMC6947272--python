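import pytest

from nanoamp.simulate import builtin_panel


@pytest.fixture(scope="session")
def panel_and_profiles():
    """The built-in 10-amplicon AML panel with its error profiles."""
    return builtin_panel()


@pytest.fixture(scope="session")
def panel(panel_and_profiles):
    return panel_and_profiles[0]


@pytest.fixture(scope="session")
def profiles(panel_and_profiles):
    return panel_and_profiles[1]
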
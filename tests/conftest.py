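import pytest

from ctdnakit.panel import toy_panel


@pytest.fixture(scope="session")
def panel():
    return toy_panel()


@pytest.fixture(scope="session")
def ar(panel):
    return panel.ar
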
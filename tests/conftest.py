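import pytest

from pnsbflux.master import build_master_model


@pytest.fixture(scope="session")
def master():
    """The default PNSB master model (built once per session)."""
    return build_master_model()
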
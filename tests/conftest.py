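import warnings

import pytest


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    """Suppress informational fit warnings unless a test asserts on them."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
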
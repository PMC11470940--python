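import warnings

import pytest

try:
    from hypothesis import settings

    settings.register_profile("deterministic", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("deterministic")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(autouse=True)
def _quiet_small_sample_warnings():
    """Many tests intentionally use small site counts; silence the advisory."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*recommended.*")
        yield
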
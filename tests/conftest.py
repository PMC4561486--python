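import pytest

from spsevol.profiles import load_packaged_profile


@pytest.fixture(scope="session")
def profile():
    return load_packaged_profile()
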
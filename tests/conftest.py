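import pytest
from hypothesis import HealthCheck, settings

from adrdnlp import load_default_cutoffs, load_default_lexicon

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def cutoffs():
    return load_default_cutoffs()
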
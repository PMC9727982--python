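import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from padx.extraction import default_rules
from padx.lexicon import load_default_lexicon
from padx.segmenter import default_hmm_params


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def hmm():
    return default_hmm_params()
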
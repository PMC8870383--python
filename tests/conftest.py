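import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cookietalk.features import FeatureExtractor, transcripts_to_table
from cookietalk.synthetic_corpus import default_separable_config, generate_corpus

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def extractor() -> FeatureExtractor:
    """One shared extractor with all bundled resources loaded."""
    return FeatureExtractor()


@pytest.fixture(scope="session")
def separable_features(extractor):
    """Feature table of the strong-separation preset (n=200, seed 7)."""
    transcripts = generate_corpus(default_separable_config(100, 100, seed=7))
    frame, failures = transcripts_to_table(transcripts, extractor)
    assert not failures
    return frame


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
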
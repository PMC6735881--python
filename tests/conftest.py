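import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from maveimpute import normalize, synth

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def normalized_scores(dataset: synth.SynthDataset) -> pd.DataFrame:
    """Parsed score table rescaled to the anchor scale, adaptive-corrected."""
    df = dataset.parsed_scores()
    anchors = normalize.fit_anchors(df)
    return normalize.correct_adaptive_frame(normalize.rescale_frame(df, anchors))


@pytest.fixture(scope="session")
def small_dataset() -> synth.SynthDataset:
    """A 30-residue synthetic MAVE dataset shared across tests."""
    return synth.generate(synth.SynthConfig(length=30, seed=1))


@pytest.fixture(scope="session")
def small_scores(small_dataset) -> pd.DataFrame:
    return normalized_scores(small_dataset)


#: Reduced ensemble size for tests that exercise contracts, not accuracy.
FAST_HP = {"n_estimators": 60}
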
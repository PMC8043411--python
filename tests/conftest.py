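import numpy as np
import pytest

from screamcalls import alarm_split, synth


@pytest.fixture(scope="session")
def planted_split() -> alarm_split.CategorySplit:
    """The alarm/non-alarm partition the perceptual analyses recover."""
    return alarm_split.CategorySplit(
        frozenset({"pain", "fear", "anger"}),
        frozenset({"pleasure", "sadness", "joy"}),
    )


@pytest.fixture(scope="session")
def separable_features() -> "synth.FeatureTable":
    """7 well-separated Gaussian classes, 60 sounds each, 88 features."""
    return synth.make_feature_table(
        n_classes=7, n_per_class=60, n_features=88, separation=10.0, seed=11
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
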
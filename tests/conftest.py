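import pytest
from hypothesis import settings

from scclassify import ClassSet, MixtureParams

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def three_classes() -> ClassSet:
    return ClassSet(("Adeno", "COVID", "SARS"))


@pytest.fixture(scope="session")
def vaccination_mixture() -> MixtureParams:
    """The 2-component normal mixture fitted to state-level vaccination
    percentages: weights ~0.468/0.532, means 41.7/54.9, sds 4.45/6.01."""
    return MixtureParams(
        weights=(0.4678343, 0.5321657),
        means=(41.7228, 54.8779),
        sds=(4.447488, 6.008174),
    )
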
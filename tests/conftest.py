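import pytest

from qualiannot import FeatureDef, Modality, SessionConfig, SingleEncoding

MITOTIC_STAGES = ("interphase", "prophase", "metaphase", "anaphase")


@pytest.fixture
def single_config():
    return SessionConfig(Modality.SINGLE, keywords=MITOTIC_STAGES)


@pytest.fixture
def one_hot_config():
    return SessionConfig(
        Modality.SINGLE, keywords=MITOTIC_STAGES, single_encoding=SingleEncoding.ONE_HOT
    )


@pytest.fixture
def multi_config():
    return SessionConfig(
        Modality.MULTI, keywords=("normal", "cystic", "out_of_focus", "empty")
    )


@pytest.fixture
def features_config():
    return SessionConfig(
        Modality.FEATURES,
        features=(
            FeatureDef("texture", ("granular", "smooth")),
            FeatureDef("shape", ("circle", "ellipse")),
            FeatureDef("pigmentation", ("dark", "clear")),
        ),
    )
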
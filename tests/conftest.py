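import pytest

from pscea import ModelSettings, ParametricSurvival, default_parameters

# Fitted log-logistic (shape, scale) pairs for both arms' PFS and OS curves.
TABLE2 = {
    ("treatment", "pfs"): (3.07673, 6.88847),
    ("treatment", "os"): (2.63812, 13.97048),
    ("control", "pfs"): (3.97539, 5.39080),
    ("control", "os"): (2.83146, 12.47755),
}


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def settings():
    return ModelSettings()


@pytest.fixture(scope="session")
def table2_models():
    return {k: ParametricSurvival("loglogistic", v) for k, v in TABLE2.items()}
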
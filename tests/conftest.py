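from pathlib import Path

import pytest

from pgxcea import ModelParameters, base_panel, default_registry, hla_only_panel

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def params():
    return ModelParameters()


@pytest.fixture
def registry():
    return default_registry()


@pytest.fixture
def combined_panel():
    return base_panel()


@pytest.fixture
def hla_panel():
    return hla_only_panel()


@pytest.fixture
def data_dir():
    return DATA_DIR
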
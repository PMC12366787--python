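from pathlib import Path

import pytest

from hypograze import SimConfig, default_ciliate_config

DATA_DIR = Path(__file__).resolve().parents[1] / "data"


@pytest.fixture
def ciliate_cfg() -> SimConfig:
    return default_ciliate_config(seed=1)


@pytest.fixture
def taxa_path() -> Path:
    return DATA_DIR / "hypolimnion_ciliate_taxa.csv"
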
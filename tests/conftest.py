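from pathlib import Path

import pytest

from regionoverlap import make_toy_workspace

GOLDEN = Path(__file__).parent / "data" / "golden"


@pytest.fixture
def toy_ws():
    return make_toy_workspace()


@pytest.fixture
def golden_dir():
    return GOLDEN
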
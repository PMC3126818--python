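import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from znf.aligner import AlignerParams
from znf.io import blosum85
from znf.scan import default_profiles


@pytest.fixture(scope="session")
def blosum():
    return blosum85()


@pytest.fixture(scope="session")
def aligner_params(blosum):
    return AlignerParams(matrix=blosum)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


from znf.simulate import random_finger as random_motif  # noqa: E402
from znf.simulate import random_motif_sequence  # noqa: E402


@pytest.fixture
def make_motifs():
    return random_motif_sequence
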
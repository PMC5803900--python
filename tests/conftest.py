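import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from elevgrad import ElevationGrid, SpeciesRange


@pytest.fixture
def grid() -> ElevationGrid:
    return ElevationGrid()


@pytest.fixture
def two_species(grid):
    return [
        SpeciesRange("sp1", "Aves", "EN", 660, 1000),
        SpeciesRange("sp2", "Mammalia", "VU", 900, 1200),
    ]
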
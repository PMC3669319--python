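import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cfba.fixtures import (
    ToyConsortiumParams,
    make_minimal_pair,
    make_screen_consortium,
    make_toy_consortium,
)
from cfba.model import FractionVector


@pytest.fixture(scope="session")
def toy():
    """The frozen mutualistic toy consortium (unconstrained cross-feeding)."""
    return make_toy_consortium()


@pytest.fixture(scope="session")
def minimal_pair():
    """The 11-free-variable pair used for vertex-enumeration cross-checks."""
    return make_minimal_pair()


@pytest.fixture(scope="session")
def screen_consortium():
    return make_screen_consortium()


def frac(cm, f0: float) -> FractionVector:
    """Fraction vector for a two-species community, first species at f0."""
    sp0, sp1 = cm.species_ids
    return FractionVector({sp0: f0, sp1: 1.0 - f0})
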
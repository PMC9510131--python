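import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cma import fixtures
from cma.structio import StructureModel


@pytest.fixture
def polyala_helix():
    """10-residue poly-Ala helix: 5 atoms per residue, 50 atoms."""
    chain = fixtures.build_helix_chain(10, "A")
    return StructureModel([chain])


@pytest.fixture
def c2_helix_dimer():
    """Noiseless C2 helix dimer, separated (no interface contacts)."""
    return fixtures.make_c2_dimer(fixtures.FixtureSpec(separation=16.0, seed=1))


@pytest.fixture
def bound_blob_dimer():
    """Bound two-domain blob dimer (crossed topology) plus domain specs."""
    return fixtures.make_topology_dimer(
        "crossed", fixtures.FixtureSpec(geometry="blob", seed=0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
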
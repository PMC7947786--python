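import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from divcons.pipeline import analyze_bundle
from divcons.synthetic_data import SimulationConfig, simulate_families


@pytest.fixture(scope="session")
def bundle():
    """One default-condition synthetic two-family bundle."""
    return simulate_families(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def analysis(bundle):
    """Full end-to-end analysis of the default bundle (SSN included)."""
    return analyze_bundle(bundle)


@pytest.fixture(scope="session")
def insertion_bundle():
    """Bundle whose family A carries a 5-residue insertion (a mini Dop-loop)."""
    return simulate_families(SimulationConfig(seed=23, insertion=("A", 100, 5)))


@pytest.fixture(scope="session")
def matrix_scorer():
    """Substitution-score lookup shared with the oracles (input data, not code)."""
    from divcons.sequence_families import load_matrix

    mat = load_matrix("BLOSUM62")
    return lambda x, y: float(mat[x, y])
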
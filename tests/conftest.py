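import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracle helpers

from repgut.repertoire_io import load_germline_reference
from repgut.synthetic_repertoire import SimulationConfig, simulate_repertoire


@pytest.fixture(scope="session")
def reference():
    return load_germline_reference("builtin")


@pytest.fixture(scope="session")
def small_clean_sim(reference):
    """A small error-free repertoire with default SHM loads."""
    config = SimulationConfig(seed=7, n_clones=20, read_error_rate=0.0)
    return simulate_repertoire(config, reference)


@pytest.fixture(scope="session")
def small_clean_annotated(small_clean_sim):
    from repgut.annotation import annotate

    return annotate(small_clean_sim.sequences(), small_clean_sim.reference)
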
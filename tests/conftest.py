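import numpy as np
import pytest

from cnevolve import GenomeLayout, SimulationConfig, WindowTrack, simulate_dataset
from cnevolve.calls import CopyNumberProfile


@pytest.fixture
def small_layout():
    """Two arms (one X), 10 windows each, 1 kb windows."""
    return GenomeLayout(("chr2L", "chrX"), (10_000, 10_000), 1000)


@pytest.fixture
def flat_track(small_layout):
    return WindowTrack(small_layout, np.full(small_layout.n_windows, 50.0))


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the default conditions (shared)."""
    return simulate_dataset(SimulationConfig(seed=11))


def make_profile(layout, states, ploidy=2):
    return CopyNumberProfile(layout, np.asarray(states, dtype=np.int64), ploidy)
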
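import numpy as np
import pandas as pd
import pytest

from arrestome import interactome as net
from arrestome.data_model import ScoredInteraction, SpectralCountTable
from arrestome.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config synthetic study shared across read-only tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_network(default_dataset):
    data = default_dataset
    cutoff = net.select_cutoff_by_bfdr(data.scored, 0.01)
    return net.filter_high_confidence(data.scored, cutoff, min_spec=6)


@pytest.fixture
def toy_counts():
    """Two baits, four preys, two replicates; hand-enumerable."""
    rows = [
        ("A", "x", 1, 5), ("A", "x", 2, 6),
        ("A", "y", 1, 8), ("A", "y", 2, 7),
        ("A", "z", 1, 2), ("A", "z", 2, 9),
        ("A", "w", 1, 6), ("A", "w", 2, 6),
        ("B", "x", 1, 3), ("B", "x", 2, 0),
    ]
    counts = pd.DataFrame(rows, columns=["bait", "prey", "replicate", "count"])
    controls = pd.DataFrame(
        [("c1", "x", 2), ("c1", "y", 1), ("c2", "x", 3)],
        columns=["run", "prey", "count"],
    )
    return SpectralCountTable(counts, controls, species="toy", n_replicates=2)


def make_scored(rows):
    """rows: (bait, prey, score, bfdr, counts tuple)."""
    return [ScoredInteraction(b, p, s, f, tuple(c)) for b, p, s, f, c in rows]


@pytest.fixture
def toy_scored():
    return make_scored([
        ("A", "x", 0.95, 0.005, (8, 9)),
        ("A", "y", 0.90, 0.008, (6, 7)),
        ("A", "z", 0.70, 0.04, (12, 15)),
        ("A", "w", 0.99, 0.001, (3, 5)),
        ("B", "x", 0.20, 0.60, (6, 6)),
    ])
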
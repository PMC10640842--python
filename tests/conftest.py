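import numpy as np
import pandas as pd
import pytest

from bloomnet import (
    InteractionTable,
    PlotMetadata,
    SimulationConfig,
    build_all_networks,
    simulate_experiment,
)


@pytest.fixture
def toy_table() -> InteractionTable:
    """Two plots in two blocks/treatments, hand-enumerable."""
    df = pd.DataFrame(
        [
            ("p1", "b1", "C", "plantA", "ins1", 2),
            ("p1", "b1", "C", "plantB", "ins1", 1),
            ("p1", "b1", "C", "plantA", "ins2", 4),
            ("p2", "b2", "F", "plantA", "ins1", 3),
            ("p2", "b2", "F", "plantC", "ins3", 5),
        ],
        columns=["plot", "block", "treatment", "plant", "insect", "count"],
    )
    return InteractionTable(df)


@pytest.fixture
def toy_meta() -> dict[str, PlotMetadata]:
    return {
        "p1": PlotMetadata("p1", "b1", "C", plants_bloomed=3, display=1200.0),
        "p2": PlotMetadata("p2", "b2", "F", plants_bloomed=2, display=800.0),
    }


@pytest.fixture(scope="session")
def small_experiment():
    """One seeded synthetic season, shared across tests."""
    table, metadata, truth = simulate_experiment(SimulationConfig(seed=11))
    return table, metadata, truth


@pytest.fixture(scope="session")
def small_networks(small_experiment):
    table, metadata, _ = small_experiment
    return build_all_networks(table, metadata)


def brute_force_nodf(b: np.ndarray) -> float:
    """Independent pairwise NODF oracle using explicit set overlap."""
    b = (np.asarray(b) > 0).astype(int)
    m, n = b.shape

    def paired(vectors):
        total = 0.0
        cnt = 0
        for i in range(len(vectors)):
            for j in range(i + 1, len(vectors)):
                cnt += 1
                si = {k for k, v in enumerate(vectors[i]) if v}
                sj = {k for k, v in enumerate(vectors[j]) if v}
                if len(si) == len(sj):
                    continue
                dense, sparse = (si, sj) if len(si) > len(sj) else (sj, si)
                if not sparse:
                    continue
                total += 100.0 * len(dense & sparse) / len(sparse)
        return total, cnt

    rows, nr = paired([list(r) for r in b])
    cols, nc = paired([list(c) for c in b.T])
    return (rows + cols) / (nr + nc)
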
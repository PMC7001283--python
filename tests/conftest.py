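import numpy as np
import pandas as pd
import pytest

from genotox import SimulationParams, TrainingSet, default_test_panel, \
    generate_flow_study, generate_test_study, generate_training_set


@pytest.fixture(scope="session")
def params() -> SimulationParams:
    return SimulationParams(seed=42)


@pytest.fixture(scope="session")
def training(params) -> TrainingSet:
    return generate_training_set(params)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A scaled-down study for fast pipeline-level tests."""
    return SimulationParams(seed=42, n_background_genes=100)


@pytest.fixture(scope="session")
def test_study(small_params):
    return generate_test_study(default_test_panel(), small_params)


@pytest.fixture(scope="session")
def flow_study(params) -> pd.DataFrame:
    return generate_flow_study(default_test_panel(), params)


@pytest.fixture()
def toy_training() -> TrainingSet:
    """The 2-gene, 4-chemical hand-workable training set."""
    X = pd.DataFrame(
        [[0.0, 0.0], [0.0, 2.0], [4.0, 0.0], [4.0, 2.0]],
        index=["a1", "a2", "b1", "b2"], columns=["g1", "g2"])
    y = pd.Series(["DDI", "DDI", "non-DDI", "non-DDI"], index=X.index)
    return TrainingSet(X=X, y=y)


def make_wells(vehicle_counts, treated_groups, cells=20000):
    """Build a flow well table from event counts.

    ``treated_groups`` maps concentration_index -> list of (events, cells)
    or plain event counts (then ``cells`` applies).
    """
    rows = []
    def norm(item):
        return item if isinstance(item, tuple) else (item, cells)
    for rep, item in enumerate(vehicle_counts, 1):
        ev, n = norm(item)
        rows.append(dict(chemical="X", concentration_index=0, replicate=rep,
                         scored_cells=n, mn_events=ev, nuclei_count=10000,
                         bead_count=5000, is_vehicle=True))
    for conc, group in treated_groups.items():
        for rep, item in enumerate(group, 1):
            ev, n = norm(item)
            rows.append(dict(chemical="X", concentration_index=conc,
                             replicate=rep, scored_cells=n, mn_events=ev,
                             nuclei_count=10000, bead_count=5000,
                             is_vehicle=False))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
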
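import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """A compact simulation: 20 lines, 300 genes, light planting."""
    from rospanel.synthetic import PlantedSet, SimulationConfig

    return SimulationConfig(
        seed=42,
        n_lines=20,
        n_genes=300,
        planted_sets=(
            PlantedSet(("plasma", "h2o2"), 15, 0.6, +1),
            PlantedSet(("plasma",), 15, 0.6, -1),
            PlantedSet(("hocl",), 10, 0.5, +1),
        ),
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    from rospanel.synthetic import simulate_panel

    return simulate_panel(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def dose_response_records():
    """Tiny hand-written dose-response table with exact control/treated means."""
    rows = []
    for rep, f0, f1 in [(1, 900.0, 480.0), (2, 1100.0, 520.0)]:
        rows.append(dict(cell_line="A", treatment="ox", dose=0.0, replicate=rep, fluorescence=f0))
        rows.append(dict(cell_line="A", treatment="ox", dose=10.0, replicate=rep, fluorescence=f1))
        rows.append(dict(cell_line="A", treatment="ox", dose=100.0, replicate=rep, fluorescence=f1 / 2))
    return pd.DataFrame(rows)
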
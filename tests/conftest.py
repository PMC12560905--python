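from pathlib import Path

import pandas as pd
import pytest

from lactaqg.simulate import SimScenario, simulate_herd

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_herd():
    """A modest clean herd reused by fixed-effects / model / CLI tests."""
    scenario = SimScenario(
        seed=7, n_generations=3, males_per_gen=10, females_per_gen=150,
        sires_per_gen=8, n_cows_with_records=250, records_per_cow=4,
    )
    ped, records, truth = simulate_herd(scenario)
    return scenario, ped, records, truth


@pytest.fixture()
def qc_fixture() -> pd.DataFrame:
    """Hand-built adversarial raw records with known per-stage removals."""
    return pd.read_csv(DATA_DIR / "qc_adversarial.csv")
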
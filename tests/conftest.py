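from pathlib import Path

import pytest

from upfpdi.pipeline import analyze_dataset
from upfpdi.reference import load_reference_tables
from upfpdi.simulate import SimulationConfig, simulate

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_bundle():
    """The shipped 12-food / 2-recipe reference bundle."""
    return load_reference_tables(DATA_DIR / "refbundle")


@pytest.fixture(scope="session")
def small_dataset():
    """Simulated cohort with a built-in uPDI-UPF slope of 0.8 (n=400)."""
    return simulate(SimulationConfig(seed=7, n_participants=400, slope_updi=0.8))


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    """(analysis table, design, scores) for the small simulated cohort."""
    ds = small_dataset
    return analyze_dataset(ds.bundle, ds.recall, ds.participants, ds.design)
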
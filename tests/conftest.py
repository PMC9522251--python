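import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cisgrn.simulate import SimulationConfig, emit_dataset, simulate_all


def tiny_sim_config(seed: int = 7, **overrides) -> SimulationConfig:
    defaults = dict(
        seed=seed,
        n_chroms=2,
        chrom_length=120_000,
        n_genes=60,
        n_enhancers=30,
        n_decoy_ac_peaks=30,
        n_decoy_me1_peaks=30,
        n_motifs=10,
        n_background_footprints=60,
        n_knockdowns=3,
        max_tss_distance=20_000,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_data():
    """Small in-memory synthetic dataset shared across unit tests."""
    return simulate_all(tiny_sim_config())


@pytest.fixture(scope="session")
def default_data():
    """Default-size synthetic dataset (200 enhancers, 200 decoys/mark)."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """Tiny dataset written out as files."""
    outdir = tmp_path_factory.mktemp("tiny_dataset")
    emit_dataset(tiny_sim_config(), outdir)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
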
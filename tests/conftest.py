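import numpy as np
import pandas as pd
import pytest

from mapshift import synthetic_data as sd


def small_config(**overrides) -> sd.SimulationConfig:
    """A scaled-down simulation for fast unit tests."""
    defaults = dict(
        n_proteins=300,
        n_compartments=6,
        n_markers=60,
        n_movers=5,
        n_decoy_flagged=5,
        n_low_quality=5,
    )
    defaults.update(overrides)
    return sd.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_truth() -> sd.MapSetTruth:
    """One full-size map-set simulation at the default study conditions."""
    return sd.generate_mapset(sd.SimulationConfig(), seed=0)


@pytest.fixture(scope="session")
def small_truth() -> sd.MapSetTruth:
    return sd.generate_mapset(small_config(), seed=11)


@pytest.fixture(scope="session")
def control_profiles(default_truth) -> pd.DataFrame:
    """Concatenated per-map normalized profiles of the two control maps."""
    from mapshift import profiles_io as pio

    profs = {
        key: pio.build_profiles(default_truth.mapset.values[key])
        for key in [("control", 1), ("control", 2)]
    }
    return pd.concat(
        [profs[("control", 1)].add_prefix("c1_"), profs[("control", 2)].add_prefix("c2_")],
        axis=1,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
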
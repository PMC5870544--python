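import numpy as np
import pandas as pd
import pytest

from plasmadrift import FeatureTable, SimulationConfig, ArchetypeSpec, simulate


@pytest.fixture
def toy_table() -> FeatureTable:
    """3 samples x 4 features with simple positive intensities."""
    return FeatureTable(
        pd.DataFrame(
            [[10.0, 20.0, 5.0, 1.0],
             [20.0, 40.0, 10.0, 2.0],
             [12.0, 18.0, 6.0, 1.5]],
            index=["s1", "s2", "s3"],
            columns=["d1.0", "d2.0", "d3.0", "d4.0"],
        )
    )


def small_sim_config(seed: int = 0, noise_sd: float = 0.05, **kw) -> SimulationConfig:
    """Compact simulation: 8 subjects x 60 features, same archetype mix."""
    spec = (
        ArchetypeSpec("increase", 12, 1.8, attenuation=2.5, tau_h=20.0),
        ArchetypeSpec("increase", 8, 0.55, attenuation=1.1, tau_h=8.0),
        ArchetypeSpec("increase", 6, 0.25, attenuation=0.25, tau_h=6.0),
        ArchetypeSpec("decrease", 14, 0.8, attenuation=3.5, tau_h=16.0),
        ArchetypeSpec("stable", 10, 0.0),
        ArchetypeSpec("excursion_3h", 6, 0.6),
    )
    kw.setdefault("n_subjects", 8)
    kw.setdefault("n_features", 60)
    kw.setdefault("cluster_spec", spec)
    return SimulationConfig(noise_sd=noise_sd, seed=seed, **kw)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated study shared across read-only tests."""
    return simulate(small_sim_config(seed=42))


def meta_at(meta: pd.DataFrame, temperature: float) -> pd.DataFrame:
    return meta[meta["temperature_c"] == temperature].reset_index(drop=True)
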
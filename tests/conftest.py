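import numpy as np
import pandas as pd
import pytest

from ftirco.spectra_io import SampleMeta, SpectraSet, WavenumberAxis
from ftirco import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def small_set(rng):
    """Random 5-sample x 20-channel set with full design metadata."""
    axis = WavenumberAxis(np.linspace(800.0, 1800.0, 20))
    matrix = rng.normal(size=(5, 20))
    meta = pd.DataFrame(
        [
            SampleMeta(
                sample_id=f"s{i}",
                strain="MCI",
                n_source="AS",
                pi_level="Pi1",
                bio_rep=1 + i % 3,
                tech_rep=1 + i % 2,
            ).as_dict()
            for i in range(5)
        ]
    )
    return SpectraSet(axis, matrix, meta)


@pytest.fixture(scope="session")
def study_biomass():
    """Full study-shaped simulated biomass set (936 spectra), shared across
    tests to keep the suite fast."""
    design = sd.expand_technical(sd.study_design(), tech_reps=3)
    sset, truth = sd.simulate_biomass_set(design, seed=11)
    return sset, truth


@pytest.fixture(scope="session")
def study_media():
    sset, truth = sd.simulate_media_set(sd.study_design(), seed=11)
    return sset, truth
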
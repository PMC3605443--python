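import numpy as np
import pytest

import steatopipe as sp


@pytest.fixture(scope="session")
def cohort_df():
    """Default 59-patient / 10-control synthetic cohort, fixed seed."""
    return sp.cohort_to_frame(sp.generate_cohort(seed=11))


@pytest.fixture(scope="session")
def phantom_10pct():
    """Histology phantom at 10% target fat with one vessel and one tear."""
    spec = sp.HistologyPhantomSpec(target_fat_fraction=0.10, seed=5)
    return sp.generate_histology_phantom(spec)


@pytest.fixture(scope="session")
def no_t1_params():
    """Signal parameters that switch off T1 weighting (weights = densities)."""
    def make(t2star=20.0, noise_sd=0.0, seed=None):
        return sp.MRISignalParams(
            flip_angle=90.0, tr=1e9, t1_water=586.0, t1_fat=343.0,
            t2star=t2star, proton_density_water=50.0, proton_density_fat=50.0,
            noise_sd=noise_sd, seed=seed,
        )
    return make
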
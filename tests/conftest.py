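import numpy as np
import pandas as pd
import pytest

import ewaskit as ek
from ewaskit.data import EffectSpec


@pytest.fixture(scope="session")
def manifest():
    return ek.generate_manifest(1000, 60, 100, 0.02, 0.05, seed=1)


@pytest.fixture(scope="session")
def reference():
    return ek.generate_reference(100, 1.5, seed=3)


@pytest.fixture(scope="session")
def null_cohort(manifest, reference):
    """Cohort with no spiked effects and one planted violator per QC rule."""
    return ek.generate_cohort(
        manifest, reference, 60, 50, EffectSpec(), responder_frac=0.5, seed=7,
        planted_qc=ek.PlantedQC(low_call=1, boundary_call=1, missing_signal=1,
                                sex_swap=1, control_outlier=1))


@pytest.fixture(scope="session")
def clean_cohort(manifest, reference):
    """Cohort with no planted QC violators (all samples clean)."""
    return ek.generate_cohort(manifest, reference, 50, 40, EffectSpec(),
                              responder_frac=0.5, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
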
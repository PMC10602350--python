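import numpy as np
import pytest

from cardiovar import synthetic as syn


@pytest.fixture(scope="session")
def control_phenotype() -> syn.PhenotypeSpec:
    return syn.CONTROL_PHENOTYPE


@pytest.fixture(scope="session")
def hfref_phenotype() -> syn.PhenotypeSpec:
    return syn.HFREF_PHENOTYPE


@pytest.fixture(scope="session")
def rendered_control(control_phenotype):
    """A control-like rendered record with its ground truth (25 cycles, 1 kHz)."""
    beats = syn.generate_beat_series(control_phenotype, 25, seed=11)
    record, truth = syn.render_pv_record(beats, control_phenotype, 1000.0)
    return record, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230)
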
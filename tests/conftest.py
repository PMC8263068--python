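import numpy as np
import pytest

from grslogic.benchmarks import reference_catalog
from grslogic.enumeration import build_panel
from grslogic.error_model import fit_global_error_params
from grslogic.synthetic_data import generate_noisy_dataset


@pytest.fixture(scope="session")
def catalog():
    """Filtered + deduplicated representative catalog (all 216 entries)."""
    return reference_catalog()


@pytest.fixture(scope="session")
def retained(catalog):
    return catalog.retained()


@pytest.fixture(scope="session")
def amplitude_panel():
    return build_panel("amplitude26")


@pytest.fixture(scope="session")
def noisy_dataset(retained, amplitude_panel):
    """2-replicate base-noise dataset for the retained catalog (normalized)."""
    return generate_noisy_dataset(retained, amplitude_panel, 2, seed=20210624)


@pytest.fixture(scope="session")
def fitted_error(noisy_dataset):
    """(params, stats) of the time-value global fit on the shared dataset."""
    return fit_global_error_params(noisy_dataset.values, noisy_dataset.timepoints,
                                   mode="time_value")


@pytest.fixture()
def rng():
    return np.random.default_rng(20210624)
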
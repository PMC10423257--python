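import numpy as np
import pytest

from sirtdosim import (PatientSpec, PhantomSpec, Lesion, make_nema_phantom,
                       make_synthetic_patient)


@pytest.fixture
def rng():
    return np.random.default_rng(20230812)


@pytest.fixture(scope="session")
def default_phantom():
    """Ground-truth NEMA-style phantom on the default grid."""
    spec = PhantomSpec()
    truth, vois = make_nema_phantom(spec)
    return spec, truth, vois


@pytest.fixture(scope="session")
def padded_phantom():
    """Phantom with 30 mm of empty grid around the body (>= 3 FWHM at 10 mm)."""
    spec = PhantomSpec(grid_padding_mm=30.0)
    truth, vois = make_nema_phantom(spec)
    return spec, truth, vois


@pytest.fixture
def two_lesion_patient():
    spec = PatientSpec(
        lesions=[Lesion((20.0, 10.0, 0.0), 25.0), Lesion((-30.0, -10.0, 10.0), 14.0)],
        tn_ratio=3.8, administered_activity_GBq=1.5, discrepancy_sigma=0.3,
        seed=42)
    return spec, make_synthetic_patient(spec)
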
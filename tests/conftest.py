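import numpy as np
import pytest

from t1rho import (GridSpec, PhantomSpec, SpinLockProtocol, TissueRelaxation,
                   build_phantom, t1rho_grid)


@pytest.fixture(scope="session")
def protocol() -> SpinLockProtocol:
    return SpinLockProtocol()


@pytest.fixture(scope="session")
def tissue_params() -> dict:
    """Mutant-group tissue parameters with all four FSLs."""
    return {
        "brain": TissueRelaxation(882.0, 120.0,
                                  {100.0: 119.0, 500.0: 100.0,
                                   1000.0: 98.0, 2000.0: 108.0}, s0=100.0),
        "tumour": TissueRelaxation(988.0, 139.0,
                                   {100.0: 147.0, 500.0: 127.0,
                                    1000.0: 126.0, 2000.0: 137.0}, s0=100.0),
    }


@pytest.fixture(scope="session")
def single_slice_phantom(tissue_params):
    """34x34 single-slice phantom with a tumour, for fit tests."""
    spec = PhantomSpec(grid=GridSpec(34, 34, 1), tumour_radius_mm=1.3,
                       tissue_params=tissue_params)
    return build_phantom(spec)


@pytest.fixture(scope="session")
def full_phantom(tissue_params):
    """Full 34x34x10 phantom with a tumour."""
    spec = PhantomSpec(grid=t1rho_grid(), tumour_radius_mm=1.3,
                       tissue_params=tissue_params)
    return build_phantom(spec)


@pytest.fixture(scope="session")
def truth_cohort():
    """Default cohort at the ground-truth (measurement) level."""
    from t1rho import generate_cohort
    return generate_cohort(imaging=False, seed=11)
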
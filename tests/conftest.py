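import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cfmsim as cm

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def seq() -> cm.SequenceParams:
    return cm.SequenceParams()


@pytest.fixture(scope="session")
def cyl86_map() -> cm.SusceptibilityMap:
    """Single straight cylinder, d = 8.6 um, chi = 3e-8 cgs, 128^3 grid."""
    params = cm.CFMParams(beta=0.0, diameter_um=8.6, chi_cgs=3e-8)
    return cm.build_susceptibility_map(params)


@pytest.fixture(scope="session")
def cyl86_field(cyl86_map) -> cm.FieldMap:
    """Dipole field of the d = 8.6 um cylinder perpendicular to B0 (1 T)."""
    return cm.dipole_field(cyl86_map, 1.0, (0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def run_series(seq):
    """Simulate the 5-point segment-count series for one parameter cell."""

    def _run(beta=0.0, phi=0.0, orientation=1, diameter_um=5.6, D=1e-10,
             chi_cgs=3e-8, n_walkers=5000, seed=0, grid_n=128,
             segment_counts=(1, 3, 5, 7, 9), b0=1.0):
        direction = cm.b0_direction_for_orientation(orientation)
        records = []
        for i, n_seg in enumerate(segment_counts):
            params = cm.CFMParams(
                beta=beta, phi=phi, orientation=orientation,
                diameter_um=diameter_um, n_segments=n_seg,
                grid_n=grid_n, chi_cgs=chi_cgs,
            )
            smap = cm.build_susceptibility_map(params)
            fmap = cm.dipole_field(smap, b0, direction)
            records.append(
                cm.simulate_signal(smap, fmap, seq, D, n_walkers, seed + i)
            )
        return records

    return _run


@pytest.fixture
def empty_map():
    """Vessel-free 32^3 map (all voxels extravascular)."""
    n = 32
    return cm.SusceptibilityMap(
        values=np.zeros((n, n, n)),
        inside_mask=np.zeros((n, n, n), dtype=bool),
        voxel_size_um=2.0,
        volume_fraction=0.0,
    )
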
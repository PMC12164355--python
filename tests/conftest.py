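import warnings

import numpy as np
import pytest

from plasmoniso import (
    ClusterGeometry,
    Medium,
    SolverSettings,
    build_radial_geometry,
    solve_cluster_spectrum,
)


@pytest.fixture(scope="session")
def medium():
    return Medium()


@pytest.fixture(scope="session")
def coarse_grid():
    """450-650 nm at 2 nm: spans both plasmonic bands, fast to solve."""
    return np.arange(450.0, 651.0, 2.0)


@pytest.fixture(scope="session")
def single_sphere_geometry():
    return ClusterGeometry(
        centers=np.zeros((1, 3)), radii=[6.0], subgroup_ids=[0], sp_nominal=1.0
    )


def solve_quiet(geometry, **kw):
    """Cluster solve with fidelity warnings silenced (sub-nm-gap test cases)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return solve_cluster_spectrum(geometry, **kw)


@pytest.fixture(scope="session")
def radial_cluster_spectra(coarse_grid):
    """Per-particle extinction spectra of the default radial ensemble vs sp."""
    out = {}
    for sp in (0.6, 1.0, 2.0, 4.0):
        res = solve_quiet(
            build_radial_geometry(sp),
            wavelength_grid=coarse_grid,
            settings=SolverSettings(polarization="x"),
        )
        out[sp] = res.per_particle()[2]
    return out
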
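"""Mie theory for an isolated gold nanosphere.

The multipole (Lorenz-Mie) series gives the absorption, scattering and
extinction cross sections of a single sphere embedded in a non-absorbing
medium -- the "plasmonically uncoupled" endpoint of every mixture analysis in
this package.  The implementation follows the standard Bohren & Huffman
formulation with the logarithmic-derivative downward recurrence, truncated at
the size-adaptive Wiscombe order n_max = x + 4 x^(1/3) + 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import DielectricModel, Medium, gold_dielectric
from .spectra import DEFAULT_GRID, Spectrum

__all__ = [
    "IncidentField",
    "incident_irradiance",
    "mie_cross_sections",
    "mie_efficiencies",
]

#: Impedance of free space, Ohm.
Z0_FREE_SPACE = 376.73

#: Hard ceiling on the multipole order; reaching it raises a convergence error.
MAX_MIE_ORDER = 80


def incident_irradiance(E0: float, Z0: float = Z0_FREE_SPACE) -> float:
    """Irradiance I = E0^2 / (2 Z0) of a plane wave, in W/m^2.

    ``E0`` is the incident field amplitude (V/m) and ``Z0`` the wave impedance
    of the system (Ohm).  E0 = 0 is allowed and gives zero irradiance.
    """
    if E0 < 0:
        raise ValueError("field amplitude E0 must be >= 0")
    if Z0 <= 0:
        raise ValueError("impedance Z0 must be > 0")
    return E0 * E0 / (2.0 * Z0)


@dataclass(frozen=True)
class IncidentField:
    """Incident plane wave: amplitude E0 (V/m) and system impedance Z0 (Ohm)."""

    E0: float = 1.0e5
    Z0: float = Z0_FREE_SPACE

    @property
    def irradiance(self) -> float:
        return incident_irradiance(self.E0, self.Z0)


def _mie_q(m: complex, x: float) -> tuple[float, float]:
    """Extinction and scattering efficiencies for one (m, x); scalar core."""
    nstop = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    if nstop > MAX_MIE_ORDER:
        raise ValueError(
            f"Mie series would need order {nstop} > {MAX_MIE_ORDER}; "
            "sphere too large for this implementation"
        )
    mx = m * x
    nmx = int(max(nstop, abs(mx)) + 16)
    D = np.zeros(nmx + 1, dtype=complex)
    for n in range(nmx, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)

    psi0, psi1 = np.cos(x), np.sin(x)      # Riccati-Bessel psi_{-1}, psi_0
    chi0, chi1 = -np.sin(x), np.cos(x)
    xi1 = psi1 - 1j * chi1
    qext = 0.0
    qsca = 0.0
    for n in range(1, nstop + 1):
        psi = (2 * n - 1) / x * psi1 - psi0
        chi = (2 * n - 1) / x * chi1 - chi0
        xi = psi - 1j * chi
        dn = D[n]
        da = dn / m + n / x
        db = dn * m + n / x
        a = (da * psi - psi1) / (da * xi - xi1)
        b = (db * psi - psi1) / (db * xi - xi1)
        qext += (2 * n + 1) * (a + b).real
        qsca += (2 * n + 1) * (abs(a) ** 2 + abs(b) ** 2)
        psi0, psi1 = psi1, psi
        chi0, chi1 = chi1, chi
        xi1 = xi
    return 2.0 / x ** 2 * qext, 2.0 / x ** 2 * qsca


def mie_efficiencies(m, x):
    """Vectorized (Q_ext, Q_sca) over arrays of relative index m and size x."""
    m = np.atleast_1d(np.asarray(m, dtype=complex))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    qe = np.empty(x.shape)
    qs = np.empty(x.shape)
    for i, (mi, xi) in enumerate(zip(m, x)):
        qe[i], qs[i] = _mie_q(mi, xi)
    return qe, qs


def mie_cross_sections(
    radius_nm: float,
    medium: Medium | None = None,
    wavelength_grid=None,
    dielectric: DielectricModel | None = None,
):
    """Absorption, scattering and extinction cross sections of one sphere.

    Parameters
    ----------
    radius_nm:
        Sphere radius in nm (> 0).
    medium:
        Embedding medium; defaults to n = 1.343.
    wavelength_grid:
        Wavelengths in nm; defaults to 400-800 nm at 1 nm.
    dielectric:
        Particle permittivity model; defaults to the embedded gold table.

    Returns
    -------
    (sigma_abs, sigma_sca, sigma_ext) : three ``Spectrum`` objects in nm^2,
    satisfying sigma_ext = sigma_abs + sigma_sca pointwise.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be > 0")
    medium = medium or Medium()
    grid = np.asarray(
        DEFAULT_GRID if wavelength_grid is None else wavelength_grid, dtype=float
    )
    eps = (dielectric or gold_dielectric())(grid)
    m = np.sqrt(np.asarray(eps, dtype=complex)) / medium.refractive_index
    m = np.where(m.imag < 0, np.conj(m), m)
    x = 2.0 * np.pi * medium.refractive_index * radius_nm / grid
    qext, qsca = mie_efficiencies(m, x)
    area = np.pi * radius_nm ** 2
    sigma_ext = qext * area
    sigma_sca = qsca * area
    sigma_abs = np.clip(sigma_ext - sigma_sca, 0.0, None)
    sigma_ext = sigma_abs + sigma_sca  # enforce the identity exactly
    return (
        Spectrum(grid, sigma_abs, channel="absorption"),
        Spectrum(grid, sigma_sca, channel="scattering"),
        Spectrum(grid, sigma_ext, channel="extinction"),
    )
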
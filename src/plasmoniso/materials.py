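"""Optical constants of gold and of the embedding medium.

All electromagnetic computations in this package (Mie theory, coupled-dipole
cluster solves) draw their material response from here.  Two interchangeable
descriptions of the gold relative permittivity are provided:

* an embedded experimental table (Johnson & Christy-style single-crystal
  optical constants, visible/near-IR), linearly interpolated in wavelength;
* an analytic Drude + two-Lorentz oscillator model fitted to that table,
  useful when a smooth, continuously differentiable permittivity is wanted.

The embedding medium is a non-absorbing dielectric described by its real
refractive index.  The default, n = 1.343, models the aqueous/lipid
environment of nanoparticle-on-vesicle assemblies; a small plasmonic gold
sphere in this medium resonates near 521-525 nm, consistent with the
single-particle extinction peak of citrate-stabilised ~12 nm particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DielectricModel",
    "Medium",
    "gold_dielectric",
    "gold_permittivity",
    "EV_NM",
]

#: Planck constant x speed of light in eV.nm; converts photon energy <-> wavelength.
EV_NM = 1239.84193

# Gold optical constants (photon energy eV, n, k), Johnson & Christy-style
# single-crystal values spanning ~285-1940 nm.
_GOLD_NK_EV = np.array([
    [0.64, 0.92, 13.78],
    [0.77, 0.56, 11.21],
    [0.89, 0.43, 9.519],
    [1.02, 0.35, 8.145],
    [1.14, 0.27, 7.150],
    [1.26, 0.22, 6.350],
    [1.39, 0.17, 5.663],
    [1.51, 0.16, 5.083],
    [1.64, 0.14, 4.542],
    [1.76, 0.13, 4.103],
    [1.88, 0.14, 3.697],
    [2.01, 0.21, 3.272],
    [2.13, 0.29, 2.863],
    [2.26, 0.43, 2.455],
    [2.38, 0.62, 2.081],
    [2.50, 1.04, 1.833],
    [2.63, 1.31, 1.849],
    [2.75, 1.38, 1.914],
    [2.88, 1.45, 1.948],
    [3.00, 1.46, 1.958],
    [3.12, 1.47, 1.952],
    [3.25, 1.46, 1.933],
    [3.37, 1.48, 1.895],
    [3.50, 1.50, 1.866],
    [3.62, 1.48, 1.871],
    [3.74, 1.48, 1.883],
    [3.87, 1.54, 1.898],
    [3.99, 1.53, 1.893],
    [4.12, 1.53, 1.889],
    [4.24, 1.49, 1.878],
    [4.36, 1.47, 1.869],
])

# Drude + two-Lorentz fit to the table above, weighted least squares on
# relative deviation over 400-800 nm (max relative deviation 4.6%):
#   eps(w) = eps_inf - wp^2/(w(w + i g0))
#            + f1 w1^2/(w1^2 - w^2 - i w g1) + f2 w2^2/(w2^2 - w^2 - i w g2)
# with photon energies in eV.
_DL_PARAMS = dict(
    eps_inf=6.33606, wp=9.02239, g0=0.0328454,
    f1=0.330296, w1=2.67097, g1=0.452875,
    f2=1.86287, w2=3.20323, g2=1.10014,
)
_DL_WINDOW = (350.0, 900.0)


def _drude_lorentz_eps(wavelength_nm: np.ndarray) -> np.ndarray:
    w = EV_NM / np.asarray(wavelength_nm, dtype=float)
    p = _DL_PARAMS
    eps = p["eps_inf"] - p["wp"] ** 2 / (w * (w + 1j * p["g0"]))
    eps = eps + p["f1"] * p["w1"] ** 2 / (p["w1"] ** 2 - w ** 2 - 1j * w * p["g1"])
    eps = eps + p["f2"] * p["w2"] ** 2 / (p["w2"] ** 2 - w ** 2 - 1j * w * p["g2"])
    return eps


@dataclass(frozen=True)
class DielectricModel:
    """Complex relative permittivity of a (metal) material vs wavelength.

    Parameters
    ----------
    model_kind:
        ``"table"`` for linear interpolation of a sampled table, or
        ``"analytic_drude_lorentz"`` for the closed-form oscillator model.
    wavelength_nm, epsilon:
        Table nodes (ascending wavelength) and complex permittivity values;
        only used when ``model_kind == "table"``.
    window_nm:
        Validity window; evaluation outside raises ``ValueError``.
    """

    model_kind: str = "table"
    wavelength_nm: np.ndarray | None = None
    epsilon: np.ndarray | None = None
    window_nm: tuple[float, float] = (300.0, 900.0)
    name: str = "Au"

    def __post_init__(self):
        if self.model_kind not in ("table", "analytic_drude_lorentz"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.model_kind == "table":
            lam = np.asarray(self.wavelength_nm, dtype=float)
            eps = np.asarray(self.epsilon, dtype=complex)
            if lam.ndim != 1 or lam.size < 2 or lam.size != eps.size:
                raise ValueError("table needs matching 1-d wavelength/epsilon arrays")
            if np.any(np.diff(lam) <= 0):
                raise ValueError("table wavelengths must be strictly increasing")
            if np.any(eps.imag < -1e-12):
                raise ValueError("passive material requires Im(eps) >= 0")
            object.__setattr__(self, "wavelength_nm", lam)
            object.__setattr__(self, "epsilon", eps)

    def __call__(self, wavelength_nm) -> np.ndarray | complex:
        scalar = np.isscalar(wavelength_nm)
        lam = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
        lo, hi = self.window_nm
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"wavelength outside the {self.name} dielectric validity window "
                f"[{lo:g}, {hi:g}] nm"
            )
        if self.model_kind == "table":
            re = np.interp(lam, self.wavelength_nm, self.epsilon.real)
            im = np.interp(lam, self.wavelength_nm, self.epsilon.imag)
            eps = re + 1j * im
        else:
            eps = _drude_lorentz_eps(lam)
        return complex(eps[0]) if scalar else eps

    @classmethod
    def from_file(cls, path, name: str = "user") -> "DielectricModel":
        """Load a dielectric table from 2/3-column text.

        Columns: wavelength_nm, Re(eps) [, Im(eps)]; '#' starts a comment.
        """
        data = np.loadtxt(path, comments="#", ndmin=2)
        if data.shape[1] == 2:
            lam, re = data.T
            im = np.zeros_like(re)
        elif data.shape[1] >= 3:
            lam, re, im = data[:, 0], data[:, 1], data[:, 2]
        else:
            raise ValueError("dielectric table needs 2 or 3 numeric columns")
        order = np.argsort(lam)
        return cls(
            model_kind="table",
            wavelength_nm=lam[order],
            epsilon=re[order] + 1j * im[order],
            window_nm=(float(lam.min()), float(lam.max())),
            name=name,
        )


def _gold_table() -> tuple[np.ndarray, np.ndarray]:
    ev, n, k = _GOLD_NK_EV.T
    lam = EV_NM / ev
    m = n + 1j * k
    eps = m * m
    order = np.argsort(lam)
    return lam[order], eps[order]


def gold_dielectric(kind: str = "table") -> DielectricModel:
    """The package's embedded gold permittivity model.

    ``kind="table"`` (default) interpolates the embedded experimental optical
    constants; ``kind="analytic_drude_lorentz"`` evaluates the fitted
    oscillator model (valid 350-900 nm).
    """
    if kind == "table":
        lam, eps = _gold_table()
        return DielectricModel(
            model_kind="table", wavelength_nm=lam, epsilon=eps,
            window_nm=(300.0, 900.0), name="Au",
        )
    if kind == "analytic_drude_lorentz":
        return DielectricModel(
            model_kind="analytic_drude_lorentz", window_nm=_DL_WINDOW, name="Au",
        )
    raise ValueError(f"unknown gold dielectric kind {kind!r}")


_DEFAULT_GOLD = gold_dielectric("table")


def gold_permittivity(wavelength_nm, model: DielectricModel | None = None):
    """Complex relative permittivity of gold at the given wavelength(s) [nm]."""
    return (_DEFAULT_GOLD if model is None else model)(wavelength_nm)


@dataclass(frozen=True)
class Medium:
    """Non-absorbing embedding medium (default: aqueous/lipid, n = 1.343).

    ``relative_permittivity`` is derived as n^2; permeability is 1 and
    conductivity 0 throughout the package.  Use ``Medium.from_permittivity``
    to interpret a quoted value as a permittivity instead of an index.
    """

    refractive_index: float = 1.343
    permeability: float = field(default=1.0, init=False)
    conductivity: float = field(default=0.0, init=False)

    def __post_init__(self):
        if not (self.refractive_index >= 1.0):
            raise ValueError("medium refractive index must be >= 1")

    @property
    def relative_permittivity(self) -> float:
        return self.refractive_index ** 2

    @classmethod
    def from_permittivity(cls, eps: float) -> "Medium":
        if eps < 1.0:
            raise ValueError("medium permittivity must be >= 1")
        return cls(refractive_index=float(np.sqrt(eps)))
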
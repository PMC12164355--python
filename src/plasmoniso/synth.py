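"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's raw data:

* concentration series of UV-vis mixture spectra: a fixed nanoparticle
  concentration titrated with vesicle templates, the coupled fraction
  following the saturation law f = min(1, c_template * N_sat / c_AuNP)
  (N_sat nanoparticles saturate one template).  Within the saturation
  (nanoparticle-excess) regime the series is a strict two-endpoint mixture
  family and shows an exact isosbestic point; above saturation the coupled
  endpoint becomes heterogeneous from spectrum to spectrum (smaller,
  variable red shift), destroying the common crossing -- mirroring the loss
  of the isosbestic feature at high template concentration.
* noisy SAXS curves: Schulz-sphere form factor times sticky-hard-sphere
  structure factor with multiplicative (counting-statistics-like) Gaussian
  noise.
* sigmoidal spacing-calibration tables lambda_iso(<sp>) with additive
  Gaussian noise.

Every generator returns a machine-readable ground-truth record and is
bit-reproducible from (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isosbestic import MixtureSeries, mixture_spectrum, sigmoid_lambda_iso
from .saxs import SAXSProfile, SchulzSphereParams, SHSParams, intensity_model
from .spectra import DEFAULT_GRID, Spectrum

__all__ = [
    "SpectralScenario",
    "SAXSScenario",
    "parametric_endpoints",
    "generate_mixture_series",
    "generate_saxs_profile",
    "generate_calibration_set",
]

# Parametric (solver-independent) endpoint model -------------------------------
#
# The uncoupled endpoint is a Lorentzian at the single-particle resonance
# (524 nm, half-width GAMMA_UNCOUPLED).  The coupled endpoint keeps
# PRIMARY_RETAIN of that band and carries a second Lorentzian (half-width
# GAMMA_COUPLED) centred at mu(sp), a logistic (distance-dependent-coupling)
# map anchored at 609 nm for sp = 0.3 nm and 553 nm for sp = 0.8 nm.  The
# endpoint crossing is pinned at
#
#   lambda*(mu) = 524 + CROSS_SHIFT_FRACTION * (mu - 524)
#
# by solving the red-band amplitude from the crossing condition, so
# lambda_iso(sp) inherits the logistic shape exactly: plateaus 541.4 / 524
# nm, midpoint 0.55 nm, slope factor 0.2325 nm, passing through the
# observed isosbestic anchors 537 nm (sp = 0.3) and 528.4 nm (sp = 0.8) of
# the soft- and stiff-template assemblies.

PRIMARY_PEAK_NM = 524.0
RED_SHIFT_MAX_NM = 114.0       # red-band plateau shift as sp -> 0
RED_MIDPOINT_NM = 0.55         # logistic midpoint in sp, nm
RED_SLOPE_NM = 0.25 / np.log(85.0 / 29.0)   # ~0.2324, fixes both anchors
GAMMA_UNCOUPLED = 30.0         # half-width at half-maximum, nm
GAMMA_COUPLED = 45.0           # red band is broader than the primary band
PRIMARY_RETAIN = 0.75          # fraction of the 524-nm band kept on coupling
CROSS_SHIFT_FRACTION = 30.0 / 196.0   # crossing shift per unit band shift


def _lorentz(lam, center, gamma):
    return gamma**2 / ((lam - center) ** 2 + gamma**2)


def red_band_center(sp_nm: float) -> float:
    """Centre of the coupled (red) band vs surface spacing, nm."""
    return PRIMARY_PEAK_NM + RED_SHIFT_MAX_NM / (
        1.0 + np.exp((sp_nm - RED_MIDPOINT_NM) / RED_SLOPE_NM)
    )


def crossing_wavelength(red_center_nm: float) -> float:
    """Endpoint crossing pinned by the red-band centre, nm."""
    return PRIMARY_PEAK_NM + CROSS_SHIFT_FRACTION * (red_center_nm - PRIMARY_PEAK_NM)


def parametric_endpoints(sp_nm: float, wavelength_grid=None, red_center: float | None = None):
    """(coupled, uncoupled) parametric endpoint spectra for a given spacing.

    The red-band amplitude is solved from the crossing condition
    coupled(lambda*) = uncoupled(lambda*), so the pair crosses exactly at
    ``crossing_wavelength(red_band_center(sp_nm))``.
    """
    lam = np.asarray(
        DEFAULT_GRID if wavelength_grid is None else wavelength_grid, dtype=float
    )
    mu = red_band_center(sp_nm) if red_center is None else red_center
    lam_star = crossing_wavelength(mu)
    w_red = (1.0 - PRIMARY_RETAIN) * (
        _lorentz(lam_star, PRIMARY_PEAK_NM, GAMMA_UNCOUPLED)
        / _lorentz(lam_star, mu, GAMMA_COUPLED)
    )
    unc = _lorentz(lam, PRIMARY_PEAK_NM, GAMMA_UNCOUPLED)
    cpl = PRIMARY_RETAIN * unc + w_red * _lorentz(lam, mu, GAMMA_COUPLED)
    return (
        Spectrum(lam, cpl, channel="extinction"),
        Spectrum(lam, unc, channel="extinction"),
    )


@dataclass(frozen=True)
class SpectralScenario:
    """Study conditions for a concentration series of mixture spectra.

    Defaults reproduce the reference titration: nanoparticles at
    4.4e12 /mL, templates spanning 6e10-3.2e11 /mL (number ratios ~74/1
    down to ~14/1), saturation capacity N_sat = 14 nanoparticles per
    template, spacing sp = 0.3 nm for the soft-template (DOPC-like) cluster.
    """

    aunp_concentration: float = 4.4e12          # particles/mL
    template_concentrations: tuple = tuple(np.geomspace(6e10, 3.2e11, 8))
    n_sat: float = 14.0
    sp_nm: float = 0.3
    endpoint_source: str = "parametric_lorentzian"   # or "solver"
    noise_sigma: float = 0.0                    # additive, absorbance units
    seed: int = 0
    wavelength_grid: tuple | None = None
    #: tolerance band at the changeover: saturation holds while
    #: c_template * N_sat <= (1 + this) * c_AuNP
    saturation_tolerance: float = 0.05

    def __post_init__(self):
        if self.aunp_concentration <= 0 or self.n_sat <= 0:
            raise ValueError("concentrations and N_sat must be positive")
        c = np.asarray(self.template_concentrations, dtype=float)
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("template concentrations must be positive, increasing")
        if self.endpoint_source not in ("parametric_lorentzian", "solver"):
            raise ValueError("endpoint_source must be 'parametric_lorentzian' or 'solver'")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _solver_endpoints(sp_nm, grid):
    import warnings

    from .clusters import build_radial_geometry, solve_cluster_spectrum
    from .mie import mie_cross_sections

    geom = build_radial_geometry(sp_nm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = solve_cluster_spectrum(geom, wavelength_grid=grid)
    coupled = res.per_particle()[2]
    uncoupled = mie_cross_sections(6.0, wavelength_grid=grid)[2]
    # bring both to comparable (unit-peak) scale, like normalized absorbance
    cmax = coupled.values.max()
    return (
        Spectrum(coupled.wavelengths_nm, coupled.values / cmax, channel="extinction"),
        Spectrum(uncoupled.wavelengths_nm, uncoupled.values / cmax, channel="extinction"),
    )


def generate_mixture_series(scenario: SpectralScenario):
    """Concentration series of mixture spectra plus the ground-truth record.

    Returns ``(MixtureSeries, truth)`` where ``truth`` holds the coupled
    fractions, regime labels, endpoints and per-spectrum red-band centres.
    """
    rng = np.random.default_rng(scenario.seed)
    grid = (
        np.asarray(scenario.wavelength_grid, dtype=float)
        if scenario.wavelength_grid is not None
        else DEFAULT_GRID
    )
    if scenario.endpoint_source == "solver":
        coupled0, uncoupled = _solver_endpoints(scenario.sp_nm, grid)
    else:
        coupled0, uncoupled = parametric_endpoints(scenario.sp_nm, grid)

    c = np.asarray(scenario.template_concentrations, dtype=float)
    load = c * scenario.n_sat / scenario.aunp_concentration
    f = np.minimum(1.0, load)
    saturated = load <= 1.0 + scenario.saturation_tolerance

    mu0 = red_band_center(scenario.sp_nm)
    out_spectra = []
    red_centers = []
    for i, (fi, sat) in enumerate(zip(f, saturated)):
        if sat:
            coupled = coupled0
            red_centers.append(float(mu0))
        else:
            # heterogeneous clusters: smaller, randomly variable red shift
            # that shrinks further with template excess
            excess = load[i]  # > 1 + tolerance here
            jitter = rng.uniform(0.85, 1.0)
            mu_het = PRIMARY_PEAK_NM + (mu0 - PRIMARY_PEAK_NM) * jitter / excess
            red_centers.append(float(mu_het))
            coupled, _ = parametric_endpoints(scenario.sp_nm, grid, red_center=mu_het)
        spec = mixture_spectrum(fi, coupled, uncoupled)
        # observed spectra carry the absorbance channel: instrument noise can
        # legitimately push tail values below zero
        values = spec.values
        if scenario.noise_sigma > 0:
            values = values + rng.normal(0.0, scenario.noise_sigma, grid.size)
        out_spectra.append(Spectrum(grid, values, channel="absorbance"))

    series = MixtureSeries(
        spectra=out_spectra,
        coupled_fractions=f,
        template_concentrations=c,
        aunp_concentration=scenario.aunp_concentration,
    )
    truth = dict(
        coupled_fractions=f,
        regime=np.where(saturated, "saturation", "excess-template"),
        coupled_endpoint=coupled0,
        uncoupled_endpoint=uncoupled,
        red_band_centers=np.array(red_centers, dtype=float),
        number_ratio=scenario.aunp_concentration / c,
        sp_nm=scenario.sp_nm,
        seed=scenario.seed,
    )
    return series, truth


@dataclass(frozen=True)
class SAXSScenario:
    """Generating truth for one synthetic SAXS profile."""

    form: SchulzSphereParams = SchulzSphereParams()
    structure: SHSParams | None = SHSParams(volume_fraction=0.0189, stickiness=0.0634)
    scale: float = 1.0
    background: float = 0.0
    q_nm: tuple = tuple(np.geomspace(0.3, 3.0, 200))
    noise_fraction: float = 0.0      # multiplicative Gaussian
    seed: int = 0

    def __post_init__(self):
        if self.scale < 0 or self.background < 0 or self.noise_fraction < 0:
            raise ValueError("scale, background and noise fraction must be >= 0")
        q = np.asarray(self.q_nm, dtype=float)
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("Q grid must be positive and strictly increasing")


def generate_saxs_profile(scenario: SAXSScenario):
    """Synthetic I(Q) = scale*P*S + bg with multiplicative noise, plus truth."""
    rng = np.random.default_rng(scenario.seed)
    q = np.asarray(scenario.q_nm, dtype=float)
    clean = intensity_model(
        q, scenario.scale, scenario.background, scenario.form, scenario.structure
    )
    i = clean.intensity
    if scenario.noise_fraction > 0:
        noise = rng.normal(0.0, scenario.noise_fraction, q.size)
        i = i * (1.0 + noise)
        dI = scenario.noise_fraction * clean.intensity
        profile = SAXSProfile(q, i, dI=dI)
    else:
        profile = clean
    truth = dict(
        form=scenario.form,
        structure=scenario.structure,
        scale=scenario.scale,
        background=scenario.background,
        noise_fraction=scenario.noise_fraction,
        seed=scenario.seed,
        clean_intensity=clean.intensity,
    )
    return profile, truth


def generate_calibration_set(
    params=(538.0, 526.0, 0.7, 0.25),
    sp_grid=None,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """(sp, lambda_iso) table from the spacing sigmoid plus Gaussian noise.

    ``params`` is (lambda_A, lambda_B, sp0, k).  Returns (sp, lambda_iso,
    truth) with the generating parameters in ``truth``.
    """
    lambda_a, lambda_b, sp0, k = params
    if not (lambda_a > lambda_b and k > 0):
        raise ValueError("need lambda_A > lambda_B and k > 0")
    sp = (
        np.asarray(sp_grid, dtype=float)
        if sp_grid is not None
        else np.linspace(0.1, 1.6, 16)
    )
    if np.any(sp <= 0):
        raise ValueError("sp grid must be positive")
    rng = np.random.default_rng(seed)
    lam = sigmoid_lambda_iso(sp, lambda_a, lambda_b, sp0, k)
    if noise_sigma > 0:
        lam = lam + rng.normal(0.0, noise_sigma, sp.size)
    truth = dict(params=np.array(params), noise_sigma=noise_sigma, seed=seed)
    return sp, lam, truth
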
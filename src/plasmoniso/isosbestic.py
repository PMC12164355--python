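"""Isosbestic-point analysis of two-population plasmonic mixtures.

When a nanoparticle suspension contains exactly two spectral species -- free
(plasmonically uncoupled) particles and clustered (coupled) particles with
fixed structure -- every convex mixture f*coupled + (1-f)*uncoupled passes
through the wavelength where the two endpoint spectra cross.  That crossing,
the isosbestic wavelength lambda_iso, is independent of the mixing fraction
and therefore of the template (vesicle) concentration; it depends only on the
cluster's interparticle spacing <sp>.  The spacing dependence follows a
four-parameter sigmoid

    lambda_iso(<sp>) = (lambda_A - lambda_B) / (1 + exp((<sp> - sp0)/k)) + lambda_B

whose inversion turns a measured lambda_iso into a spacing estimate, and --
through a second monotone calibration -- into a membrane-stiffness estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model

from .clusters import SolverSettings, build_radial_geometry, solve_cluster_spectrum
from .materials import Medium
from .mie import mie_cross_sections
from .spectra import Spectrum, peak_wavelengths

__all__ = [
    "MixtureSeries",
    "IsosbesticResult",
    "FamilyResult",
    "SigmoidCalibration",
    "StiffnessCalibration",
    "AggregationIndex",
    "mixture_spectrum",
    "find_isosbestic",
    "isosbestic_from_family",
    "isosbestic_sweep",
    "sigmoid_lambda_iso",
    "fit_sigmoid",
    "invert_sigmoid",
    "aggregation_index",
    "classify_concentration_regime",
    "fit_stiffness_map",
    "invert_stiffness",
]

#: Default crossing-search window, nm.
DEFAULT_WINDOW = (450.0, 650.0)

#: Isosbestic "present" dispersion threshold, nm (experimental lambda_iso is
#: reported to +-1 nm; the family criterion is slightly looser).
DISPERSION_THRESHOLD_NM = 1.5


@dataclass
class MixtureSeries:
    """Ordered family of spectra indexed by coupled fraction/concentration."""

    spectra: list
    coupled_fractions: np.ndarray | None = None
    template_concentrations: np.ndarray | None = None  # particles/mL
    aunp_concentration: float | None = None            # particles/mL

    def __post_init__(self):
        if len(self.spectra) == 0:
            raise ValueError("empty series")
        g0 = self.spectra[0]
        for s in self.spectra[1:]:
            if not g0.same_grid(s):
                raise ValueError("all spectra in a series must share one grid")
        if self.coupled_fractions is not None:
            f = np.asarray(self.coupled_fractions, dtype=float)
            if f.shape != (len(self.spectra),) or np.any((f < 0) | (f > 1)):
                raise ValueError("coupled fractions must be in [0, 1], one per spectrum")
            self.coupled_fractions = f
        if self.template_concentrations is not None:
            c = np.asarray(self.template_concentrations, dtype=float)
            if np.any(c <= 0):
                raise ValueError("concentrations must be positive")
            self.template_concentrations = c

    def __len__(self):
        return len(self.spectra)


def mixture_spectrum(f: float, coupled: Spectrum, uncoupled: Spectrum) -> Spectrum:
    """Convex mixture f*coupled + (1-f)*uncoupled on the shared grid."""
    if not (0.0 <= f <= 1.0):
        raise ValueError("mixing fraction f must lie in [0, 1]")
    if not coupled.same_grid(uncoupled):
        raise ValueError("endpoint spectra must share one wavelength grid")
    return Spectrum(
        coupled.wavelengths_nm,
        f * coupled.values + (1.0 - f) * uncoupled.values,
        channel=coupled.channel,
    )


@dataclass(frozen=True)
class IsosbesticResult:
    """Crossing of two spectra: position (nm) or None, and crossing count."""

    lambda_iso: float | None
    n_crossings: int

    @property
    def found(self) -> bool:
        return self.lambda_iso is not None


def find_isosbestic(
    spec_a: Spectrum,
    spec_b: Spectrum,
    window: tuple = DEFAULT_WINDOW,
) -> IsosbesticResult:
    """Locate the isosbestic crossing of two spectra inside ``window``.

    Zero crossings of (A - B) are found by sign change and refined by linear
    interpolation.  With multiple crossings, the one closest to the primary
    peak of ``spec_b`` (the uncoupled/pivot population) is returned together
    with the total count.  Identical spectra are a degenerate input (error);
    no crossing at all yields ``IsosbesticResult(None, 0)``.
    """
    if not spec_a.same_grid(spec_b):
        raise ValueError("spectra must share one wavelength grid")
    lam = spec_a.wavelengths_nm
    sel = (lam >= window[0]) & (lam <= window[1])
    if sel.sum() < 2:
        raise ValueError("crossing window contains fewer than 2 grid points")
    x = lam[sel]
    d = spec_a.values[sel] - spec_b.values[sel]
    scale = max(np.abs(spec_a.values).max(), np.abs(spec_b.values).max())
    if np.abs(d).max() <= 1e-12 * scale:
        raise ValueError("degenerate input: spectra are identical within the window")

    sign = np.sign(d)
    crossings = []
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        x0 = x[i] - d[i] * (x[i + 1] - x[i]) / (d[i + 1] - d[i])
        crossings.append(float(x0))
    for i in np.flatnonzero(d == 0):
        crossings.append(float(x[i]))
    crossings = sorted(set(crossings))
    if not crossings:
        return IsosbesticResult(None, 0)
    try:
        peaks = peak_wavelengths(spec_b)
        pivot = max(peaks, key=lambda t: t[1])[0] if peaks else x[np.argmax(d)]
    except ValueError:
        pivot = float(np.mean(window))
    best = min(crossings, key=lambda c: abs(c - pivot))
    return IsosbesticResult(best, len(crossings))


@dataclass(frozen=True)
class FamilyResult:
    """Isosbestic statistics over a spectral family."""

    lambda_iso_mean: float | None
    dispersion_nm: float | None
    is_isosbestic: bool
    crossings: tuple


def isosbestic_from_family(
    series: MixtureSeries,
    window: tuple = DEFAULT_WINDOW,
    dispersion_threshold_nm: float = DISPERSION_THRESHOLD_NM,
) -> FamilyResult:
    """Pairwise crossings of consecutive spectra and the isosbestic verdict.

    The family shows a genuine isosbestic point when every consecutive pair
    crosses and the standard deviation of the crossing wavelengths stays
    within ``dispersion_threshold_nm``.
    """
    if len(series) < 3:
        raise ValueError("an isosbestic family needs at least 3 spectra")
    xs = []
    all_found = True
    for a, b in zip(series.spectra[1:], series.spectra[:-1]):
        try:
            res = find_isosbestic(a, b, window)
        except ValueError:
            all_found = False
            continue
        if res.found:
            xs.append(res.lambda_iso)
        else:
            all_found = False
    if len(xs) < 2:
        return FamilyResult(None, None, False, tuple(xs))
    mean = float(np.mean(xs))
    disp = float(np.std(xs))
    return FamilyResult(mean, disp, all_found and disp <= dispersion_threshold_nm, tuple(xs))


# ---------------------------------------------------------------------------
# lambda_iso vs <sp> sweep
# ---------------------------------------------------------------------------

def isosbestic_sweep(
    sp_values,
    endpoint_source: str = "parametric",
    medium: Medium | None = None,
    wavelength_grid=None,
    window: tuple = DEFAULT_WINDOW,
    radius_nm: float = 6.0,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Track lambda_iso as a function of <sp>.

    For each spacing the coupled endpoint is either the parametric
    two-Lorentzian cluster spectrum (``endpoint_source="parametric"``,
    solver-independent) or a coupled-dipole solve of the default radial
    63-particle geometry (``"solver"``); the uncoupled endpoint is the
    single-particle spectrum.  Rows where the crossing is absent or
    degenerate are flagged.

    Returns a DataFrame with columns sp_nm, lambda_iso_nm, n_crossings, found.
    """
    from .synth import parametric_endpoints  # local import to avoid cycle

    sp_values = np.asarray(sp_values, dtype=float)
    if np.any(sp_values <= 0):
        raise ValueError("sp values must be positive")
    medium = medium or Medium()
    rows = []
    for sp in sp_values:
        if endpoint_source == "parametric":
            coupled, uncoupled = parametric_endpoints(sp, wavelength_grid)
        elif endpoint_source == "solver":
            import warnings as _w

            geom = build_radial_geometry(sp, radius_nm)
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                res = solve_cluster_spectrum(
                    geom, medium, wavelength_grid, settings or SolverSettings()
                )
            coupled = res.per_particle()[2]
            uncoupled = mie_cross_sections(
                radius_nm, medium, coupled.wavelengths_nm
            )[2]
        else:
            raise ValueError("endpoint_source must be 'parametric' or 'solver'")
        try:
            res_iso = find_isosbestic(coupled, uncoupled, window)
            lam, n = res_iso.lambda_iso, res_iso.n_crossings
        except ValueError:
            lam, n = None, 0
        rows.append(
            dict(sp_nm=sp, lambda_iso_nm=lam, n_crossings=n, found=lam is not None)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sigmoidal spacing calibration
# ---------------------------------------------------------------------------

def sigmoid_lambda_iso(sp, lambda_a: float, lambda_b: float, sp0: float, k: float):
    """lambda_iso(<sp>) = (lambda_A - lambda_B)/(1 + exp((sp - sp0)/k)) + lambda_B."""
    sp = np.asarray(sp, dtype=float)
    return (lambda_a - lambda_b) / (1.0 + np.exp((sp - sp0) / k)) + lambda_b


@dataclass(frozen=True)
class SigmoidCalibration:
    """Fitted sigmoid lambda_iso(<sp>): parameters, covariance, diagnostics.

    lambda_a is the upper (small-spacing) plateau, lambda_b the lower
    (large-spacing) plateau, sp0 the inflection spacing, k > 0 the slope
    factor; predicted lambda_iso decreases strictly with <sp>.
    """

    lambda_a: float
    lambda_b: float
    sp0: float
    k: float
    covariance: np.ndarray = field(default=None, repr=False)
    residuals: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if not (self.lambda_a > self.lambda_b):
            raise ValueError("calibration requires lambda_a > lambda_b")
        if not (self.k > 0):
            raise ValueError("calibration requires slope factor k > 0")

    @property
    def params(self) -> np.ndarray:
        return np.array([self.lambda_a, self.lambda_b, self.sp0, self.k])

    def predict(self, sp):
        return sigmoid_lambda_iso(sp, *self.params)

    @property
    def stderr(self) -> np.ndarray:
        if self.covariance is None:
            return np.full(4, np.nan)
        return np.sqrt(np.diag(self.covariance))


def _map_covariance(out) -> np.ndarray | None:
    """Covariance of (lambda_a, lambda_b, sp0/s0, k) from an lmfit result.

    The fits parameterize lambda_a = lambda_b + delta (delta > 0 enforces
    ordering), so the raw covariance over the free parameters is mapped back
    by the constant Jacobian of that reparameterization.
    """
    if out.covar is None:
        return None
    names = ["lambda_a", "lambda_b", "sp0", "k"]
    J = np.zeros((4, len(out.var_names)))
    for col, vn in enumerate(out.var_names):
        if vn == "delta":
            J[0, col] = 1.0
        elif vn in names:
            J[names.index(vn), col] = 1.0
            if vn == "lambda_b":
                J[0, col] += 1.0  # lambda_a = lambda_b + delta
    return J @ out.covar @ J.T


def fit_sigmoid(sp, lambda_iso, weights=None) -> SigmoidCalibration:
    """Nonlinear least-squares fit of the lambda_iso(<sp>) sigmoid.

    Initialization: plateaus from the observed max/min, sp0 from the abscissa
    of the steepest numerical gradient, k from the quartile spread of sp.
    Bounds enforce k > 0 and lambda_a > lambda_b.
    """
    sp = np.asarray(sp, dtype=float)
    lam = np.asarray(lambda_iso, dtype=float)
    if sp.size != lam.size or sp.size < 5:
        raise ValueError("sigmoid fit needs >= 5 (sp, lambda_iso) points")

    order = np.argsort(sp)
    sps, lams = sp[order], lam[order]
    grad = np.gradient(lams, sps)
    sp0_init = float(sps[np.argmin(grad)])  # steepest descent
    k_init = max(float(np.subtract(*np.percentile(sps, [75, 25]))) / 4.0, 1e-3)

    model = Model(sigmoid_lambda_iso, independent_vars=["sp"])
    pars = model.make_params(
        lambda_a=float(lams.max()),
        lambda_b=float(lams.min()),
        sp0=sp0_init,
        k=k_init,
    )
    pars["k"].set(min=1e-6)
    # soft ordering: keep the difference positive via a bounded delta param
    pars.add("delta", value=float(lams.max() - lams.min()) or 1.0, min=1e-9)
    pars["lambda_a"].set(expr="lambda_b + delta")

    out = model.fit(lams, pars, sp=sps, weights=weights)
    if not np.isfinite(out.chisqr):
        raise RuntimeError(
            "sigmoid fit failed to converge "
            f"(init: lambda_a={lams.max():g}, lambda_b={lams.min():g}, "
            f"sp0={sp0_init:g}, k={k_init:g}): {out.message}"
        )
    # a missing covariance signals ill-conditioning (e.g. one-flank data);
    # the calibration is still returned, with cov = None
    cov = _map_covariance(out)
    return SigmoidCalibration(
        lambda_a=float(out.params["lambda_a"].value),
        lambda_b=float(out.params["lambda_b"].value),
        sp0=float(out.params["sp0"].value),
        k=float(out.params["k"].value),
        covariance=cov,
        residuals=np.asarray(out.residual),
    )


def invert_sigmoid(
    lambda_iso: float,
    cal: SigmoidCalibration,
    sigma_lambda: float = 0.0,
) -> tuple[float, float]:
    """Invert the sigmoid: spacing <sp> (nm) and its 1-sigma uncertainty.

    <sp> = sp0 + k * ln((lambda_A - lambda_B)/(lambda_iso - lambda_B) - 1);
    requires lambda_B < lambda_iso < lambda_A strictly.  Uncertainty combines
    first-order propagation of ``sigma_lambda`` with the calibration's
    parameter covariance (when available).
    """
    la, lb, sp0, k = cal.params
    if not (lb < lambda_iso < la):
        raise ValueError(
            f"lambda_iso = {lambda_iso} nm outside the open calibration range "
            f"({lb:.6g}, {la:.6g}) nm"
        )
    ratio = (la - lb) / (lambda_iso - lb) - 1.0
    sp = sp0 + k * np.log(ratio)

    # sp = sp0 + k [ln(D - u) - ln u] with D = la - lb, u = lambda_iso - lb
    u = lambda_iso - lb
    D = la - lb
    d_la = k / (D - u)
    d_lb = k / u                    # dD/dlb = du/dlb = -1; the (D-u) term cancels
    d_sp0 = 1.0
    d_k = float(np.log(ratio))
    d_lam = -k * (1.0 / (D - u) + 1.0 / u)

    var = (d_lam * sigma_lambda) ** 2
    if cal.covariance is not None:
        g = np.array([d_la, d_lb, d_sp0, d_k])
        var += float(g @ cal.covariance @ g)
    return float(sp), float(np.sqrt(var))


# ---------------------------------------------------------------------------
# aggregation index and concentration regimes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggregationIndex:
    """Aggregation-index value with the definition it was computed under."""

    value: float
    definition: str


def aggregation_index(spectrum: Spectrum, definition: str = "band_ratio") -> AggregationIndex:
    """Scalar clustering descriptor of an extinction spectrum.

    ``"band_ratio"`` (default): integral over 600-700 nm divided by the
    integral over 500-600 nm -- grows as spectral weight moves into the
    coupled (red) band.  ``"peak_ratio"``: value at 650 nm divided by the
    value at the primary peak.  The definition used is recorded in the
    result.
    """
    lam = spectrum.wavelengths_nm
    if lam[0] > 500.0 or lam[-1] < 700.0:
        raise ValueError("aggregation index needs spectral coverage of 500-700 nm")
    if definition == "band_ratio":
        grid = np.linspace(500.0, 700.0, 401)
        vals = np.interp(grid, lam, spectrum.values)
        red = np.trapezoid(vals[grid >= 600.0], grid[grid >= 600.0])
        green = np.trapezoid(vals[grid <= 600.0], grid[grid <= 600.0])
        if green == 0:
            raise ValueError("zero 500-600 nm band integral")
        return AggregationIndex(float(red / green), definition)
    if definition == "peak_ratio":
        peaks = peak_wavelengths(spectrum)
        pivot = max(peaks, key=lambda t: t[1])[0] if peaks else lam[np.argmax(spectrum.values)]
        return AggregationIndex(
            float(spectrum.value_at(650.0) / spectrum.value_at(pivot)), definition
        )
    raise ValueError(f"unknown aggregation-index definition {definition!r}")


def classify_concentration_regime(series: MixtureSeries, definition: str = "band_ratio") -> pd.DataFrame:
    """Label each spectrum saturation (nanoparticle excess) vs excess-template.

    The aggregation index rises with template concentration while free
    nanoparticles remain in excess (clusters saturate each template) and
    falls once templates outnumber the nanoparticle supply; the regime
    boundary is placed at the AI maximum.  Isosbestic analysis is valid only
    within the saturation regime.
    """
    if series.template_concentrations is None:
        raise ValueError("series must carry template concentrations")
    c = series.template_concentrations
    if np.any(np.diff(c) <= 0):
        raise ValueError("template concentrations must be strictly increasing")
    ai = np.array(
        [aggregation_index(s, definition).value for s in series.spectra]
    )
    i_max = int(np.argmax(ai))
    regime = np.where(
        np.arange(len(series)) <= i_max, "saturation", "excess-template"
    )
    return pd.DataFrame(
        dict(
            template_concentration=c,
            aggregation_index=ai,
            regime=regime,
            ai_definition=definition,
        )
    )


# ---------------------------------------------------------------------------
# membrane-stiffness calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StiffnessCalibration:
    """Monotone sigmoid map stiffness -> lambda_iso with inverse.

    Same functional family as the spacing sigmoid, with stiffness (N/m) as
    abscissa: softer membranes pack particles closer and give larger
    lambda_iso.
    """

    lambda_a: float
    lambda_b: float
    s0: float
    k: float
    covariance: np.ndarray = field(default=None, repr=False)

    def predict(self, stiffness):
        return sigmoid_lambda_iso(stiffness, self.lambda_a, self.lambda_b, self.s0, self.k)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.lambda_a, self.lambda_b, self.s0, self.k])


def fit_stiffness_map(stiffness, lambda_iso, noise_tolerance_nm: float = 1.0) -> StiffnessCalibration:
    """Fit the monotone stiffness -> lambda_iso sigmoid.

    Requires >= 4 pairs with a decreasing trend (lambda_iso falls as
    stiffness grows); a non-monotone trend beyond ``noise_tolerance_nm``
    raises a calibration error.
    """
    s = np.asarray(stiffness, dtype=float)
    lam = np.asarray(lambda_iso, dtype=float)
    if s.size != lam.size or s.size < 4:
        raise ValueError("stiffness calibration needs >= 4 pairs")
    order = np.argsort(s)
    s, lam = s[order], lam[order]
    if np.any(np.diff(lam) > noise_tolerance_nm):
        raise ValueError("lambda_iso does not decrease monotonically with stiffness")

    model = Model(sigmoid_lambda_iso, independent_vars=["sp"])
    pars = model.make_params(
        lambda_a=float(lam.max()),
        lambda_b=float(lam.min()) - 0.5,
        sp0=float(np.median(s)),
        k=max(float(np.ptp(s)) / 6.0, 1e-5),
    )
    pars["k"].set(min=1e-9)
    pars.add("delta", value=float(np.ptp(lam)) or 1.0, min=1e-9)
    pars["lambda_a"].set(expr="lambda_b + delta")
    out = model.fit(lam, pars, sp=s)
    if not np.isfinite(out.chisqr):
        raise RuntimeError(f"stiffness calibration failed: {out.message}")
    cov = _map_covariance(out)
    return StiffnessCalibration(
        lambda_a=float(out.params["lambda_a"].value),
        lambda_b=float(out.params["lambda_b"].value),
        s0=float(out.params["sp0"].value),
        k=float(out.params["k"].value),
        covariance=cov,
    )


def invert_stiffness(
    lambda_iso: float,
    cal: StiffnessCalibration,
    sigma_lambda: float = 0.0,
) -> tuple[float, float]:
    """Stiffness (N/m) and uncertainty from a measured lambda_iso."""
    proxy = SigmoidCalibration(
        lambda_a=cal.lambda_a, lambda_b=cal.lambda_b, sp0=cal.s0, k=cal.k,
        covariance=cal.covariance,
    )
    return invert_sigmoid(lambda_iso, proxy, sigma_lambda)
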
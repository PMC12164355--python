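"""Spectrum container and generic spectral utilities (peaks, resampling)."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

__all__ = ["Spectrum", "peak_wavelengths", "DEFAULT_GRID"]

#: Default simulation grid: 400-800 nm at 1 nm resolution.
DEFAULT_GRID = np.arange(400.0, 801.0, 1.0)


@dataclass(frozen=True)
class Spectrum:
    """A sampled optical spectrum on a strictly increasing wavelength grid.

    ``values`` may be cross sections (nm^2), absorbance (dimensionless) or any
    per-wavelength channel; ``channel`` records which.  Cross-section channels
    are validated to be non-negative.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    channel: str = "extinction"
    normalized: bool = False

    def __post_init__(self):
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if lam.ndim != 1 or lam.shape != val.shape:
            raise ValueError("wavelengths and values must be matching 1-d arrays")
        if lam.size < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(val)):
            raise ValueError("spectrum values must be finite")
        if self.channel in ("absorption", "scattering", "extinction") and np.any(
            val < -1e-9 * max(1.0, np.abs(val).max())
        ):
            raise ValueError(f"{self.channel} cross sections must be >= 0")
        object.__setattr__(self, "wavelengths_nm", lam)
        object.__setattr__(self, "values", val)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def value_at(self, wavelength_nm: float) -> float:
        """Linear interpolation at a single wavelength (must be in range)."""
        lam = self.wavelengths_nm
        if not (lam[0] <= wavelength_nm <= lam[-1]):
            raise ValueError(
                f"{wavelength_nm} nm outside spectrum range [{lam[0]}, {lam[-1]}]"
            )
        return float(np.interp(wavelength_nm, lam, self.values))

    def interp_to(self, grid) -> "Spectrum":
        """Resample onto ``grid`` by linear interpolation (grid must be inside)."""
        grid = np.asarray(grid, dtype=float)
        lam = self.wavelengths_nm
        if grid[0] < lam[0] - 1e-9 or grid[-1] > lam[-1] + 1e-9:
            raise ValueError("target grid extends beyond the spectrum support")
        return replace(
            self, wavelengths_nm=grid, values=np.interp(grid, lam, self.values)
        )

    def normalize_at(self, wavelength_nm: float = 350.0, tol_nm: float = 1.0) -> "Spectrum":
        """Divide by the value at the grid point nearest ``wavelength_nm``.

        The anchor must lie within ``tol_nm`` of an actual sample; the
        conventional anchor for experimental extinction spectra is 350 nm.
        """
        lam = self.wavelengths_nm
        i = int(np.argmin(np.abs(lam - wavelength_nm)))
        if abs(lam[i] - wavelength_nm) > tol_nm:
            raise ValueError(
                f"no grid point within {tol_nm} nm of the {wavelength_nm} nm anchor"
            )
        anchor = self.values[i]
        if anchor == 0:
            raise ValueError("cannot normalize: anchor value is zero")
        return replace(self, values=self.values / anchor, normalized=True)

    def same_grid(self, other: "Spectrum", tol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and bool(np.allclose(self.wavelengths_nm, other.wavelengths_nm, atol=tol))
        )


def _quadratic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid extremum position from a parabola through points i-1, i, i+1."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(x[i] + delta * (x[min(i + 1, len(x) - 1)] - x[i]))


def peak_wavelengths(spectrum: Spectrum, min_prominence: float = 0.02):
    """Locate local maxima of a spectrum.

    Parameters
    ----------
    spectrum:
        Input spectrum with at least 5 samples.
    min_prominence:
        Minimum peak prominence as a fraction of the spectrum maximum.

    Returns
    -------
    list of (wavelength_nm, prominence_fraction) sorted by wavelength; the
    peak position is refined below the grid step by quadratic interpolation
    through the three samples around each maximum.  A flat or monotone
    spectrum yields an empty list.
    """
    if len(spectrum) < 5:
        raise ValueError("peak finding needs a spectrum with >= 5 samples")
    y = spectrum.values
    ymax = float(np.max(np.abs(y)))
    if ymax == 0 or np.ptp(y) == 0:
        return []
    idx, props = find_peaks(y, prominence=min_prominence * ymax)
    out = []
    for i, prom in zip(idx, props["prominences"]):
        out.append((_quadratic_refine(spectrum.wavelengths_nm, y, int(i)), float(prom / ymax)))
    out.sort(key=lambda t: t[0])
    return out
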
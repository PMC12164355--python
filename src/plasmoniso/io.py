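"""Text readers/writers for spectra, SAXS profiles, geometries, calibrations.

All formats are plain delimited text with '#' comment headers, the exchange
formats of bench UV-vis and reduced SAXS data.  Wavelengths and lengths are
nm, Q is nm^-1 internally; unit conversion happens only at these boundaries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .clusters import ClusterGeometry
from .isosbestic import SigmoidCalibration, StiffnessCalibration
from .saxs import SAXSProfile
from .spectra import Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_saxs_profile",
    "write_saxs_profile",
    "read_geometry",
    "write_geometry",
    "read_calibration",
    "write_calibration",
    "RunConfig",
]


def _numeric_rows(path, n_min_cols: int):
    rows = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as err:
                raise ValueError(f"{path}: non-numeric content at line {ln}") from err
            if len(vals) < n_min_cols:
                raise ValueError(
                    f"{path}: expected >= {n_min_cols} columns at line {ln}"
                )
            rows.append((ln, vals))
    return rows


def read_spectrum(path, normalize_350: bool = False, channel: str = "extinction") -> Spectrum:
    """Read a 2-column (wavelength_nm, value) text spectrum.

    Wavelengths are sorted ascending; duplicate wavelengths are rejected with
    the offending line number.  With ``normalize_350`` the spectrum is
    divided by its value at the grid point nearest 350 nm (within 1 nm).
    """
    rows = _numeric_rows(path, 2)
    if len(rows) < 5:
        raise ValueError(f"{path}: a spectrum needs at least 5 data rows")
    lam = np.array([v[0] for _, v in rows])
    val = np.array([v[1] for _, v in rows])
    order = np.argsort(lam)
    lam, val = lam[order], val[order]
    dup = np.flatnonzero(np.diff(lam) == 0)
    if dup.size:
        ln = rows[int(np.argsort([v[0] for _, v in rows])[dup[0] + 1])][0]
        raise ValueError(f"{path}: duplicate wavelength near line {ln}")
    spec = Spectrum(lam, val, channel=channel)
    if normalize_350:
        spec = spec.normalize_at(350.0)
    return spec


def write_spectrum(spectrum: Spectrum, path) -> None:
    header = (
        f"wavelength_nm  {spectrum.channel}"
        + ("  (normalized at 350 nm)" if spectrum.normalized else "")
    )
    np.savetxt(
        path,
        np.column_stack([spectrum.wavelengths_nm, spectrum.values]),
        header=header,
        fmt="%.17g",
    )


def read_saxs_profile(path, unit: str = "nm^-1") -> SAXSProfile:
    """Read a 2-3 column (Q, I[, dI]) text profile; unit 'nm^-1' or 'A^-1'."""
    rows = _numeric_rows(path, 2)
    if len(rows) < 5:
        raise ValueError(f"{path}: a profile needs at least 5 data rows")
    q = np.array([v[0] for _, v in rows])
    i = np.array([v[1] for _, v in rows])
    has_di = all(len(v) >= 3 for _, v in rows)
    di = np.array([v[2] for _, v in rows]) if has_di else None
    order = np.argsort(q)
    return SAXSProfile.from_arrays(
        q[order], i[order], di[order] if di is not None else None, unit=unit
    )


def write_saxs_profile(profile: SAXSProfile, path) -> None:
    cols = [profile.q_nm, profile.intensity]
    names = "Q_nm^-1  I"
    if profile.dI is not None:
        cols.append(profile.dI)
        names += "  dI"
    np.savetxt(path, np.column_stack(cols), header=names, fmt="%.17g")


def write_geometry(geometry: ClusterGeometry, path) -> None:
    """id, x, y, z (nm), radius (nm), subgroup as delimited text."""
    n = geometry.n_particles
    data = np.column_stack(
        [
            np.arange(n),
            geometry.centers,
            geometry.radii,
            geometry.subgroup_ids,
        ]
    )
    header = (
        f"arrangement={geometry.arrangement} sp_nominal_nm={geometry.sp_nominal}\n"
        "id  x_nm  y_nm  z_nm  radius_nm  subgroup"
    )
    np.savetxt(path, data, header=header, fmt="%.16g")


def read_geometry(path) -> ClusterGeometry:
    arrangement, sp_nominal = "radial_2d", 1.0
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") and "arrangement=" in raw:
                for tok in raw[1:].split():
                    if tok.startswith("arrangement="):
                        arrangement = tok.split("=", 1)[1]
                    if tok.startswith("sp_nominal_nm="):
                        sp_nominal = float(tok.split("=", 1)[1])
    data = np.loadtxt(path, comments="#", ndmin=2)
    return ClusterGeometry(
        centers=data[:, 1:4],
        radii=data[:, 4],
        subgroup_ids=data[:, 5].astype(int),
        sp_nominal=sp_nominal,
        arrangement=arrangement,
    )


# ---------------------------------------------------------------------------
# calibration documents
# ---------------------------------------------------------------------------

_CAL_KINDS = {"sigmoid_sp": SigmoidCalibration, "sigmoid_stiffness": StiffnessCalibration}


def write_calibration(cal, path) -> None:
    """Key/value text document with the 4x4 parameter covariance."""
    if isinstance(cal, SigmoidCalibration):
        kind, names = "sigmoid_sp", ["lambda_a", "lambda_b", "sp0", "k"]
        vals = cal.params
    elif isinstance(cal, StiffnessCalibration):
        kind, names = "sigmoid_stiffness", ["lambda_a", "lambda_b", "s0", "k"]
        vals = cal.params
    else:
        raise TypeError(f"cannot serialize calibration of type {type(cal)!r}")
    lines = [f"kind = {kind}"]
    lines += [f"{n} = {v:.12g}" for n, v in zip(names, vals)]
    if cal.covariance is not None:
        for i, row in enumerate(np.asarray(cal.covariance)):
            lines.append(f"cov_{i} = " + " ".join(f"{x:.12g}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibration(path):
    kv = {}
    cov_rows = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: expected 'key = value' at line {ln}")
        key, val = (t.strip() for t in line.split("=", 1))
        if key.startswith("cov_"):
            cov_rows[int(key[4:])] = [float(x) for x in val.split()]
        else:
            kv[key] = val
    kind = kv.pop("kind", "sigmoid_sp")
    if kind not in _CAL_KINDS:
        raise ValueError(f"{path}: unknown calibration kind {kind!r}")
    cov = None
    if cov_rows:
        cov = np.array([cov_rows[i] for i in sorted(cov_rows)])
    if kind == "sigmoid_sp":
        return SigmoidCalibration(
            lambda_a=float(kv["lambda_a"]),
            lambda_b=float(kv["lambda_b"]),
            sp0=float(kv["sp0"]),
            k=float(kv["k"]),
            covariance=cov,
        )
    return StiffnessCalibration(
        lambda_a=float(kv["lambda_a"]),
        lambda_b=float(kv["lambda_b"]),
        s0=float(kv["s0"]),
        k=float(kv["k"]),
        covariance=cov,
    )


@dataclass
class RunConfig:
    """Resolved analysis configuration, embedded in every output for audit."""

    medium_index: float = 1.343
    grid_start_nm: float = 400.0
    grid_stop_nm: float = 800.0
    grid_step_nm: float = 1.0
    window_lo_nm: float = 450.0
    window_hi_nm: float = 650.0
    dispersion_threshold_nm: float = 1.5
    ai_definition: str = "band_ratio"
    shs_epsilon: float = 0.02
    sigma_hc_rule: str = "2*R_core"
    seed: int = 0
    output_dir: str = "."

    def wavelength_grid(self) -> np.ndarray:
        return np.arange(
            self.grid_start_nm, self.grid_stop_nm + self.grid_step_nm / 2,
            self.grid_step_nm,
        )

    def to_file(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kv = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: expected 'key = value' at line {ln}")
            key, val = (t.strip() for t in line.split("=", 1))
            kv[key] = val
        fields = cls.__dataclass_fields__
        kwargs = {}
        for key, val in kv.items():
            if key not in fields:
                raise ValueError(f"{path}: unknown config key {key!r}")
            typ = fields[key].type
            if typ in ("float", float):
                kwargs[key] = float(val)
            elif typ in ("int", int):
                kwargs[key] = int(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_json_dict(self) -> dict:
        return asdict(self)


def write_report(path, *, inputs, config: RunConfig, lambda_iso=None,
                 dispersion=None, sp_estimate=None, stiffness_estimate=None,
                 warnings=()) -> None:
    """JSON analysis report with the resolved configuration embedded."""
    doc = dict(
        inputs=list(map(str, inputs)),
        config=config.to_json_dict(),
        lambda_iso=lambda_iso,
        dispersion=dispersion,
        sp_estimate=sp_estimate,
        stiffness_estimate=stiffness_estimate,
        warnings=list(warnings),
    )
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
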
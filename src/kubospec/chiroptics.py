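"""UV-VIS absorption, circular dichroism and optical rotatory dispersion
from electronic transition data.

Each electronic transition carries a wavelength, an electric (mu) and a
magnetic (m) transition-dipole 3-vector in atomic units.  Its rotational
strength is the scalar product R = mu . m: the CD band sign, and hence the
sign of the high-frequency wing of the associated ORD dispersion lobe, is
positive exactly when the angle between mu and m is below 90 degrees.

Band shapes are Lorentzian on the wavenumber axis (nu = 1e7/lambda_nm);
ORD follows from CD by the Kramers-Kronig transform

    phi(nu) = (2/pi) P int nu' d_eps(nu') / (nu'^2 - nu^2) dnu',

evaluated with the MacLaurin (alternating-point) principal-value
quadrature.  Absolute intensity scales default to 1 (arbitrary units):
the modelling targets band positions and signs, not molar amplitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectra import Spectrum1D

__all__ = [
    "ElectronicTransition",
    "BandShape",
    "rotational_strength",
    "cd_spectrum",
    "kramers_kronig_ord",
    "inverse_kramers_kronig",
    "uvvis_absorption",
    "read_transitions",
    "write_transitions",
]


@dataclass(frozen=True)
class ElectronicTransition:
    """One electronic transition: wavelength (nm), electric and magnetic
    transition-dipole 3-vectors (a.u.), oscillator strength."""

    wavelength: float
    mu: tuple[float, float, float] = (0.0, 0.0, 0.0)
    m: tuple[float, float, float] = (0.0, 0.0, 0.0)
    f_osc: float = 0.0

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")
        if self.f_osc < 0:
            raise ValueError("oscillator strength must be >= 0")
        object.__setattr__(self, "mu", tuple(float(x) for x in self.mu))
        object.__setattr__(self, "m", tuple(float(x) for x in self.m))

    @property
    def wavenumber(self) -> float:
        """Transition energy in cm^-1."""
        return 1e7 / self.wavelength


@dataclass(frozen=True)
class BandShape:
    """Lorentzian band profile; ``gamma`` is the half-width at half maximum
    in the stated unit ('nm' widths are converted per band)."""

    gamma: float
    unit: str = "cm-1"

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("band width must be positive")
        if self.unit not in ("cm-1", "nm"):
            raise ValueError("band width unit must be 'cm-1' or 'nm'")

    def gamma_wavenumber(self, nu0: float) -> float:
        """HWHM in cm^-1 at band center nu0 (cm^-1); nm widths are
        converted with the local dispersion d(nu)/d(lambda) = -1e7/lambda^2."""
        if self.unit == "cm-1":
            return self.gamma
        lam0 = 1e7 / nu0
        return 1e7 * self.gamma / lam0**2


def rotational_strength(t: ElectronicTransition) -> float:
    """Rotational strength R = mu . m (a.u.); sign(R) = sign(cos theta)."""
    mu = np.asarray(t.mu)
    m = np.asarray(t.m)
    if np.linalg.norm(mu) == 0 or np.linalg.norm(m) == 0:
        warnings.warn("zero-norm transition dipole: R = 0", stacklevel=2)
        return 0.0
    return float(np.dot(mu, m))


def _lorentzian(nu: np.ndarray, nu0: float, gamma: float) -> np.ndarray:
    """Unit-area Lorentzian on the wavenumber axis, HWHM gamma."""
    return (gamma / np.pi) / ((nu - nu0) ** 2 + gamma**2)


def _nm_grid_to_wavenumber(grid_nm: np.ndarray):
    nu = 1e7 / np.asarray(grid_nm, dtype=float)[::-1]
    return nu


def cd_spectrum(
    transitions: list[ElectronicTransition],
    shape: BandShape,
    grid_nm: np.ndarray,
    scale: float = 1.0,
) -> Spectrum1D:
    """Circular dichroism spectrum on a wavelength grid (nm).

    d_eps(nu) = scale * sum_i R_i * (nu/nu_i) * L(nu; nu_i, Gamma), with L
    a unit-area Lorentzian on the wavenumber axis.
    """
    grid_nm = np.asarray(grid_nm, dtype=float)
    nu = 1e7 / grid_nm
    vals = np.zeros_like(nu)
    for t in transitions:
        R = rotational_strength(t) if (any(t.mu) and any(t.m)) else 0.0
        if R == 0.0:
            continue
        nu0 = t.wavenumber
        vals += R * (nu / nu0) * _lorentzian(nu, nu0, shape.gamma_wavenumber(nu0))
    return Spectrum1D(grid_nm, scale * vals, axis_unit="nm", value_unit="a.u.")


def uvvis_absorption(
    transitions: list[ElectronicTransition],
    shape: BandShape,
    grid_nm: np.ndarray,
    scale: float = 1.0,
) -> Spectrum1D:
    """Electronic absorption spectrum: eps(nu) ~ sum_i f_i L(nu; nu_i, G)."""
    grid_nm = np.asarray(grid_nm, dtype=float)
    nu = 1e7 / grid_nm
    vals = np.zeros_like(nu)
    for t in transitions:
        nu0 = t.wavenumber
        vals += t.f_osc * _lorentzian(nu, nu0, shape.gamma_wavenumber(nu0))
    return Spectrum1D(grid_nm, scale * vals, axis_unit="nm", value_unit="a.u.")


def _maclaurin_kk(nu: np.ndarray, f: np.ndarray, sign: float, weight: str) -> np.ndarray:
    """MacLaurin principal-value quadrature of the KK kernel on a uniform
    wavenumber grid: points of parity opposite to the evaluation point are
    summed with doubled spacing, which skips the singularity at machine
    precision cost ~ h^2."""
    h = nu[1] - nu[0]
    out = np.empty_like(f)
    nu2 = nu**2
    for parity in (0, 1):
        src = slice(1 - parity, None, 2)
        nus, fs = nu[src], f[src]
        tgt = np.arange(parity, nu.size, 2)
        denom = nus[None, :] ** 2 - nu2[tgt, None]
        if weight == "nu_prime":
            kern = nus[None, :] * fs[None, :] / denom
        else:  # weight nu (inverse transform)
            kern = nu[tgt, None] * fs[None, :] / denom
        out[tgt] = kern.sum(axis=1)
    return sign * (2.0 / np.pi) * 2.0 * h * out


def _kk_check_margin(nu: np.ndarray, f: np.ndarray) -> None:
    edge = max(abs(f[0]), abs(f[-1]))
    peak = np.max(np.abs(f)) or 1.0
    if edge > 0.01 * peak:
        warnings.warn(
            "CD grid may be too narrow for the Kramers-Kronig transform: "
            f"edge amplitude is {edge / peak:.1%} of the peak (truncation "
            "error of the same order)",
            stacklevel=3,
        )


def kramers_kronig_ord(cd: Spectrum1D) -> Spectrum1D:
    """Optical rotatory dispersion from a CD spectrum.

    phi(nu) = (2/pi) P int nu' d_eps(nu') / (nu'^2 - nu^2) dnu'.  The input
    may be sampled on a uniform wavelength (nm) or wavenumber (cm^-1) axis;
    internally the transform runs on a uniform wavenumber grid, which must
    extend well beyond the outermost band (a truncation warning is issued
    otherwise).  For a single Lorentzian CD band the result matches the
    closed-form dispersive Lorentzian; a positive band yields a positive
    high-frequency wing.

    The overall sign fixes the rotation-direction convention: it is chosen
    so that a band of positive rotational strength (mu-m angle below 90
    degrees) has a positive dispersion wing on its high-frequency side.
    """
    if cd.axis_unit == "nm":
        nu_raw = 1e7 / cd.axis[::-1]
        f_raw = cd.values[::-1]
        nu = np.linspace(nu_raw[0], nu_raw[-1], max(4 * nu_raw.size, 2048))
        f = np.interp(nu, nu_raw, f_raw)
    else:
        nu, f = cd.axis, cd.values
        steps = np.diff(nu)
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("KK transform needs a uniform wavenumber grid")
    _kk_check_margin(nu, f)
    phi = _maclaurin_kk(nu, f, sign=-1.0, weight="nu_prime")
    if cd.axis_unit == "nm":
        phi_nm = np.interp(1e7 / cd.axis[::-1], nu, phi)[::-1]
        return Spectrum1D(cd.axis, phi_nm, axis_unit="nm", value_unit="a.u.")
    return Spectrum1D(nu, phi, axis_unit="cm-1", value_unit="a.u.")


def inverse_kramers_kronig(ord_spec: Spectrum1D) -> Spectrum1D:
    """Recover CD from ORD: the inverse dispersion relation with the sign
    convention of :func:`kramers_kronig_ord` (uniform wavenumber axis
    required)."""
    if ord_spec.axis_unit != "cm-1":
        raise ValueError("inverse transform expects a wavenumber axis")
    nu, f = ord_spec.axis, ord_spec.values
    vals = _maclaurin_kk(nu, f, sign=+1.0, weight="nu")
    return Spectrum1D(nu, vals, axis_unit="cm-1", value_unit="a.u.")


def write_transitions(transitions: list[ElectronicTransition], path: str | Path) -> None:
    """TSV: wavelength_nm f_osc mu_x mu_y mu_z m_x m_y m_z."""
    with open(path, "w") as fh:
        fh.write("# columns: wavelength_nm f_osc mu_x mu_y mu_z m_x m_y m_z\n")
        for t in transitions:
            row = [t.wavelength, t.f_osc, *t.mu, *t.m]
            fh.write("\t".join(f"{x:.8g}" for x in row) + "\n")


def read_transitions(path: str | Path) -> list[ElectronicTransition]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 8:
                raise ValueError(f"{path}: line {lineno}: expected 8 columns")
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
            out.append(
                ElectronicTransition(
                    wavelength=vals[0],
                    f_osc=vals[1],
                    mu=tuple(vals[2:5]),
                    m=tuple(vals[5:8]),
                )
            )
    if not out:
        raise ValueError(f"{path}: empty transition table")
    return out
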
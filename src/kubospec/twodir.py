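"""Absorptive 2DIR spectra by the second-order cumulant expansion.

Each resonance contributes rephasing and non-rephasing Liouville pathways.
With a common line-broadening function g(t) the pathway line-shape factors
are

    rephasing:      exp[-g(t1) + g(t2) - g(t3) - g(t1+t2) - g(t2+t3)
                        + g(t1+t2+t3)]
    non-rephasing:  exp[-g(t1) - g(t2) - g(t3) + g(t1+t2) + g(t2+t3)
                        - g(t1+t2+t3)]

Ground-state bleach / stimulated emission (negative) appears at
(pump, probe) = (w01, w01) and excited-state absorption (positive) at
(w01, w12).  Cross peaks between coupled modes i and j carry a bleach at
(w01_i, w01_j) and an ESA at (w01_i, w01_j + x_ij); when the off-diagonal
anharmonicity x_ij vanishes the two cancel exactly.  For cross peaks the
mixed-interval g factors use the product Delta1_i*Delta1_j scaled by a
correlation coefficient (default 1: fluctuations of modes belonging to the
same molecule/solvation shell are fully correlated); the homogeneous
delta-term of the FFCF is treated as uncorrelated between distinct modes.

The absorptive spectrum is the properly sign-folded sum of the two phases,
purely real, computed by double FFT over the coherence times t1, t3 in a
rotating frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .constants import CM1_TO_RADPS
from .lineshape import g_diffusive
from .params import ResonanceSpec
from .spectra import Spectrum2D

__all__ = [
    "orientational_factor",
    "SimConfig",
    "SpeciesMixture",
    "simulate_2dir",
    "mix_species",
    "center_line_slope",
]


def orientational_factor(theta_deg: float, pol: str) -> float:
    """Isotropic orientational weight of a four-wave-mixing pathway.

    ``theta_deg`` is the angle between the two transition dipoles involved
    (0 for a diagonal peak).  Conventions: parallel (ZZZZ)
    (1 + 2 cos^2 theta)/15, perpendicular (ZZXX) (2 - cos^2 theta)/15,
    magic angle 1/9 (orientation-free).
    """
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError("theta must lie in [0, 180] degrees")
    c2 = np.cos(np.deg2rad(theta_deg)) ** 2
    if pol == "parallel":
        return float((1.0 + 2.0 * c2) / 15.0)
    if pol == "perpendicular":
        return float((2.0 - c2) / 15.0)
    if pol == "magic":
        return 1.0 / 9.0
    raise ValueError(f"unknown polarization {pol!r}")


@dataclass(frozen=True)
class SimConfig:
    """Numerical settings of the 2DIR response-function evaluation.

    t1 and t3 run on ``n_t = round(t_max/dt)`` points; the response is
    cosine-apodized over the trailing ``apodize`` fraction, zero padded to
    ``n_fft`` and double-FFT'd.  ``coherence_lifetime_factor`` is the
    fraction of gamma1 damping the 0-1 coherences (1/2 by convention);
    the diagonal ESA 1-2 coherence decays with (gamma1+gamma2)/2 scaled the
    same way.  ``cross_correlation`` is the correlation coefficient of the
    diffusive frequency fluctuations of distinct modes.
    """

    t_max: float = 3.2
    dt: float = 0.02
    n_fft: int = 512
    apodize: float = 0.10
    coherence_lifetime_factor: float = 0.5
    cross_correlation: float = 1.0

    @classmethod
    def fine(cls) -> "SimConfig":
        """Higher-resolution settings for presentation-quality maps and
        center-line-slope analysis."""
        return cls(t_max=6.0, dt=0.01, n_fft=2048)

    @property
    def n_t(self) -> int:
        return int(round(self.t_max / self.dt))

    def times(self) -> np.ndarray:
        return np.arange(self.n_t) * self.dt

    def window(self) -> np.ndarray:
        """Cosine apodization over the trailing fraction of the time grid."""
        n = self.n_t
        w = np.ones(n)
        n_apo = max(int(np.ceil(self.apodize * n)), 1)
        ramp = 0.5 * (1.0 + np.cos(np.linspace(0.0, np.pi, n_apo)))
        w[n - n_apo:] = ramp
        return w


@dataclass
class SpeciesMixture:
    """Weighted collection of species, each with its own resonances and
    off-diagonal anharmonic couplings."""

    members: list[tuple[str, list[ResonanceSpec], dict, float]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("mixture needs at least one member")
        weights = np.array([m[3] for m in self.members], dtype=float)
        if np.any(weights < 0):
            raise ValueError("mixture weights must be >= 0")
        if weights.sum() == 0:
            raise ValueError("mixture weights must not all be zero")


def _angle_between(d1, d2) -> float:
    c = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def simulate_2dir(
    resonances: list[ResonanceSpec],
    t2: float,
    pump_grid: np.ndarray,
    probe_grid: np.ndarray,
    pol: str = "parallel",
    couplings: dict[tuple[int, int], float] | None = None,
    config: SimConfig | None = None,
) -> Spectrum2D:
    """Absorptive 2DIR spectrum of a set of (possibly coupled) resonances.

    Parameters
    ----------
    resonances : list of ResonanceSpec
        Diagonal resonances; each must carry its FFCF.
    t2 : float
        Waiting time, ps.
    pump_grid, probe_grid : array_like
        Output frequency axes, cm^-1, strictly increasing.
    pol : str
        'parallel', 'perpendicular' or 'magic'.
    couplings : dict, optional
        Off-diagonal anharmonicities ``{(i, j): x_ij}`` in cm^-1 (0-based
        indices, order-insensitive).  Coupled pairs produce cross peaks;
        uncoupled pairs contribute exactly cancelling bleach/ESA.
    config : SimConfig, optional
    """
    if t2 < 0:
        raise ValueError("waiting time t2 must be >= 0")
    if not resonances:
        raise ValueError("at least one resonance is required")
    for r in resonances:
        if r.ffcf is None:
            raise ValueError("every resonance must carry FFCF parameters")
    cfg = config or SimConfig()
    couplings = dict(couplings or {})
    pump_grid = np.asarray(pump_grid, dtype=float)
    probe_grid = np.asarray(probe_grid, dtype=float)

    t = cfg.times()
    n = t.size
    win = cfg.window()
    omega_ref = 0.25 * (pump_grid[0] + pump_grid[-1] + probe_grid[0] + probe_grid[-1])
    cf = cfg.coherence_lifetime_factor

    # diffusive g caches, keyed by the Delta1 product and tau_c
    cache_1d: dict[tuple, np.ndarray] = {}
    cache_2d: dict[tuple, np.ndarray] = {}
    t13 = t[:, None] + t[None, :]

    def gd1(d1sq, tau_c, shift):
        key = (d1sq, tau_c, shift)
        if key not in cache_1d:
            cache_1d[key] = g_diffusive(d1sq, tau_c, t + shift)
        return cache_1d[key]

    def gd2(d1sq, tau_c):
        key = (d1sq, tau_c)
        if key not in cache_2d:
            cache_2d[key] = g_diffusive(d1sq, tau_c, t13 + t2)
        return cache_2d[key]

    total_r = np.zeros((n, n), dtype=complex)
    total_nr = np.zeros((n, n), dtype=complex)

    pairs = [(i, i) for i in range(len(resonances))]
    for (a, b) in couplings:
        i, j = min(a, b), max(a, b)
        if i == j or j >= len(resonances):
            raise ValueError(f"invalid coupling indices {(a, b)}")
        pairs.append((i, j))
        pairs.append((j, i))

    for (i, j) in pairs:
        ri, rj = resonances[i], resonances[j]
        pi, pj = ri.ffcf, rj.ffcf
        diagonal = i == j
        rho = 1.0 if diagonal else cfg.cross_correlation
        tau_c = pi.tau_c if diagonal else 0.5 * (pi.tau_c + pj.tau_c)
        d_ii = pi.Delta1**2
        d_jj = pj.Delta1**2
        d_ij = pi.Delta1 * pj.Delta1

        g1 = g_diffusive(d_ii, pi.tau_c, t) + t / pi.T2_star
        g3 = g_diffusive(d_jj, pj.tau_c, t) + t / pj.T2_star
        g_t2 = float(g_diffusive(d_ij, tau_c, np.array([t2]))[0])
        g12 = gd1(d_ij, tau_c, t2)  # g(t1 + t2)
        g23 = gd1(d_ij, tau_c, t2)  # g(t2 + t3), same 1-D profile
        g123 = gd2(d_ij, tau_c)     # g(t1 + t2 + t3)

        mixed = g_t2 - g12[:, None] - g23[None, :] + g123
        base = -g1[:, None] - g3[None, :]
        expo_r = base + rho * mixed
        expo_nr = base - rho * mixed

        # t1 / t3 coherence decays and t2 population decay
        decay1 = np.exp(-cf * pi.gamma1 * t) * win
        decay3_gb = np.exp(-cf * pj.gamma1 * t) * win
        if diagonal:
            decay3_esa = np.exp(-cf * (pj.gamma1 + pj.gamma2) * t) * win
        else:
            # same rate as the cross bleach so that x_ij -> 0 cancels exactly
            decay3_esa = decay3_gb
        pop_t2 = np.exp(-pi.gamma1 * t2)

        theta = 0.0 if diagonal else _angle_between(ri.dipole, rj.dipole)
        orient = orientational_factor(theta, pol)
        if diagonal:
            amp = 2.0 * ri.weight
            omega_esa = rj.omega12
        else:
            amp = np.sqrt(ri.weight * rj.weight)
            x_ij = couplings.get((i, j), couplings.get((j, i), 0.0))
            omega_esa = rj.omega01 + x_ij
        amp *= orient * pop_t2

        om_i = (ri.omega01 - omega_ref) * CM1_TO_RADPS
        om_j = (rj.omega01 - omega_ref) * CM1_TO_RADPS
        om_e = (omega_esa - omega_ref) * CM1_TO_RADPS

        probe_kernel = (
            -np.exp(-1j * om_j * t) * decay3_gb
            + np.exp(-1j * om_e * t) * decay3_esa
        ) * amp
        shape_r = np.exp(expo_r)
        shape_nr = np.exp(expo_nr)
        total_r += (np.exp(1j * om_i * t) * decay1)[:, None] * shape_r * probe_kernel[None, :]
        total_nr += (np.exp(-1j * om_i * t) * decay1)[:, None] * shape_nr * probe_kernel[None, :]

    # half-weight t=0 edges (trapezoid rule of the half-Fourier integrals)
    for arr in (total_r, total_nr):
        arr[0, :] *= 0.5
        arr[:, 0] *= 0.5

    nf = cfg.n_fft
    # detection (t3): signal e^{-i w t3} pairs with the e^{+i w t} kernel
    # (ifft); pump (t1): rephasing e^{+i w t1} pairs with fft, non-rephasing
    # with ifft — both phases then fold onto the positive pump frequency
    det_r = np.fft.ifft(total_r, n=nf, axis=1) * nf
    det_nr = np.fft.ifft(total_nr, n=nf, axis=1) * nf
    sr = np.fft.fft(det_r, n=nf, axis=0)
    snr = np.fft.ifft(det_nr, n=nf, axis=0) * nf
    absorptive = np.real(sr + snr) * cfg.dt**2

    freqs = 2.0 * np.pi * np.fft.fftfreq(nf, d=cfg.dt)
    order = np.argsort(freqs)
    pump_full = omega_ref + freqs[order] / CM1_TO_RADPS
    probe_full = omega_ref + freqs[order] / CM1_TO_RADPS
    # axis 0 = t1 -> pump; axis 1 = t3 -> probe
    absorptive = absorptive[np.ix_(order, order)]

    spline = RectBivariateSpline(pump_full, probe_full, absorptive, kx=3, ky=3)
    values = spline(pump_grid, probe_grid).T  # -> (probe, pump)
    return Spectrum2D(pump_grid, probe_grid, values, t2=t2, polarization=pol)


def mix_species(
    mix: SpeciesMixture,
    t2: float,
    pump_grid: np.ndarray,
    probe_grid: np.ndarray,
    pol: str = "parallel",
    config: SimConfig | None = None,
) -> Spectrum2D:
    """Weighted sum of per-species absorptive 2DIR spectra.

    Weights are normalized to unit sum at use, so only ratios matter
    (e.g. a 3:1 mixture of two hydration states).
    """
    weights = np.array([m[3] for m in mix.members], dtype=float)
    weights = weights / weights.sum()
    out = None
    for (label, resonances, couplings, _), w in zip(mix.members, weights):
        spec = simulate_2dir(
            resonances, t2, pump_grid, probe_grid, pol, couplings, config
        )
        out = spec.values * w if out is None else out + spec.values * w
    return Spectrum2D(
        np.asarray(pump_grid, float),
        np.asarray(probe_grid, float),
        out,
        t2=t2,
        polarization=pol,
    )


def center_line_slope(
    spec: Spectrum2D,
    center: float,
    half_window: float = 6.0,
) -> float:
    """Center line slope (CLS) of the diagonal bleach around ``center``.

    For each pump frequency within ``center +/- half_window`` the probe
    position of the bleach minimum is refined by a parabolic fit through
    the three points bracketing the discrete minimum; the CLS is the linear
    slope of those probe positions versus pump frequency.  Its decay with
    waiting time approximates the normalized FFCF, so an exponential fit of
    CLS(t2) recovers the spectral-diffusion correlation time.
    """
    pump, probe, v = spec.pump_axis, spec.probe_axis, spec.values
    sel = np.where(np.abs(pump - center) <= half_window)[0]
    if sel.size < 3:
        raise ValueError("CLS window contains fewer than 3 pump slices")
    xs, ys = [], []
    for jx in sel:
        col = v[:, jx]
        k = int(np.argmin(col))
        if k == 0 or k == col.size - 1:
            continue
        y0, y1, y2 = col[k - 1], col[k], col[k + 1]
        denom = y0 - 2 * y1 + y2
        frac = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        step = probe[k + 1] - probe[k]
        xs.append(pump[jx])
        ys.append(probe[k] + frac * step)
    slope = np.polyfit(xs, ys, 1)[0]
    return float(slope)
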
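"""Synthetic data with known ground truth.

The generators stand in for the experiment: they forward-simulate the
observables (linear IR, absorptive 2DIR maps, polarization-resolved
kinetic traces) from stated parameters and add seeded white Gaussian noise
scaled to the signal maximum — a detector-noise approximation.  Every
generator is bit-reproducible given (parameters, seed).

``CARBONYL_BAND_RESONANCES`` is the package's built-in three-resonance
parameterization of the Cu(L-proline)2 carbonyl band near 1600 cm^-1 (the
dominant antisymmetric-stretch resonance at 1604.1 cm^-1 flanked by two
weaker components), with a shared spectral-diffusion term Delta1 = 8.4
cm^-1, tau_c = 1.57 ps.  The default kinetic parameters are the complex's
biexponential population decay (380 fs / 820 fs, equal amplitudes) and a
5 ps single-exponential rotational anisotropy.

The electronic-transition fixtures (`TRANS0_TRANSITIONS`,
`CIS0_TRANSITIONS`) are synthetic stand-ins: the wavelengths are the
computed visible d-d transitions of the unhydrated trans/cis conformers,
while dipole vectors and strengths are invented plausibly since only band
positions and ORD signs are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .chiroptics import ElectronicTransition
from .kinetics import DecayTrace
from .lineshape import linear_absorption
from .params import FFCFParams, ResonanceSpec
from .spectra import Spectrum1D, Spectrum2D
from .twodir import SimConfig, simulate_2dir
from .vpt2 import AnharmonicField

import warnings

__all__ = [
    "GroundTruth",
    "CARBONYL_BAND_RESONANCES",
    "carbonyl_band_resonances",
    "carbonyl_band_dataset",
    "gen_kinetics",
    "gen_anharmonic_fixture",
    "TRANS0_TRANSITIONS",
    "CIS0_TRANSITIONS",
    "DEFAULT_LINEAR_GRID",
    "DEFAULT_MAP_GRID",
]

#: Three-resonance carbonyl-band parameter set: (omega01, omega12, weight,
#: Delta1, T2*, tau_c, gamma1, gamma2).
_CARBONYL_ROWS = (
    (1595.1, 1588.5, 0.20, 8.4, 0.80, 1.57, 1.00, 1.3),
    (1604.1, 1598.5, 0.56, 8.4, 0.96, 1.57, 0.98, 1.3),
    (1620.9, 1612.3, 0.24, 8.4, 0.96, 1.57, 1.00, 1.3),
)


def carbonyl_band_resonances() -> list[ResonanceSpec]:
    """The built-in three-resonance carbonyl-band parameter set."""
    out = []
    for (w01, w12, w, d1, t2s, tc, g1, g2) in _CARBONYL_ROWS:
        out.append(
            ResonanceSpec(
                omega01=w01,
                omega12=w12,
                weight=w,
                ffcf=FFCFParams(T2_star=t2s, Delta1=d1, tau_c=tc, gamma1=g1, gamma2=g2),
            )
        )
    return out


CARBONYL_BAND_RESONANCES = carbonyl_band_resonances()

DEFAULT_LINEAR_GRID = np.arange(1540.0, 1680.0 + 1e-9, 0.25)
DEFAULT_MAP_GRID = np.arange(1560.0, 1660.0 + 1e-9, 1.0)


@dataclass
class GroundTruth:
    """The generating parameters of a synthetic data set."""

    resonances: list[ResonanceSpec] = field(default_factory=list)
    kinetics: dict = field(default_factory=dict)
    anharmonic: AnharmonicField | None = None
    noise: float = 0.0
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise level must be >= 0")


def carbonyl_band_dataset(
    noise: float = 0.01,
    seed: int = 0,
    t2s: tuple[float, ...] = (0.9, 2.0),
    pol: str = "parallel",
    linear_grid: np.ndarray | None = None,
    map_grid: np.ndarray | None = None,
    config: SimConfig | None = None,
    resonances: list[ResonanceSpec] | None = None,
) -> tuple[Spectrum1D, list[Spectrum2D], GroundTruth]:
    """Noisy linear IR plus 2DIR maps from the carbonyl-band parameters.

    Forward-simulates the three built-in resonances (or a supplied list)
    on the default grids, then adds i.i.d. Gaussian noise with standard
    deviation ``noise`` times the spectrum maximum.  With ``noise=0`` the
    output is deterministic and seed-independent.
    """
    if noise < 0:
        raise ValueError("noise level must be >= 0")
    res = resonances if resonances is not None else carbonyl_band_resonances()
    lg = DEFAULT_LINEAR_GRID if linear_grid is None else np.asarray(linear_grid)
    mg = DEFAULT_MAP_GRID if map_grid is None else np.asarray(map_grid)
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        linear = linear_absorption(res, lg)
        maps = [simulate_2dir(res, t2, mg, mg, pol, config=cfg) for t2 in t2s]

    if noise > 0:
        linear.values = linear.values + rng.normal(
            0.0, noise * np.max(np.abs(linear.values)), linear.values.shape
        )
        for m in maps:
            m.values = m.values + rng.normal(
                0.0, noise * np.max(np.abs(m.values)), m.values.shape
            )
    truth = GroundTruth(resonances=res, noise=noise, seed=seed,
                        extra={"t2s": list(t2s), "polarization": pol})
    return linear, maps, truth


def gen_kinetics(
    amplitudes: tuple[float, ...] = (0.5, 0.5),
    lifetimes: tuple[float, ...] = (0.38, 0.82),
    r0: float = 0.4,
    tau_R: float = 5.0,
    noise: float = 0.02,
    seed: int = 0,
    times: np.ndarray | None = None,
) -> tuple[DecayTrace, GroundTruth]:
    """Synthetic polarization-resolved pump-probe traces.

    The population is P(t) = sum a_i exp(-t/tau_i); the anisotropy
    r(t) = r0 exp(-t/tau_R) maps onto the polarized signals as
    S_par = P (1 + 2 r) and S_perp = P (1 - r), so the magic-angle
    combination (S_par + 2 S_perp)/3 equals P exactly and carries no
    rotational information.  Defaults are the complex-carbonyl values
    (380/820 fs equal-amplitude biexponential, tau_R = 5 ps).  Gaussian
    noise of standard deviation ``noise`` times the signal maximum is
    added independently to both polarized channels.
    """
    if times is None:
        times = np.arange(0.0, 5.0 + 1e-9, 0.02)
    times = np.asarray(times, dtype=float)
    pop = sum(a * np.exp(-times / tau) for a, tau in zip(amplitudes, lifetimes))
    r = r0 * np.exp(-times / tau_R)
    s_par = pop * (1.0 + 2.0 * r)
    s_perp = pop * (1.0 - r)
    rng = np.random.default_rng(seed)
    if noise > 0:
        s_par = s_par + rng.normal(0.0, noise * np.max(np.abs(s_par)), times.shape)
        s_perp = s_perp + rng.normal(0.0, noise * np.max(np.abs(s_perp)), times.shape)
    trace = DecayTrace(times, par=s_par, perp=s_perp)
    truth = GroundTruth(
        kinetics={
            "amplitudes": list(amplitudes),
            "lifetimes": list(lifetimes),
            "r0": r0,
            "tau_R": tau_R,
        },
        noise=noise,
        seed=seed,
    )
    return trace, truth


def gen_anharmonic_fixture(kind: str, **kw) -> AnharmonicField:
    """Analytic force-constant fixtures with known anharmonicity.

    Kinds
    -----
    'morse' : one-mode Morse oscillator with ``omega_e`` and ``omega_e_x_e``
        (defaults 1700, 10 cm^-1).  The reduced-coordinate expansion of
        D(1 - e^{-a q})^2 gives phi_iii = -6 D a^3, phi_iiii = 14 D a^4
        with D = omega_e^2/(4 omega_e_x_e), a = sqrt(omega_e/(2 D)); the
        VPT2 diagonal constant then reproduces -omega_e_x_e exactly.
    'two_mode' : two modes coupled only through ``phi_iijj`` (default -8
        cm^-1), so x_ij = phi_iijj/4 exactly.
    'carbonyl_pair' : two carbonyl stretching modes near 1600 cm^-1 whose
        diagonal quartic constants reproduce the observed 5.6 cm^-1
        anharmonic red-shift of the dominant band (x_ii = -2.8 cm^-1)
        after scaling the harmonic frequencies by 0.97.
    """
    if kind == "morse":
        we = float(kw.get("omega_e", 1700.0))
        wexe = float(kw.get("omega_e_x_e", 10.0))
        D = we**2 / (4.0 * wexe)
        a = np.sqrt(we / (2.0 * D))
        return AnharmonicField(
            omegas=[we],
            cubic={(0, 0, 0): -6.0 * D * a**3},
            quartic={(0, 0, 0, 0): 14.0 * D * a**4},
        )
    if kind == "two_mode":
        phi = float(kw.get("phi_iijj", -8.0))
        omegas = kw.get("omegas", (1650.0, 1450.0))
        return AnharmonicField(omegas=list(omegas), quartic={(0, 0, 1, 1): phi})
    if kind == "carbonyl_pair":
        # harmonic frequencies chosen so the scaled fundamentals land on
        # the dominant/satellite carbonyl resonances
        x_ii = -2.8
        x_ij = float(kw.get("x_ij", -1.0))
        w1 = (1604.1 - 2.0 * x_ii - 0.5 * x_ij) / 0.97
        w2 = (1620.9 - 2.0 * x_ii - 0.5 * x_ij) / 0.97
        return AnharmonicField(
            omegas=[w1, w2],
            quartic={
                (0, 0, 0, 0): 16.0 * x_ii,
                (1, 1, 1, 1): 16.0 * x_ii,
                (0, 0, 1, 1): 4.0 * x_ij,
            },
        )
    raise ValueError(f"unknown fixture kind {kind!r}")


# Synthetic electronic-transition fixtures for the unhydrated conformers:
# wavelengths are the computed visible d-d resonances; dipole vectors and
# oscillator strengths are invented (only positions/signs are modelled).
TRANS0_TRANSITIONS = [
    ElectronicTransition(473.0, mu=(0.8, 0.1, 0.0), m=(0.5, 0.3, 0.2), f_osc=0.004),
    ElectronicTransition(533.0, mu=(0.2, 0.9, 0.0), m=(-0.1, 0.6, 0.3), f_osc=0.006),
    ElectronicTransition(549.0, mu=(0.1, 0.2, 0.9), m=(0.0, -0.4, 0.5), f_osc=0.005),
]

CIS0_TRANSITIONS = [
    ElectronicTransition(504.0, mu=(0.9, 0.0, 0.1), m=(0.4, 0.2, 0.0), f_osc=0.005),
    ElectronicTransition(521.0, mu=(0.0, 0.8, 0.2), m=(0.2, -0.5, 0.1), f_osc=0.006),
    ElectronicTransition(545.0, mu=(0.2, 0.1, 0.8), m=(-0.1, 0.3, 0.4), f_osc=0.004),
]
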
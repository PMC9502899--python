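"""Parameter containers for vibrational resonances and their frequency
fluctuations.

A vibrational resonance of the carbonyl band is described by the frequencies
of its |0>->|1> and |1>->|2> transitions, a dimensionless amplitude weight,
the direction of its transition dipole, and a frequency fluctuation
correlation function (FFCF)

    xi(t) = delta(t)/T2* + Delta1^2 * exp(-t/tau_c)

whose parameters are the pure dephasing time ``T2*`` (ps), the fluctuation
amplitude of the diffusive term ``Delta1`` (cm^-1) and its correlation time
``tau_c`` (ps), together with the population relaxation rates ``gamma1`` and
``gamma2`` (ps^-1) of the first and second excited vibrational states.

``Delta1`` is stored in cm^-1 exactly as reported in fit tables; conversion
to angular units happens only inside the line-broadening function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class FFCFParams:
    """Frequency-fluctuation / dephasing parameters of one resonance.

    Parameters
    ----------
    T2_star : float
        Pure dephasing time, ps.  Enters the FFCF as the homogeneous
        delta-function term delta(t)/T2*.
    Delta1 : float
        Fluctuation amplitude of the diffusive (spectral diffusion) term,
        cm^-1.
    tau_c : float
        Correlation time of the diffusive term, ps.
    gamma1, gamma2 : float
        Population relaxation rates of |1> and |2>, ps^-1.
    """

    T2_star: float
    Delta1: float
    tau_c: float
    gamma1: float = 0.0
    gamma2: float = 0.0

    def __post_init__(self) -> None:
        if not self.T2_star > 0:
            raise ValueError(f"T2_star must be > 0, got {self.T2_star}")
        if self.Delta1 < 0:
            raise ValueError(f"Delta1 must be >= 0, got {self.Delta1}")
        if not self.tau_c > 0:
            raise ValueError(f"tau_c must be > 0, got {self.tau_c}")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("gamma1 and gamma2 must be >= 0")


@dataclass(frozen=True)
class ResonanceSpec:
    """One vibrational resonance of a carbonyl band.

    ``omega01`` and ``omega12`` are the |0>->|1> and |1>->|2> transition
    frequencies in cm^-1; positive diagonal anharmonicity means
    ``omega12 <= omega01``.  ``weight`` is the dimensionless amplitude
    fraction of the resonance within the band and ``dipole`` the unit
    transition-dipole direction used for orientational factors.
    """

    omega01: float
    omega12: float
    ffcf: FFCFParams
    weight: float = 1.0
    dipole: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.omega12 > self.omega01 + 1e-9:
            raise ValueError(
                f"omega12 ({self.omega12}) must not exceed omega01 "
                f"({self.omega01}) for positive diagonal anharmonicity"
            )
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must lie in [0, 1], got {self.weight}")
        d = np.asarray(self.dipole, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ValueError("dipole must be a finite non-zero 3-vector")
        object.__setattr__(self, "dipole", tuple(d / n))

    @property
    def anharmonicity(self) -> float:
        """Diagonal anharmonic red-shift omega01 - omega12, cm^-1."""
        return self.omega01 - self.omega12


def resonances_to_json(resonances: list[ResonanceSpec], path: str | Path) -> None:
    """Serialize a resonance list to JSON."""
    payload = [asdict(r) for r in resonances]
    Path(path).write_text(json.dumps(payload, indent=2))


def resonances_from_json(path: str | Path) -> list[ResonanceSpec]:
    """Load a resonance list written by :func:`resonances_to_json`."""
    payload = json.loads(Path(path).read_text())
    out = []
    for item in payload:
        ffcf = FFCFParams(**item.pop("ffcf"))
        item["dipole"] = tuple(item.get("dipole", (0.0, 0.0, 1.0)))
        out.append(ResonanceSpec(ffcf=ffcf, **item))
    return out
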
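"""Anharmonicity constants from cubic/quartic force fields by second-order
vibrational perturbation theory (VPT2).

The force field is expressed in reduced (dimensionless) normal coordinates
with all constants in cm^-1, the common quantum-chemistry printout
convention: V = 1/2 sum w_i q_i^2 + 1/6 sum phi_ijk q_i q_j q_k
+ 1/24 sum phi_ijkl q_i q_j q_k q_l, with the cubic/quartic tensors
symmetric under index permutation.  Rotational (Coriolis) contributions are
omitted: the model targets solution-phase, non-rotating chromophores.

The VPT2 anharmonicity constants are

  x_ii = phi_iiii/16 - (5/48) phi_iii^2/w_i
         - (1/16) sum_{k != i} phi_iik^2 (8 w_i^2 - 3 w_k^2)
                               / (w_k (4 w_i^2 - w_k^2))

  x_ij = phi_iijj/4 - (1/4) sum_k phi_iik phi_jjk / w_k
         + (1/2) sum_k phi_ijk^2 w_k (w_k^2 - w_i^2 - w_j^2) / D_ijk,

  D_ijk = (w_i+w_j+w_k)(w_i+w_j-w_k)(w_i-w_j+w_k)(w_i-w_j-w_k).

Fundamental and overtone frequencies follow as
nu_i = scale*w_i + 2 x_ii + 1/2 sum_{j != i} x_ij and
nu_i(1->2) = nu_i + 2 x_ii; the frequency ``scale`` (typically 0.97)
absorbs the systematic harmonic-frequency overestimate of DFT.

Near-resonant denominators (Fermi resonances) are excluded by
deperturbation: any term whose denominator falls below a configurable
threshold is dropped, recorded, and reported via a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AnharmonicField",
    "XMatrix",
    "diagonal_x",
    "offdiagonal_x",
    "x_matrix",
    "shifted_frequencies",
    "read_force_constants",
    "write_force_constants",
]

#: Default deperturbation threshold for near-resonant denominators, cm^-1
#: (applied to |2 w_i - w_k| and to the individual +/- combinations of
#: D_ijk).  Standard deperturbation practice.
RESONANCE_THRESHOLD = 50.0


def _sym_key(idx: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(sorted(idx))


@dataclass
class AnharmonicField:
    """Harmonic frequencies plus sparse symmetric cubic/quartic constants.

    ``cubic[(i, j, k)]`` and ``quartic[(i, j, k, l)]`` hold phi values in
    cm^-1 with 0-based mode indices; absent entries are zero and index
    permutations are equivalent.
    """

    omegas: np.ndarray
    cubic: dict[tuple[int, int, int], float] = field(default_factory=dict)
    quartic: dict[tuple[int, int, int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omegas = np.asarray(self.omegas, dtype=float)
        if np.any(self.omegas <= 0):
            raise ValueError("harmonic frequencies must be positive")
        self.cubic = {_sym_key(k): float(v) for k, v in self.cubic.items()}
        self.quartic = {_sym_key(k): float(v) for k, v in self.quartic.items()}
        nmode = self.omegas.size
        for key in list(self.cubic) + list(self.quartic):
            if any(i < 0 or i >= nmode for i in key):
                raise ValueError(f"force-constant index {key} out of range")

    @property
    def n_modes(self) -> int:
        return int(self.omegas.size)

    def phi3(self, i: int, j: int, k: int) -> float:
        return self.cubic.get(_sym_key((i, j, k)), 0.0)

    def phi4(self, i: int, j: int, k: int, l: int) -> float:
        return self.quartic.get(_sym_key((i, j, k, l)), 0.0)


@dataclass
class XMatrix:
    """Symmetric matrix of anharmonicity constants, cm^-1.

    ``excluded`` lists (i, j, k) index triples whose near-resonant terms
    were deperturbed (dropped) during evaluation.
    """

    x: np.ndarray
    excluded: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if not np.allclose(self.x, self.x.T):
            raise ValueError("x matrix must be symmetric")


def diagonal_x(
    field_: AnharmonicField,
    i: int,
    threshold: float = RESONANCE_THRESHOLD,
    _excluded: list | None = None,
) -> float:
    """Diagonal anharmonicity constant x_ii in cm^-1."""
    w = field_.omegas
    wi = w[i]
    out = field_.phi4(i, i, i, i) / 16.0
    out -= (5.0 / 48.0) * field_.phi3(i, i, i) ** 2 / wi
    for k in range(field_.n_modes):
        if k == i:
            continue
        phi = field_.phi3(i, i, k)
        if phi == 0.0:
            continue
        if abs(2.0 * wi - w[k]) < threshold:
            warnings.warn(
                f"near-resonant 2w_{i} ~ w_{k} term excluded from x_{i}{i} "
                f"(|2w_i - w_k| = {abs(2 * wi - w[k]):.2f} cm-1)",
                stacklevel=2,
            )
            if _excluded is not None:
                _excluded.append((i, i, k))
            continue
        out -= (
            phi**2
            * (8.0 * wi**2 - 3.0 * w[k] ** 2)
            / (w[k] * (4.0 * wi**2 - w[k] ** 2))
            / 16.0
        )
    return float(out)


def offdiagonal_x(
    field_: AnharmonicField,
    i: int,
    j: int,
    threshold: float = RESONANCE_THRESHOLD,
    _excluded: list | None = None,
) -> float:
    """Off-diagonal anharmonicity constant x_ij (i != j) in cm^-1."""
    if i == j:
        raise ValueError("offdiagonal_x requires i != j")
    w = field_.omegas
    wi, wj = w[i], w[j]
    out = field_.phi4(i, i, j, j) / 4.0
    for k in range(field_.n_modes):
        a, b = field_.phi3(i, i, k), field_.phi3(j, j, k)
        if a != 0.0 and b != 0.0:
            out -= 0.25 * a * b / w[k]
        phi = field_.phi3(i, j, k)
        if phi == 0.0:
            continue
        combos = (wi + wj - w[k], wi - wj + w[k], -wi + wj + w[k])
        if min(abs(c) for c in combos) < threshold:
            warnings.warn(
                f"Fermi-resonant triple ({i},{j},{k}) excluded from x_{i}{j}",
                stacklevel=2,
            )
            if _excluded is not None:
                _excluded.append((i, j, k))
            continue
        delta = (wi + wj + w[k]) * combos[0] * combos[1] * combos[2]
        out += 0.5 * phi**2 * w[k] * (w[k] ** 2 - wi**2 - wj**2) / delta
    return float(out)


def x_matrix(
    field_: AnharmonicField, threshold: float = RESONANCE_THRESHOLD
) -> XMatrix:
    """Full symmetric anharmonicity matrix of a force field."""
    n = field_.n_modes
    x = np.zeros((n, n))
    excluded: list[tuple[int, int, int]] = []
    for i in range(n):
        x[i, i] = diagonal_x(field_, i, threshold, excluded)
        for j in range(i + 1, n):
            x[i, j] = x[j, i] = offdiagonal_x(field_, i, j, threshold, excluded)
    return XMatrix(x, excluded)


def shifted_frequencies(
    field_: AnharmonicField, x: XMatrix, scale: float = 0.97
) -> list[tuple[float, float]]:
    """Anharmonic (omega01, omega12) pairs for every mode, cm^-1.

    omega01_i = scale*w_i + 2 x_ii + 1/2 sum_{j != i} x_ij and
    omega12_i = omega01_i + 2 x_ii (negative x_ii red-shifts the 1->2
    transition, the normal positive diagonal anharmonicity).  The harmonic
    ``scale`` factor must lie in (0.8, 1.1].
    """
    if not 0.8 < scale <= 1.1:
        raise ValueError("scale factor must lie in (0.8, 1.1]")
    out = []
    for i in range(field_.n_modes):
        off = sum(x.x[i, j] for j in range(field_.n_modes) if j != i)
        w01 = scale * field_.omegas[i] + 2.0 * x.x[i, i] + 0.5 * off
        w12 = w01 + 2.0 * x.x[i, i]
        out.append((float(w01), float(w12)))
    return out


def write_force_constants(field_: AnharmonicField, path: str | Path) -> None:
    """Plain-text force-constant table: '# omegas:' header, then lines
    'i j k value' (cubic) and 'i j k l value' (quartic), 1-based indices."""
    with open(path, "w") as fh:
        fh.write("# omegas: " + " ".join(f"{w:.6f}" for w in field_.omegas) + "\n")
        for key, v in sorted(field_.cubic.items()):
            fh.write(" ".join(str(i + 1) for i in key) + f" {v:.10g}\n")
        for key, v in sorted(field_.quartic.items()):
            fh.write(" ".join(str(i + 1) for i in key) + f" {v:.10g}\n")


def read_force_constants(path: str | Path) -> AnharmonicField:
    """Read the table written by :func:`write_force_constants`."""
    omegas = None
    cubic, quartic = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("omegas:"):
                    omegas = np.array(body.split(":", 1)[1].split(), dtype=float)
                continue
            parts = line.split()
            if len(parts) not in (4, 5):
                raise ValueError(
                    f"{path}: line {lineno}: expected 'i j k value' or "
                    f"'i j k l value'"
                )
            try:
                idx = tuple(int(p) - 1 for p in parts[:-1])
                value = float(parts[-1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed entry") from exc
            if len(idx) == 3:
                cubic[idx] = value
            else:
                quartic[idx] = value
    if omegas is None:
        raise ValueError(f"{path}: missing '# omegas:' header")
    return AnharmonicField(omegas, cubic, quartic)
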
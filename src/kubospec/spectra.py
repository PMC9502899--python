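"""Axis-labelled spectral containers and their plain-text formats.

``Spectrum1D`` is a two-column TSV (axis, value) with '#'-prefixed metadata
header; ``Spectrum2D`` is a TSV matrix with ``#pump:``, ``#probe:``,
``#t2:`` and ``#pol:`` header lines.  Rows of the 2D matrix run along the
probe axis, columns along the pump axis.  All parsers raise explicit errors
naming the offending line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

POLARIZATIONS = ("parallel", "perpendicular", "magic")


def _check_axis(axis: np.ndarray, name: str) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError(f"{name} axis must be 1-D with >= 2 points")
    if not np.all(np.diff(axis) > 0):
        raise ValueError(f"non-monotone axis: {name} must be strictly increasing")
    return axis


@dataclass
class Spectrum1D:
    """A 1-D spectrum: strictly increasing axis plus real values."""

    axis: np.ndarray
    values: np.ndarray
    axis_unit: str = "cm-1"
    value_unit: str = "a.u."

    def __post_init__(self) -> None:
        self.axis = _check_axis(self.axis, "spectrum")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.axis.shape:
            raise ValueError("axis and values must have identical shapes")

    @property
    def peak_position(self) -> float:
        """Axis position of the global maximum."""
        return float(self.axis[int(np.argmax(self.values))])

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# kind: spectrum1d\n")
            fh.write(f"# axis_unit: {self.axis_unit}\n")
            fh.write(f"# value_unit: {self.value_unit}\n")
            for x, y in zip(self.axis, self.values):
                fh.write(f"{x:.8g}\t{y:.10g}\n")

    @classmethod
    def read(cls, path: str | Path) -> "Spectrum1D":
        axis_unit, value_unit = "cm-1", "a.u."
        xs, ys = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if body.startswith("axis_unit:"):
                        axis_unit = body.split(":", 1)[1].strip()
                    elif body.startswith("value_unit:"):
                        value_unit = body.split(":", 1)[1].strip()
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}: line {lineno}: expected two columns, got {len(parts)}"
                    )
                try:
                    x, y = float(parts[0]), float(parts[1])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
                if not (np.isfinite(x) and np.isfinite(y)):
                    raise ValueError(f"{path}: line {lineno}: NaN/inf value")
                xs.append(x)
                ys.append(y)
        if not xs:
            raise ValueError(f"{path}: empty spectrum (no data rows)")
        return cls(np.array(xs), np.array(ys), axis_unit, value_unit)


@dataclass
class Spectrum2D:
    """An absorptive 2D spectrum at one waiting time.

    ``values[i, j]`` is the amplitude at probe frequency ``probe_axis[i]``
    and pump frequency ``pump_axis[j]``; negative amplitudes are ground-state
    bleach / stimulated emission, positive amplitudes excited-state
    absorption.
    """

    pump_axis: np.ndarray
    probe_axis: np.ndarray
    values: np.ndarray
    t2: float = 0.0
    polarization: str = "parallel"

    def __post_init__(self) -> None:
        self.pump_axis = _check_axis(self.pump_axis, "pump")
        self.probe_axis = _check_axis(self.probe_axis, "probe")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.probe_axis.size, self.pump_axis.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(probe, pump) = ({self.probe_axis.size}, {self.pump_axis.size})"
            )
        if self.polarization not in POLARIZATIONS:
            raise ValueError(f"polarization must be one of {POLARIZATIONS}")
        if self.t2 < 0:
            raise ValueError("waiting time t2 must be >= 0")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#t2: {self.t2:.6g}\n")
            fh.write(f"#pol: {self.polarization}\n")
            fh.write("#pump: " + " ".join(f"{v:.8g}" for v in self.pump_axis) + "\n")
            fh.write("#probe: " + " ".join(f"{v:.8g}" for v in self.probe_axis) + "\n")
            np.savetxt(fh, self.values, fmt="%.8g", delimiter="\t")

    @classmethod
    def read(cls, path: str | Path) -> "Spectrum2D":
        t2, pol = None, None
        pump, probe = None, None
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    try:
                        if body.startswith("t2:"):
                            t2 = float(body.split(":", 1)[1])
                        elif body.startswith("pol:"):
                            pol = body.split(":", 1)[1].strip()
                        elif body.startswith("pump:"):
                            pump = np.array(body.split(":", 1)[1].split(), dtype=float)
                        elif body.startswith("probe:"):
                            probe = np.array(body.split(":", 1)[1].split(), dtype=float)
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}: line {lineno}: malformed header"
                        ) from exc
                    continue
                try:
                    rows.append(np.array(line.split(), dtype=float))
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
        if pump is None or probe is None:
            raise ValueError(f"{path}: missing #pump:/#probe: header")
        if t2 is None or pol is None:
            raise ValueError(f"{path}: missing #t2:/#pol: header")
        if not rows:
            raise ValueError(f"{path}: empty spectrum (no data rows)")
        values = np.vstack(rows)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{path}: NaN/inf in matrix body")
        return cls(pump, probe, values, t2=t2, polarization=pol)
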
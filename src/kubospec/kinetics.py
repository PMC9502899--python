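"""Pump-probe population and anisotropy kinetics.

Magic-angle signals isolate the vibrational population decay, which for
the carbonyl band is biexponential; the polarization-resolved signals
additionally carry the orientational anisotropy

    r(t) = (S_par - S_perp) / (S_par + 2 S_perp),

which for a single transition dipole undergoing rotational diffusion decays
as a single exponential r(t) = r0 exp(-t/tau_R) with r0 <= 0.4.  The
magic-angle combination (S_par + 2 S_perp)/3 is anisotropy-free by
construction.

Both fits follow the Model -> fit() -> Results pattern: construct a model
from a trace, call ``fit`` and inspect estimates, standard errors and the
``summary()`` table on the result object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DecayTrace",
    "MultiExponentialModel",
    "MultiExponentialResults",
    "AnisotropyModel",
    "AnisotropyResults",
    "anisotropy",
]


@dataclass
class DecayTrace:
    """Time-resolved induced-absorption amplitudes.

    Either both polarizations (``par``/``perp``) or a ready magic-angle
    signal must be present; the magic-angle signal is computed as
    (S_par + 2 S_perp)/3 when absent.
    """

    times: np.ndarray
    par: np.ndarray | None = None
    perp: np.ndarray | None = None
    magic: np.ndarray | None = None
    probe_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.times < 0) or not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be non-negative and strictly increasing")
        for name in ("par", "perp", "magic"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.times.shape:
                    raise ValueError(f"{name} must match times in shape")
                setattr(self, name, v)
        if self.magic is None:
            if self.par is None or self.perp is None:
                raise ValueError("need either magic or both par and perp signals")
            self.magic = (self.par + 2.0 * self.perp) / 3.0

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            if self.par is not None and self.perp is not None:
                fh.write("# columns: time_ps par perp\n")
                for t, a, b in zip(self.times, self.par, self.perp):
                    fh.write(f"{t:.6g}\t{a:.10g}\t{b:.10g}\n")
            else:
                fh.write("# columns: time_ps magic\n")
                for t, m in zip(self.times, self.magic):
                    fh.write(f"{t:.6g}\t{m:.10g}\n")

    @classmethod
    def read(cls, path: str | Path) -> "DecayTrace":
        data = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    data.append([float(x) for x in line.split()])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
        if not data:
            raise ValueError(f"{path}: empty trace")
        arr = np.array(data)
        if arr.shape[1] == 3:
            return cls(arr[:, 0], par=arr[:, 1], perp=arr[:, 2])
        if arr.shape[1] == 2:
            return cls(arr[:, 0], magic=arr[:, 1])
        raise ValueError(f"{path}: expected 2 or 3 columns, got {arr.shape[1]}")


def _multiexp(t, amps, taus):
    return sum(a * np.exp(-t / tau) for a, tau in zip(amps, taus))


@dataclass
class MultiExponentialResults:
    """Estimates from a multi-exponential population-decay fit.

    ``amplitudes`` are normalized so that their sum equals the fitted t=0
    amplitude fraction (sum of raw amplitudes); components are sorted by
    lifetime.
    """

    amplitudes: np.ndarray
    lifetimes: np.ndarray
    amplitude_se: np.ndarray
    lifetime_se: np.ndarray
    scale: float
    residual: np.ndarray
    chi2: float

    @property
    def fractions(self) -> np.ndarray:
        """Amplitude fractions a_i normalized to unit sum."""
        return self.amplitudes / self.amplitudes.sum()

    def summary(self) -> str:
        lines = ["Multi-exponential population decay", "-" * 42]
        lines.append(f"{'comp':>4} {'a_i':>8} {'tau_i/ps':>10} {'se(tau)':>9}")
        for k, (a, tau, se) in enumerate(
            zip(self.fractions, self.lifetimes, self.lifetime_se), start=1
        ):
            lines.append(f"{k:>4} {a:8.3f} {tau:10.4f} {se:9.4f}")
        lines.append(f"chi2 = {self.chi2:.4g}")
        return "\n".join(lines)


class MultiExponentialModel:
    """Least-squares model S(t) = sum_i a_i exp(-t/tau_i).

    Parameters
    ----------
    trace : DecayTrace or (times, signal)
        Magic-angle signal to fit.
    n : int
        Number of exponential components (1-3).
    """

    def __init__(self, trace, n: int = 2):
        if isinstance(trace, DecayTrace):
            self.times, self.signal = trace.times, trace.magic
        else:
            self.times, self.signal = (np.asarray(a, dtype=float) for a in trace)
        if n not in (1, 2, 3):
            raise ValueError("n must be 1, 2 or 3")
        if self.times.size < 5 * n:
            raise ValueError(f"need at least {5 * n} points for n={n}")
        self.n = n

    def _unpack(self, p):
        return p[: self.n], p[self.n:]

    def fit(self, init: np.ndarray | None = None) -> MultiExponentialResults:
        t, y = self.times, self.signal
        s0 = float(np.max(np.abs(y)))
        if init is None:
            span = max(t[-1] - t[0], 1e-3)
            taus0 = np.geomspace(span / 20.0, span / 2.0, self.n)
            init = np.concatenate([np.full(self.n, s0 / self.n), taus0])
        lower = np.concatenate([np.full(self.n, -np.inf), np.full(self.n, 1e-4)])
        res = least_squares(
            lambda p: _multiexp(t, *self._unpack(p)) - y,
            init,
            bounds=(lower, np.inf),
            x_scale="jac",
        )
        amps, taus = self._unpack(res.x)
        order = np.argsort(taus)
        amps, taus = np.asarray(amps)[order], np.asarray(taus)[order]
        if self.n > 1 and np.any(taus[1:] / taus[:-1] < 1.5):
            warnings.warn(
                "lifetime separation below factor 1.5: fit may be "
                "ill-conditioned",
                stacklevel=2,
            )
        se = _standard_errors(res)
        amp_se, tau_se = self._unpack(se)
        return MultiExponentialResults(
            amplitudes=amps,
            lifetimes=taus,
            amplitude_se=np.asarray(amp_se)[order],
            lifetime_se=np.asarray(tau_se)[order],
            scale=float(np.sum(amps)),
            residual=res.fun,
            chi2=float(2.0 * res.cost),
        )


def _standard_errors(res) -> np.ndarray:
    """1-sigma parameter uncertainties from the converged jacobian."""
    m, n = res.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def anisotropy(trace: DecayTrace, floor_fraction: float = 0.02):
    """Anisotropy series r(t) = (S_par - S_perp)/(S_par + 2 S_perp).

    The series is truncated (with a warning) where the isotropic
    denominator drops below ``floor_fraction`` of its maximum, ahead of a
    zero crossing.

    Returns (times, r) arrays restricted to the usable window.
    """
    if trace.par is None or trace.perp is None:
        raise ValueError("anisotropy needs both polarizations")
    denom = trace.par + 2.0 * trace.perp
    floor = floor_fraction * np.max(np.abs(denom))
    bad = np.where(np.abs(denom) < floor)[0]
    stop = bad[0] if bad.size else trace.times.size
    if stop < trace.times.size:
        warnings.warn(
            "isotropic signal approaches zero: anisotropy window truncated "
            f"at t = {trace.times[stop]:.3g} ps",
            stacklevel=2,
        )
    sl = slice(0, stop)
    r = (trace.par[sl] - trace.perp[sl]) / denom[sl]
    return trace.times[sl], r


@dataclass
class AnisotropyResults:
    """Single-exponential anisotropy fit r(t) = r0 exp(-t/tau_R)."""

    r0: float
    tau_R: float
    r0_se: float
    tau_R_se: float
    times: np.ndarray
    r: np.ndarray
    chi2: float

    def summary(self) -> str:
        return (
            "Rotational anisotropy fit\n"
            "-" * 42 + "\n"
            f"r0    = {self.r0:8.4f} +/- {self.r0_se:.4f}\n"
            f"tau_R = {self.tau_R:8.4f} +/- {self.tau_R_se:.4f} ps\n"
            f"chi2  = {self.chi2:.4g}"
        )


class AnisotropyModel:
    """Rotational-diffusion model of the polarization anisotropy.

    The fit window starts at ``t_min`` (default 0.1 ps) to exclude delays
    contaminated by the coherent artefact; ``r0`` is fitted rather than
    fixed at the ideal 0.4 to absorb finite-pulse effects.  Residuals are
    weighted by the isotropic signal: for additive detector noise the
    error of r(t) = (S_par - S_perp)/(S_par + 2 S_perp) scales as the
    inverse of the denominator, so the weighting restores homoscedasticity
    and keeps the nearly signal-free tail from dominating the fit.
    """

    def __init__(self, trace: DecayTrace, t_min: float = 0.1):
        times, r = anisotropy(trace)
        denom = (trace.par + 2.0 * trace.perp)[: times.size]
        sel = times >= t_min
        if sel.sum() < 4:
            raise ValueError("too few points in the anisotropy fit window")
        self.times, self.r = times[sel], r[sel]
        w = np.abs(denom[sel])
        self.weights = w / w.max()

    def fit(self, init=(0.4, 3.0)) -> AnisotropyResults:
        res = least_squares(
            lambda p: (p[0] * np.exp(-self.times / p[1]) - self.r) * self.weights,
            np.asarray(init, dtype=float),
            bounds=([-0.5, 1e-3], [0.5, np.inf]),
            x_scale="jac",
        )
        se = _standard_errors(res)
        return AnisotropyResults(
            r0=float(res.x[0]),
            tau_R=float(res.x[1]),
            r0_se=float(se[0]),
            tau_R_se=float(se[1]),
            times=self.times,
            r=self.r,
            chi2=float(2.0 * res.cost),
        )
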
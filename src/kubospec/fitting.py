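"""Phenomenological multi-resonance fit of linear IR + 2DIR line shapes.

``FFCFSpectrumModel`` fits a small number of Kubo resonances — each with
center frequency omega01, anharmonic red-shift delta = omega01 - omega12,
amplitude weight and pure dephasing time T2*, plus (optionally shared)
spectral-diffusion parameters Delta1 and tau_c — simultaneously to a linear
absorption spectrum and a set of absorptive 2DIR maps.  The forward model
is the same cumulant-expansion engine used for simulation, so a data set
generated by :mod:`kubospec.synthetic` is fitted without model error.

Every data block (the linear spectrum and each 2D map) is normalized to
unit maximum amplitude and enters the least-squares objective with equal
weight; the optimizer is bounded trust-region least squares with an
optional multi-start protocol (centers jittered by a few cm^-1) guarding
against the local minima that strongly overlapping bands create.  With
four or more resonances inside one band the problem is typically
ill-conditioned and a warning is raised.

Usage follows the Model -> fit() -> Results convention::

    model = FFCFSpectrumModel(linear, maps, n_res=3)
    res = model.fit(seed=1)
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .lineshape import linear_absorption
from .params import FFCFParams, ResonanceSpec
from .spectra import Spectrum1D, Spectrum2D
from .twodir import SimConfig, simulate_2dir

__all__ = [
    "FFCFSpectrumModel",
    "FFCFSpectrumResults",
    "fit_ffcf",
    "residual_map",
    "rms",
]


def rms(values: np.ndarray) -> float:
    """Root-mean-square of an array (goodness-of-fit summary scalar)."""
    return float(np.sqrt(np.mean(np.asarray(values) ** 2)))


def residual_map(data: Spectrum2D, model: Spectrum2D) -> Spectrum2D:
    """Error map data - model on the shared grid.

    The returned spectrum carries the summary scalar as attribute ``rms``.
    Raises on any grid/metadata mismatch.
    """
    if not (
        np.array_equal(data.pump_axis, model.pump_axis)
        and np.array_equal(data.probe_axis, model.probe_axis)
    ):
        raise ValueError("residual_map requires identical grids")
    out = Spectrum2D(
        data.pump_axis,
        data.probe_axis,
        data.values - model.values,
        t2=data.t2,
        polarization=data.polarization,
    )
    out.rms = rms(out.values)
    return out


def _norm(a: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(a))
    return a / peak if peak > 0 else a


class FFCFSpectrumModel:
    """Joint Kubo-line-shape model of a linear spectrum and 2DIR maps.

    Parameters
    ----------
    linear : Spectrum1D
        Linear absorption spectrum.
    maps : list of Spectrum2D
        Absorptive 2DIR maps; all must share one polarization.
    n_res : int
        Number of diagonal resonances.
    share : tuple of str
        Parameters shared across resonances, subset of
        {'Delta1', 'tau_c', 'T2_star'}.
    gammas : sequence of (gamma1, gamma2)
        Population relaxation rates per resonance, ps^-1, held fixed
        during the fit (they are determined independently by pump-probe).
    config : SimConfig, optional
        2DIR engine settings; must match the settings used to produce
        model-comparable maps.
    """

    _BOUND_EPS = 2.0

    def __init__(
        self,
        linear: Spectrum1D,
        maps: list[Spectrum2D],
        n_res: int = 3,
        share: tuple[str, ...] = ("Delta1", "tau_c"),
        gammas=None,
        config: SimConfig | None = None,
        lifetime_factor: float = 0.5,
    ):
        if n_res < 1:
            raise ValueError("n_res must be >= 1")
        if n_res >= 4:
            warnings.warn(
                "fitting four or more overlapping resonances within one band "
                "is typically ill-conditioned",
                stacklevel=2,
            )
        pols = {m.polarization for m in maps}
        if len(pols) > 1:
            raise ValueError("all 2DIR maps must share one polarization")
        unknown = set(share) - {"Delta1", "tau_c", "T2_star"}
        if unknown:
            raise ValueError(f"unknown shared parameters: {sorted(unknown)}")
        self.linear = linear
        self.maps = list(maps)
        self.n_res = n_res
        self.share = tuple(share)
        self.config = config or SimConfig()
        self.lifetime_factor = lifetime_factor
        if gammas is None:
            gammas = [(0.0, 0.0)] * n_res
        if len(gammas) != n_res:
            raise ValueError("gammas must provide one (gamma1, gamma2) per resonance")
        self.gammas = [tuple(map(float, g)) for g in gammas]

        self._data_blocks = [_norm(linear.values)] + [_norm(m.values) for m in maps]
        self._block_scale = [1.0 / np.sqrt(b.size) for b in self._data_blocks]

    # ---- parameter vector layout -------------------------------------
    def _n_shared(self, name: str) -> int:
        return 1 if name in self.share else self.n_res

    def _pack_layout(self):
        n = self.n_res
        layout = [("omega01", n), ("delta", n)]
        layout.append(("T2_star", self._n_shared("T2_star")))
        layout.append(("amp", n - 1))  # amplitude of resonance 0 fixed to 1
        layout.append(("Delta1", self._n_shared("Delta1")))
        layout.append(("tau_c", self._n_shared("tau_c")))
        return layout

    def _unpack(self, p: np.ndarray) -> dict[str, np.ndarray]:
        out, pos = {}, 0
        for name, size in self._pack_layout():
            out[name] = np.asarray(p[pos: pos + size], dtype=float)
            pos += size
        return out

    def _pack(self, d: dict[str, np.ndarray]) -> np.ndarray:
        return np.concatenate([np.atleast_1d(d[name]) for name, _ in self._pack_layout()])

    def _expand(self, arr: np.ndarray) -> np.ndarray:
        return np.repeat(arr, self.n_res) if arr.size == 1 else arr

    def resonances_from(self, p: np.ndarray) -> list[ResonanceSpec]:
        """Materialize the resonance list described by a parameter vector."""
        d = self._unpack(p)
        T2 = self._expand(d["T2_star"])
        D1 = self._expand(d["Delta1"])
        tc = self._expand(d["tau_c"])
        amps = np.concatenate([[1.0], d["amp"]])
        weights = amps / amps.sum()
        out = []
        for r in range(self.n_res):
            ffcf = FFCFParams(
                T2_star=T2[r],
                Delta1=D1[r],
                tau_c=tc[r],
                gamma1=self.gammas[r][0],
                gamma2=self.gammas[r][1],
            )
            out.append(
                ResonanceSpec(
                    omega01=d["omega01"][r],
                    omega12=d["omega01"][r] - d["delta"][r],
                    ffcf=ffcf,
                    weight=float(weights[r]),
                )
            )
        return out

    # ---- forward model ----------------------------------------------
    def _model_blocks(self, p: np.ndarray) -> list[np.ndarray]:
        resonances = self.resonances_from(p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            blocks = [
                _norm(
                    linear_absorption(
                        resonances,
                        self.linear.axis,
                        lifetime_factor=self.lifetime_factor,
                    ).values
                )
            ]
            for m in self.maps:
                sim = simulate_2dir(
                    resonances,
                    m.t2,
                    m.pump_axis,
                    m.probe_axis,
                    m.polarization,
                    config=self.config,
                )
                blocks.append(_norm(sim.values))
        return blocks

    def _residuals(self, p: np.ndarray) -> np.ndarray:
        # the amplitude of each block is profiled out analytically
        # (variable projection): normalizing by the noisy data maximum
        # instead would bias every shape parameter
        blocks = self._model_blocks(p)
        out = []
        for mb, db, s in zip(blocks, self._data_blocks, self._block_scale):
            denom = np.vdot(mb, mb).real
            scale = np.vdot(mb, db).real / denom if denom > 0 else 1.0
            out.append(((scale * mb - db) * s).ravel())
        return np.concatenate(out)

    # ---- initial values and bounds ----------------------------------
    def default_init(self) -> np.ndarray:
        """Moment-based starting point from the linear band shape."""
        x, y = self.linear.axis, np.clip(_norm(self.linear.values), 0.0, None)
        w = y / y.sum()
        mean = float(np.sum(w * x))
        sd = float(np.sqrt(np.sum(w * (x - mean) ** 2)))
        if self.n_res == 1:
            centers = np.array([mean])
        else:
            centers = np.linspace(mean - 0.8 * sd, mean + 0.8 * sd, self.n_res)
        d = {
            "omega01": centers,
            "delta": np.full(self.n_res, 6.0),
            "T2_star": np.full(self._n_shared("T2_star"), 1.0),
            "amp": np.ones(self.n_res - 1),
            "Delta1": np.full(self._n_shared("Delta1"), max(0.5 * sd, 1.0)),
            "tau_c": np.full(self._n_shared("tau_c"), 1.5),
        }
        return self._pack(d)

    def _bounds(self):
        lo = {
            "omega01": np.full(self.n_res, self.linear.axis[0] + self._BOUND_EPS),
            "delta": np.zeros(self.n_res),
            "T2_star": np.full(self._n_shared("T2_star"), 0.05),
            "amp": np.full(self.n_res - 1, 1e-4),
            "Delta1": np.zeros(self._n_shared("Delta1")),
            "tau_c": np.full(self._n_shared("tau_c"), 0.02),
        }
        hi = {
            "omega01": np.full(self.n_res, self.linear.axis[-1] - self._BOUND_EPS),
            "delta": np.full(self.n_res, 30.0),
            "T2_star": np.full(self._n_shared("T2_star"), 20.0),
            "amp": np.full(self.n_res - 1, 1e3),
            "Delta1": np.full(self._n_shared("Delta1"), 40.0),
            "tau_c": np.full(self._n_shared("tau_c"), 50.0),
        }
        return self._pack(lo), self._pack(hi)

    # ---- fitting -----------------------------------------------------
    def fit(
        self,
        init: np.ndarray | None = None,
        n_starts: int = 5,
        jitter: float = 5.0,
        seed: int = 0,
        max_nfev: int | None = None,
    ) -> "FFCFSpectrumResults":
        """Bounded trust-region least squares with multi-start.

        ``n_starts - 1`` additional starts jitter the center frequencies
        uniformly within ``+/- jitter`` cm^-1; the lowest-chi^2 solution is
        kept.  Raises only on total failure; non-convergence of the best
        start is reported via ``FFCFSpectrumResults.converged`` with the
        last residual norm retained.
        """
        if init is None:
            init = self.default_init()
        init = np.asarray(init, dtype=float)
        lo, hi = self._bounds()
        if np.any(init < lo) or np.any(init > hi):
            raise ValueError("initial parameters violate bounds")
        rng = np.random.default_rng(seed)
        starts = [init]
        n_c = self.n_res
        for _ in range(max(n_starts - 1, 0)):
            p = init.copy()
            p[:n_c] = np.clip(
                p[:n_c] + rng.uniform(-jitter, jitter, n_c), lo[:n_c], hi[:n_c]
            )
            starts.append(p)
        best = None
        for p0 in starts:
            res = least_squares(
                self._residuals,
                p0,
                bounds=(lo, hi),
                x_scale="jac",
                max_nfev=max_nfev,
            )
            if best is None or res.cost < best.cost:
                best = res
        return FFCFSpectrumResults(self, best)


def _standard_errors(res) -> np.ndarray:
    m, n = res.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.pinv(res.jac.T @ res.jac) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, None)), cov
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full(n, np.nan), np.full((n, n), np.nan)


class FFCFSpectrumResults:
    """Converged estimates, uncertainties and residuals of an FFCF fit.

    Resonances are reported sorted by omega01 so the output is invariant
    to the ordering of the starting values.
    """

    def __init__(self, model: FFCFSpectrumModel, res):
        self.model = model
        self._res = res
        self.converged = bool(res.success)
        self.chi2 = float(2.0 * res.cost)
        m, n = res.jac.shape
        self.redchi = self.chi2 / max(m - n, 1)
        if not self.converged:
            warnings.warn(
                "fit did not converge: last residual norm "
                f"{np.linalg.norm(res.fun):.3g}",
                stacklevel=2,
            )
        bse, cov = _standard_errors(res)
        self._bse_vec, self._cov = bse, cov
        order = np.argsort(self.model._unpack(res.x)["omega01"])
        self._order = order
        self._build_tables()

    def _build_tables(self) -> None:
        model, res = self.model, self._res
        d = model._unpack(res.x)
        e = model._unpack(self._bse_vec)
        n = model.n_res
        amps = np.concatenate([[1.0], d["amp"]])
        weights = amps / amps.sum()
        weight_se = self._weight_se(amps)

        def exp_val(name):
            return model._expand(d[name]), model._expand(e[name])

        T2, T2e = exp_val("T2_star")
        D1, D1e = exp_val("Delta1")
        tc, tce = exp_val("tau_c")
        rows = []
        for r in self._order:
            rows.append(
                {
                    "omega01": d["omega01"][r],
                    "omega01_se": e["omega01"][r],
                    "omega12": d["omega01"][r] - d["delta"][r],
                    "omega12_se": np.hypot(e["omega01"][r], e["delta"][r]),
                    "weight": weights[r],
                    "weight_se": weight_se[r],
                    "Delta1": D1[r],
                    "Delta1_se": D1e[r],
                    "T2_star": T2[r],
                    "T2_star_se": T2e[r],
                    "tau_c": tc[r],
                    "tau_c_se": tce[r],
                    "gamma1": model.gammas[r][0],
                    "gamma2": model.gammas[r][1],
                }
            )
        self.params = pd.DataFrame(rows).reset_index(drop=True)

    def _weight_se(self, amps: np.ndarray) -> np.ndarray:
        """Delta-method standard errors of the normalized weights."""
        model = self.model
        n = model.n_res
        if n == 1:
            return np.zeros(1)
        pos = 0
        for name, size in model._pack_layout():
            if name == "amp":
                break
            pos += size
        cov_a = self._cov[pos: pos + n - 1, pos: pos + n - 1]
        S = amps.sum()
        # d w_r / d a_s for s = 1..n-1 (a_0 fixed)
        J = np.empty((n, n - 1))
        for r in range(n):
            for s in range(1, n):
                J[r, s - 1] = ((1.0 if r == s else 0.0) * S - amps[r]) / S**2
        var = np.einsum("rs,st,rt->r", J, cov_a, J)
        return np.sqrt(np.clip(var, 0.0, None))

    @property
    def resonances(self) -> list[ResonanceSpec]:
        res_list = self.model.resonances_from(self._res.x)
        return [res_list[r] for r in self._order]

    @property
    def dominant(self) -> pd.Series:
        """Parameter row of the highest-weight resonance."""
        return self.params.loc[self.params["weight"].idxmax()]

    @property
    def residual_linear(self) -> Spectrum1D:
        blocks = self.model._model_blocks(self._res.x)
        return Spectrum1D(
            self.model.linear.axis, self.model._data_blocks[0] - blocks[0]
        )

    @property
    def residual_maps(self) -> list[Spectrum2D]:
        """Error 2D spectra: normalized data minus fitted model."""
        blocks = self.model._model_blocks(self._res.x)
        out = []
        for m, db, mb in zip(self.model.maps, self._data_blocks_2d(), blocks[1:]):
            data = Spectrum2D(m.pump_axis, m.probe_axis, db, t2=m.t2,
                              polarization=m.polarization)
            fitted = Spectrum2D(m.pump_axis, m.probe_axis, mb, t2=m.t2,
                                polarization=m.polarization)
            out.append(residual_map(data, fitted))
        return out

    def _data_blocks_2d(self):
        return self.model._data_blocks[1:]

    def summary(self) -> str:
        lines = [
            "Kubo FFCF line-shape fit",
            "=" * 78,
            f"resonances: {self.model.n_res}   shared: {', '.join(self.model.share) or 'none'}"
            f"   converged: {self.converged}",
            f"chi2 = {self.chi2:.6g}   reduced chi2 = {self.redchi:.3g}",
            "-" * 78,
            f"{'omega01':>9} {'omega12':>9} {'weight':>7} {'Delta1':>7} "
            f"{'T2*/ps':>7} {'tau_c':>7} {'g1':>5} {'g2':>5}",
        ]
        for _, row in self.params.iterrows():
            lines.append(
                f"{row.omega01:9.1f} {row.omega12:9.1f} {row.weight:7.3f} "
                f"{row.Delta1:7.2f} {row.T2_star:7.3f} {row.tau_c:7.3f} "
                f"{row.gamma1:5.2f} {row.gamma2:5.2f}"
            )
            lines.append(
                f"({row.omega01_se:8.2f})({row.omega12_se:8.2f})"
                f"({row.weight_se:6.3f})({row.Delta1_se:6.2f})"
                f"({row.T2_star_se:6.3f})({row.tau_c_se:6.3f})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready parameter table (column names follow the
        conventional fit-table layout)."""
        return {
            "converged": self.converged,
            "chi2": self.chi2,
            "resonances": self.params.to_dict(orient="records"),
        }


def fit_ffcf(
    linear: Spectrum1D,
    maps: list[Spectrum2D],
    n_res: int = 3,
    share: tuple[str, ...] = ("Delta1", "tau_c"),
    init: np.ndarray | None = None,
    gammas=None,
    config: SimConfig | None = None,
    **fit_kw,
) -> FFCFSpectrumResults:
    """Convenience wrapper: build an :class:`FFCFSpectrumModel` and fit."""
    model = FFCFSpectrumModel(
        linear, maps, n_res=n_res, share=share, gammas=gammas, config=config
    )
    return model.fit(init=init, **fit_kw)
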
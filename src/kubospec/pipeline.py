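"""Config-driven workflow: generate -> fit -> simulate -> mix -> compare.

``RunConfig`` validates a plain dict (unknown keys are rejected before any
computation) and ``run_pipeline`` executes the requested stages, writing
TSV spectra plus a JSON report containing every fitted parameter, residual
RMS values and provenance (seed, package version, mixing ratios).  Any
stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .fitting import FFCFSpectrumModel, residual_map, rms
from .spectra import Spectrum1D, Spectrum2D
from .synthetic import carbonyl_band_dataset
from .twodir import SimConfig, SpeciesMixture, mix_species, simulate_2dir

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("kubospec")

_KNOWN_KEYS = {
    "stages",
    "out_dir",
    "seed",
    "noise",
    "t2s",
    "polarization",
    "n_res",
    "share",
    "n_starts",
    "mix_ratio",
    "verbose",
}

_KNOWN_STAGES = ("generate", "fit", "simulate", "mix", "compare")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list[str] = field(default_factory=list)
    out_dir: str = "pipeline_out"
    seed: int = 0
    noise: float = 0.01
    t2s: list[float] = field(default_factory=lambda: [0.9, 2.0])
    polarization: str = "parallel"
    n_res: int = 3
    share: list[str] = field(default_factory=lambda: ["Delta1", "tau_c"])
    n_starts: int = 5
    mix_ratio: list[float] = field(default_factory=lambda: [3.0, 1.0])
    verbose: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**d)
        bad = [s for s in cfg.stages if s not in _KNOWN_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad} (known: {_KNOWN_STAGES})")
        if cfg.noise < 0:
            raise ValueError("noise must be >= 0")
        return cfg


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured stages and return (and write) the report."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    logging.basicConfig(level=logging.DEBUG if config.verbose else logging.INFO)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimConfig()
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "version": __version__,
            "stages": list(config.stages),
            "noise": config.noise,
            "polarization": config.polarization,
            "sim_config": asdict(sim_cfg),
        },
        "stages": {},
    }
    state: dict = {}

    for stage in config.stages:
        logger.info("pipeline stage: %s", stage)
        try:
            if stage == "generate":
                linear, maps, truth = carbonyl_band_dataset(
                    noise=config.noise,
                    seed=config.seed,
                    t2s=tuple(config.t2s),
                    pol=config.polarization,
                    config=sim_cfg,
                )
                linear.write(out_dir / "linear.tsv")
                for m in maps:
                    m.write(out_dir / f"map_t2_{m.t2:g}.tsv")
                state.update(linear=linear, maps=maps, truth=truth)
                report["stages"]["generate"] = {
                    "files": ["linear.tsv"]
                    + [f"map_t2_{m.t2:g}.tsv" for m in maps],
                }
            elif stage == "fit":
                if "linear" not in state:
                    state["linear"] = Spectrum1D.read(out_dir / "linear.tsv")
                    state["maps"] = [
                        Spectrum2D.read(p) for p in sorted(out_dir.glob("map_t2_*.tsv"))
                    ]
                gammas = None
                if "truth" in state:
                    gammas = [
                        (r.ffcf.gamma1, r.ffcf.gamma2)
                        for r in state["truth"].resonances
                    ]
                model = FFCFSpectrumModel(
                    state["linear"],
                    state["maps"],
                    n_res=config.n_res,
                    share=tuple(config.share),
                    gammas=gammas,
                    config=sim_cfg,
                )
                result = model.fit(n_starts=config.n_starts, seed=config.seed)
                state["fit"] = result
                report["stages"]["fit"] = result.to_dict()
                report["stages"]["fit"]["residual_rms"] = {
                    f"t2_{m.t2:g}": r.rms
                    for m, r in zip(state["maps"], result.residual_maps)
                }
            elif stage == "simulate":
                resonances = (
                    state["fit"].resonances
                    if "fit" in state
                    else state["truth"].resonances
                )
                grid = state["maps"][0].pump_axis if "maps" in state else None
                if grid is None:
                    raise ValueError("no grids available; run generate first")
                sims = [
                    simulate_2dir(
                        resonances, t2, grid, grid, config.polarization, config=sim_cfg
                    )
                    for t2 in config.t2s
                ]
                state["sims"] = sims
                for s in sims:
                    s.write(out_dir / f"sim_t2_{s.t2:g}.tsv")
                report["stages"]["simulate"] = {
                    "files": [f"sim_t2_{s.t2:g}.tsv" for s in sims]
                }
            elif stage == "mix":
                if "sims" not in state or len(state["sims"]) < 2:
                    raise ValueError("mix needs at least two simulated species maps")
                resonances = (
                    state["fit"].resonances
                    if "fit" in state
                    else state["truth"].resonances
                )
                grid = state["maps"][0].pump_axis
                mixture = SpeciesMixture(
                    members=[
                        ("component-a", resonances, {}, config.mix_ratio[0]),
                        ("component-b", resonances, {}, config.mix_ratio[1]),
                    ]
                )
                mixed = mix_species(
                    mixture,
                    config.t2s[0],
                    grid,
                    grid,
                    config.polarization,
                    config=sim_cfg,
                )
                mixed.write(out_dir / "mixed.tsv")
                report["stages"]["mix"] = {
                    "ratio": list(config.mix_ratio),
                    "file": "mixed.tsv",
                }
            elif stage == "compare":
                if "maps" not in state or "sims" not in state:
                    raise ValueError("compare needs generated and simulated maps")
                rms_values = {}
                for data, sim in zip(state["maps"], state["sims"]):
                    resid = residual_map(data, sim)
                    rms_values[f"t2_{data.t2:g}"] = resid.rms
                report["stages"]["compare"] = {"residual_rms": rms_values}
        except Exception as exc:
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=float))
    logger.info("report written to %s", report_path)
    return report
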
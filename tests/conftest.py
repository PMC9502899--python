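"""Shared fixtures: reference parameter sets and a reduced-scale synthetic
data set for the fitting tests (small grids and a coarse response engine so
round-trip fits stay fast; generator and fit model share the engine, so
recovery accuracy is unaffected)."""

from __future__ import annotations

import numpy as np
import pytest

from kubospec.params import FFCFParams, ResonanceSpec
from kubospec.synthetic import carbonyl_band_dataset, carbonyl_band_resonances
from kubospec.twodir import SimConfig


@pytest.fixture(scope="session")
def band_resonances() -> list[ResonanceSpec]:
    return carbonyl_band_resonances()


@pytest.fixture(scope="session")
def dominant_ffcf() -> FFCFParams:
    """FFCF of the dominant carbonyl resonance."""
    return FFCFParams(T2_star=0.96, Delta1=8.4, tau_c=1.57, gamma1=0.98, gamma2=1.3)


SMALL_CONFIG = SimConfig(t_max=2.5, dt=0.025, n_fft=256)
SMALL_LINEAR_GRID = np.arange(1550.0, 1670.0 + 1e-9, 0.5)
SMALL_MAP_GRID = np.arange(1565.0, 1650.0 + 1e-9, 1.5)


def small_band_dataset(noise: float, seed: int):
    """Reduced-scale carbonyl-band data set (one 2DIR map, coarse grids)."""
    return carbonyl_band_dataset(
        noise=noise,
        seed=seed,
        t2s=(0.9,),
        linear_grid=SMALL_LINEAR_GRID,
        map_grid=SMALL_MAP_GRID,
        config=SMALL_CONFIG,
    )


@pytest.fixture(scope="session")
def small_noiseless_dataset():
    return small_band_dataset(noise=0.0, seed=0)
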
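"""Absorptive 2DIR simulation: orientational factors against a Monte-Carlo
isotropic average, pathway structure (signs and peak positions), cross-peak
cancellation, species mixing, and center-line-slope spectral diffusion."""

import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.spatial.transform import Rotation

from kubospec.params import FFCFParams, ResonanceSpec
from kubospec.twodir import (
    SimConfig,
    SpeciesMixture,
    center_line_slope,
    mix_species,
    orientational_factor,
    simulate_2dir,
)

NARROW = FFCFParams(T2_star=1.5, Delta1=2.0, tau_c=1.0, gamma1=0.2, gamma2=0.3)
CFG = SimConfig(t_max=6.0, dt=0.02, n_fft=1024)
GRID = np.arange(1560.0, 1660.0 + 1e-9, 0.5)


def _peak_positions(spec):
    imin = np.unravel_index(np.argmin(spec.values), spec.values.shape)
    imax = np.unravel_index(np.argmax(spec.values), spec.values.shape)
    return (
        (spec.probe_axis[imin[0]], spec.pump_axis[imin[1]]),
        (spec.probe_axis[imax[0]], spec.pump_axis[imax[1]]),
    )


class TestOrientationalFactor:
    def test_exact_values(self):
        assert orientational_factor(0.0, "parallel") == pytest.approx(0.2)
        assert orientational_factor(90.0, "parallel") == pytest.approx(1.0 / 15.0)
        assert orientational_factor(90.0, "perpendicular") == pytest.approx(2.0 / 15.0)
        assert orientational_factor(0.0, "magic") == pytest.approx(1.0 / 9.0)

    @pytest.mark.parametrize("theta", [0.0, 30.0, 54.7, 90.0, 120.0, 180.0])
    def test_parallel_plus_two_perpendicular_is_isotropic(self, theta):
        total = orientational_factor(theta, "parallel") + 2.0 * orientational_factor(
            theta, "perpendicular"
        )
        assert total == pytest.approx(1.0 / 3.0, abs=1e-14)

    @pytest.mark.parametrize("theta", [0.0, 45.0, 90.0, 135.0])
    def test_against_monte_carlo_isotropic_average(self, theta):
        """<(Z.mu1)^2 (E.mu2)^2> over random molecular orientations matches
        the closed-form parallel/perpendicular factors."""
        rng = np.random.default_rng(42)
        rots = Rotation.random(1_000_000, random_state=rng)
        th = np.deg2rad(theta)
        mu1 = np.array([0.0, 0.0, 1.0])
        mu2 = np.array([np.sin(th), 0.0, np.cos(th)])
        m1 = rots.apply(mu1)
        m2 = rots.apply(mu2)
        par = np.mean(m1[:, 2] ** 2 * m2[:, 2] ** 2)
        perp = np.mean(m1[:, 2] ** 2 * m2[:, 0] ** 2)
        assert orientational_factor(theta, "parallel") == pytest.approx(par, abs=5e-4)
        assert orientational_factor(theta, "perpendicular") == pytest.approx(
            perp, abs=5e-4
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            orientational_factor(-1.0, "parallel")
        with pytest.raises(ValueError):
            orientational_factor(30.0, "circular")


class TestSingleResonance:
    def test_peak_signs_and_positions(self):
        """One negative diagonal peak at (w01, w01), one positive peak at
        (w01, w12); probe separation equals the anharmonicity."""
        r = ResonanceSpec(1620.0, 1590.0, NARROW)
        spec = simulate_2dir([r], 0.5, GRID, GRID, config=CFG)
        (gb_probe, gb_pump), (esa_probe, esa_pump) = _peak_positions(spec)
        assert gb_pump == pytest.approx(1620.0, abs=0.5)
        assert gb_probe == pytest.approx(1620.0, abs=0.5)
        assert esa_pump == pytest.approx(1620.0, abs=0.5)
        assert esa_probe == pytest.approx(1590.0, abs=0.5)
        assert gb_probe - esa_probe == pytest.approx(r.anharmonicity, abs=1.0)

    def test_absorptive_output_real_and_t2_invariant_positions(self):
        r = ResonanceSpec(1610.0, 1585.0, NARROW)
        positions = []
        for t2 in (0.2, 1.0, 3.0):
            spec = simulate_2dir([r], t2, GRID, GRID, config=CFG)
            assert np.isrealobj(spec.values)
            assert np.all(np.isfinite(spec.values))
            positions.append(_peak_positions(spec)[0])
        assert positions[0] == positions[1] == positions[2]

    def test_bleach_volume_scales_with_weight_and_orientation(self):
        r1 = ResonanceSpec(1610.0, 1585.0, NARROW, weight=1.0)
        r2 = ResonanceSpec(1610.0, 1585.0, NARROW, weight=0.4)
        kw = dict(t2=0.5, pump_grid=GRID, probe_grid=GRID, config=CFG)
        v1 = simulate_2dir([r1], **kw).values
        v2 = simulate_2dir([r2], **kw).values
        assert np.sum(v2[v2 < 0]) / np.sum(v1[v1 < 0]) == pytest.approx(0.4, rel=1e-6)
        vperp = simulate_2dir([r1], pol="perpendicular", **kw).values
        ratio = orientational_factor(0.0, "perpendicular") / orientational_factor(
            0.0, "parallel"
        )
        assert np.sum(vperp[vperp < 0]) / np.sum(v1[v1 < 0]) == pytest.approx(
            ratio, rel=1e-6
        )

    def test_input_validation(self):
        r = ResonanceSpec(1610.0, 1585.0, NARROW)
        with pytest.raises(ValueError):
            simulate_2dir([r], -0.1, GRID, GRID)
        with pytest.raises(ValueError):
            simulate_2dir([], 0.5, GRID, GRID)


class TestCrossPeaks:
    def test_zero_coupling_equals_uncoupled_spectrum(self):
        """With x_ij = 0 the cross bleach and ESA cancel exactly: the
        coupled simulation is identical to the diagonal-only one."""
        r1 = ResonanceSpec(1620.0, 1590.0, NARROW)
        r2 = ResonanceSpec(1650.0, 1622.0, NARROW, weight=0.5, dipole=(1.0, 0.0, 0.0))
        kw = dict(t2=0.5, pump_grid=GRID, probe_grid=GRID, config=CFG)
        plain = simulate_2dir([r1, r2], **kw)
        coupled = simulate_2dir([r1, r2], couplings={(0, 1): 0.0}, **kw)
        assert np.allclose(plain.values, coupled.values, atol=1e-12)

    def test_cross_peak_grows_with_coupling(self):
        r1 = ResonanceSpec(1620.0, 1590.0, NARROW)
        r2 = ResonanceSpec(1650.0, 1622.0, NARROW, weight=0.5)
        kw = dict(t2=0.5, pump_grid=GRID, probe_grid=GRID, config=CFG)
        base = simulate_2dir([r1, r2], **kw).values
        amps = []
        for x in (0.0, 1.0, 2.0, 4.0):
            v = simulate_2dir([r1, r2], couplings={(0, 1): -x}, **kw).values
            diff = np.abs(v - base)
            # cross region: pump near r1, probe near r2
            jx = np.abs(GRID - 1620.0) <= 8
            iy = np.abs(GRID - 1648.0) <= 10
            amps.append(diff[np.ix_(iy, jx)].max())
        assert amps[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(amps) > 0)

    def test_invalid_coupling_indices(self):
        r = ResonanceSpec(1620.0, 1590.0, NARROW)
        with pytest.raises(ValueError):
            simulate_2dir([r], 0.5, GRID, GRID, couplings={(0, 1): 1.0})


class TestSpeciesMixing:
    kw = dict(t2=0.9, pump_grid=GRID, probe_grid=GRID, config=CFG)

    def test_single_species_identity(self):
        r = [ResonanceSpec(1610.0, 1585.0, NARROW)]
        mix = SpeciesMixture(members=[("only", r, {}, 1.0)])
        assert np.allclose(
            mix_species(mix, **self.kw).values,
            simulate_2dir(r, **self.kw).values,
        )

    def test_identical_members_idempotent(self):
        r = [ResonanceSpec(1610.0, 1585.0, NARROW)]
        mix = SpeciesMixture(members=[("a", r, {}, 0.5), ("b", r, {}, 0.5)])
        assert np.allclose(
            mix_species(mix, **self.kw).values,
            simulate_2dir(r, **self.kw).values,
            atol=1e-12,
        )

    def test_three_to_one_mixture_broadens_diagonal(self):
        """Mixing spectrally displaced species 3:1 broadens the diagonal
        band beyond either member alone."""
        ra = [ResonanceSpec(1602.0, 1574.0, NARROW)]
        rb = [ResonanceSpec(1607.0, 1579.0, NARROW)]
        mix = SpeciesMixture(members=[("hydrated", ra, {}, 3.0), ("dry", rb, {}, 1.0)])
        mixed = mix_species(mix, **self.kw)

        def diag_fwhm(spec):
            diag = -np.array(
                [np.interp(w, spec.probe_axis, spec.values[:, j])
                 for j, w in enumerate(spec.pump_axis)]
            )
            fine = np.arange(spec.pump_axis[0], spec.pump_axis[-1], 0.02)
            d = np.interp(fine, spec.pump_axis, diag)
            half = d >= 0.5 * d.max()
            return fine[half][-1] - fine[half][0]

        wa = diag_fwhm(simulate_2dir(ra, **self.kw))
        wb = diag_fwhm(simulate_2dir(rb, **self.kw))
        wm = diag_fwhm(mixed)
        assert wm > max(wa, wb)

    def test_all_zero_weights_rejected(self):
        r = [ResonanceSpec(1610.0, 1585.0, NARROW)]
        with pytest.raises(ValueError):
            SpeciesMixture(members=[("a", r, {}, 0.0)])


class TestSpectralDiffusion:
    def test_cls_recovers_correlation_time(self, dominant_ffcf):
        """CLS(t2) decays exponentially with the input tau_c = 1.57 ps;
        the fitted constant agrees within 10%."""
        r = ResonanceSpec(1604.1, 1598.5, dominant_ffcf, weight=1.0)
        t2s = np.array([0.2, 0.5, 1.0, 2.0, 3.0, 5.0])
        cls = [
            center_line_slope(
                simulate_2dir([r], t2, GRID, GRID, config=SimConfig.fine()), 1604.1
            )
            for t2 in t2s
        ]
        popt, _ = curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau), t2s, cls, p0=[0.5, 1.0]
        )
        assert popt[1] == pytest.approx(1.57, rel=0.10)

    def test_cls_vanishes_when_memory_lost(self, dominant_ffcf):
        """At t2 >> tau_c the frequency correlation (ellipticity) is gone."""
        r = ResonanceSpec(1604.1, 1598.5, dominant_ffcf, weight=1.0)
        early = center_line_slope(
            simulate_2dir([r], 0.2, GRID, GRID, config=SimConfig.fine()), 1604.1
        )
        late = center_line_slope(
            simulate_2dir([r], 12.0, GRID, GRID, config=SimConfig.fine()), 1604.1
        )
        assert early > 0.2
        assert abs(late) < 0.02


class TestOrientationalProperties:
    from hypothesis import given, settings, strategies as st

    @given(theta=st.floats(0.0, 180.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_isotropic_sum_rule_any_angle(self, theta):
        """parallel + 2 x perpendicular equals the angle-free isotropic
        total 1/3 for every dipole angle."""
        total = orientational_factor(theta, "parallel") + 2.0 * orientational_factor(
            theta, "perpendicular"
        )
        assert total == pytest.approx(1.0 / 3.0, abs=1e-12)

    @given(theta=st.floats(0.0, 180.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_factors_positive_and_bounded(self, theta):
        for pol in ("parallel", "perpendicular", "magic"):
            y = orientational_factor(theta, pol)
            assert 0.0 < y <= 0.2
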
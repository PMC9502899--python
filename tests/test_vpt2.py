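"""VPT2 anharmonicity constants checked against brute-force variational
diagonalization in a harmonic-oscillator product basis and against the
exact Morse-oscillator spectrum."""

import itertools
import math

import numpy as np
import pytest

from kubospec.vpt2 import (
    AnharmonicField,
    diagonal_x,
    offdiagonal_x,
    shifted_frequencies,
    x_matrix,
)
from kubospec.synthetic import gen_anharmonic_fixture


# ---- variational oracle ------------------------------------------------

def _q_matrix(nmax: int) -> np.ndarray:
    """Dimensionless coordinate operator in the harmonic basis."""
    q = np.zeros((nmax, nmax))
    for n in range(nmax - 1):
        q[n, n + 1] = q[n + 1, n] = math.sqrt((n + 1) / 2.0)
    return q


def _multiplicity(key: tuple[int, ...]) -> int:
    """Number of distinct permutations of the index multiset."""
    perms = set(itertools.permutations(key))
    return len(perms)


def variational_levels(field: AnharmonicField, nmax: int) -> np.ndarray:
    """Eigenvalues of the full vibrational Hamiltonian in a product basis
    of ``nmax`` harmonic levels per mode (cm^-1)."""
    nmode = field.n_modes
    q = _q_matrix(nmax)
    eye = np.eye(nmax)

    def mode_op(ops: dict[int, np.ndarray]) -> np.ndarray:
        out = None
        for m in range(nmode):
            term = ops.get(m, eye)
            out = term if out is None else np.kron(out, term)
        return out

    dim = nmax**nmode
    H = np.zeros((dim, dim))
    for m, w in enumerate(field.omegas):
        n_op = np.diag(np.arange(nmax) + 0.5)
        H += w * mode_op({m: n_op})
    for key, phi in field.cubic.items():
        ops: dict[int, np.ndarray] = {}
        for m in key:
            ops[m] = ops.get(m, eye) @ q
        H += (_multiplicity(key) / 6.0) * phi * mode_op(ops)
    for key, phi in field.quartic.items():
        ops = {}
        for m in key:
            ops[m] = ops.get(m, eye) @ q
        H += (_multiplicity(key) / 24.0) * phi * mode_op(ops)
    return np.linalg.eigvalsh(H)


def _state_energy(field, levels, quanta, nmax):
    """Energy of the eigenstate adiabatically connected to a harmonic
    product state, located by proximity to the harmonic estimate."""
    target = sum(w * (n + 0.5) for w, n in zip(field.omegas, quanta))
    return levels[np.argmin(np.abs(levels - target))]


# ---- tests -------------------------------------------------------------

class TestDiagonalX:
    def test_harmonic_limit_is_zero(self):
        field = AnharmonicField(omegas=[1600.0, 1200.0])
        assert diagonal_x(field, 0) == 0.0
        assert offdiagonal_x(field, 0, 1) == 0.0

    def test_pure_quartic_reduction(self):
        field = AnharmonicField(omegas=[1600.0], quartic={(0, 0, 0, 0): -44.8})
        assert diagonal_x(field, 0) == pytest.approx(-44.8 / 16.0, abs=1e-14)

    @pytest.mark.parametrize("wexe", [5.0, 10.0, 17.0])
    def test_morse_reproduces_exact_anharmonicity(self, wexe):
        """VPT2 on the Morse force field gives x_ii = -we_xe, the exact
        Morse level anharmonicity E(n) = we(n+1/2) - we_xe (n+1/2)^2."""
        field = gen_anharmonic_fixture("morse", omega_e=1700.0, omega_e_x_e=wexe)
        x = diagonal_x(field, 0)
        E = lambda n: 1700.0 * (n + 0.5) - wexe * (n + 0.5) ** 2
        x_exact = ((E(2) - E(1)) - (E(1) - E(0))) / 2.0
        assert x == pytest.approx(x_exact, rel=0.05)
        assert x == pytest.approx(-wexe, rel=1e-10)

    @pytest.mark.parametrize("wexe", [0.5, 1.0, 2.0])
    def test_morse_variational_oracle_weak_anharmonicity(self, wexe):
        """A 40-level variational diagonalization of the truncated
        cubic+quartic potential confirms VPT2 within 5% of the shift in
        the weak-anharmonicity regime (beyond it, the truncated expansion
        itself departs from Morse at higher order)."""
        field = gen_anharmonic_fixture("morse", omega_e=1700.0, omega_e_x_e=wexe)
        x = diagonal_x(field, 0)
        levels = np.sort(variational_levels(field, nmax=40))
        x_var = ((levels[2] - levels[1]) - (levels[1] - levels[0])) / 2.0
        assert x == pytest.approx(x_var, rel=0.05)

    def test_near_resonant_term_deperturbed(self):
        # omega_k ~ 2 omega_i triggers exclusion of the phi_iik term
        field = AnharmonicField(
            omegas=[800.0, 1610.0], cubic={(0, 0, 1): 30.0}
        )
        with pytest.warns(UserWarning, match="near-resonant"):
            x = diagonal_x(field, 0)
        assert x == 0.0  # only the resonant term contributed


class TestOffdiagonalX:
    def test_uncoupled_modes_give_zero(self):
        field = AnharmonicField(
            omegas=[1600.0, 1200.0],
            cubic={(0, 0, 0): -50.0},
            quartic={(0, 0, 0, 0): 30.0, (1, 1, 1, 1): 20.0},
        )
        assert offdiagonal_x(field, 0, 1) == 0.0

    def test_quartic_coupling_reduction_and_oracle(self):
        """x_ij = phi_iijj/4 exactly; the 2-mode variational combination
        band confirms it."""
        field = gen_anharmonic_fixture("two_mode", phi_iijj=-8.0)
        x = offdiagonal_x(field, 0, 1)
        assert x == pytest.approx(-2.0, abs=1e-12)
        levels = variational_levels(field, nmax=24)
        e00 = _state_energy(field, levels, (0, 0), 24)
        e10 = _state_energy(field, levels, (1, 0), 24)
        e01 = _state_energy(field, levels, (0, 1), 24)
        e11 = _state_energy(field, levels, (1, 1), 24)
        comb_expected = (e10 - e00) + (e01 - e00) + x
        assert e11 - e00 == pytest.approx(comb_expected, rel=0.02)
        assert (e11 - e10 - e01 + e00) == pytest.approx(x, rel=0.05)

    def test_fermi_resonance_flagged(self):
        # omega_i + omega_j ~ omega_k: the phi_ijk term must be excluded
        field = AnharmonicField(
            omegas=[700.0, 900.0, 1590.0], cubic={(0, 1, 2): 25.0}
        )
        with pytest.warns(UserWarning, match="Fermi"):
            x = offdiagonal_x(field, 0, 1)
        assert x == 0.0


class TestAgainstVariationalOracle:
    def test_three_mode_fundamentals(self):
        """VPT2 fundamentals agree with a 3-mode product-basis
        diagonalization within 5% of the anharmonic shift for weak
        anharmonicity (all |phi| <= 0.02 min(omega))."""
        field = AnharmonicField(
            omegas=[1000.0, 1310.0, 1660.0],
            cubic={(0, 0, 1): 12.0, (0, 1, 2): 8.0, (1, 1, 2): -10.0},
            quartic={
                (0, 0, 0, 0): -12.0,
                (1, 1, 1, 1): -16.0,
                (2, 2, 2, 2): -20.0,
                (0, 0, 1, 1): -6.0,
                (1, 1, 2, 2): -8.0,
            },
        )
        x = x_matrix(field)
        nmax = 12
        levels = variational_levels(field, nmax=nmax)
        e0 = _state_energy(field, levels, (0, 0, 0), nmax)
        for i in range(3):
            quanta = tuple(1 if m == i else 0 for m in range(3))
            e1 = _state_energy(field, levels, quanta, nmax)
            shift_var = (e1 - e0) - field.omegas[i]
            shift_vpt2 = 2.0 * x.x[i, i] + 0.5 * sum(
                x.x[i, j] for j in range(3) if j != i
            )
            assert shift_vpt2 == pytest.approx(shift_var, rel=0.05)

    def test_x_matrix_symmetric_and_order_invariant(self):
        field = AnharmonicField(
            omegas=[1000.0, 1310.0, 1660.0],
            cubic={(0, 1, 2): 8.0, (0, 0, 1): 12.0},
            quartic={(0, 0, 1, 1): -6.0, (1, 1, 2, 2): -8.0},
        )
        x = x_matrix(field)
        assert np.allclose(x.x, x.x.T)
        # permute modes 0 and 2: constants follow, x follows
        perm = [2, 1, 0]
        field_p = AnharmonicField(
            omegas=[field.omegas[p] for p in perm],
            cubic={tuple(perm.index(i) for i in k): v for k, v in field.cubic.items()},
            quartic={tuple(perm.index(i) for i in k): v for k, v in field.quartic.items()},
        )
        x_p = x_matrix(field_p)
        assert np.allclose(x_p.x, x.x[np.ix_(perm, perm)], atol=1e-12)


class TestShiftedFrequencies:
    def test_harmonic_identity(self):
        field = AnharmonicField(omegas=[1600.0, 1400.0])
        x = x_matrix(field)
        pairs = shifted_frequencies(field, x, scale=1.0)
        for (w01, w12), w in zip(pairs, field.omegas):
            assert w01 == pytest.approx(w)
            assert w12 == pytest.approx(w)

    def test_inverse_map_of_observed_split(self):
        """The observed pair (1604.1, 1598.5) implies 2 x_ii = -5.6, i.e.
        x_ii = -2.8 cm^-1."""
        w01, w12 = 1604.1, 1598.5
        x_ii = (w12 - w01) / 2.0
        assert x_ii == pytest.approx(-2.8, abs=1e-12)

    def test_scale_factor_application(self):
        assert 0.97 * 1654.6 == pytest.approx(1605.0, abs=0.05)
        field = AnharmonicField(omegas=[1654.6])
        pairs = shifted_frequencies(field, x_matrix(field), scale=0.97)
        assert pairs[0][0] == pytest.approx(1604.962, abs=1e-9)
        with pytest.raises(ValueError):
            shifted_frequencies(field, x_matrix(field), scale=0.5)

    def test_carbonyl_pair_fixture_split(self):
        """The carbonyl-pair force field reproduces the 5.6 cm^-1
        anharmonic red-shift of the dominant band."""
        field = gen_anharmonic_fixture("carbonyl_pair")
        x = x_matrix(field)
        pairs = shifted_frequencies(field, x, scale=0.97)
        assert pairs[0][0] - pairs[0][1] == pytest.approx(5.6, abs=1e-9)
        assert pairs[0][0] == pytest.approx(1604.1, abs=1e-6)


class TestForceFieldValidation:
    def test_symmetrized_storage(self):
        field = AnharmonicField(omegas=[1000.0, 1200.0], cubic={(1, 0, 0): 5.0})
        assert field.phi3(0, 0, 1) == 5.0
        assert field.phi3(0, 1, 0) == 5.0

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            AnharmonicField(omegas=[-100.0])
        with pytest.raises(ValueError):
            AnharmonicField(omegas=[1000.0], cubic={(0, 0, 3): 1.0})
        with pytest.raises(ValueError):
            offdiagonal_x(AnharmonicField(omegas=[1000.0]), 0, 0)
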
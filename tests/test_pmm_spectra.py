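"""Perturbed Matrix Method engine, broadening, and shift arithmetic."""

import numpy as np
import pytest

from cybospec.core import CybospecError, GeometryError
from cybospec.pmm import (
    QMReference,
    build_perturbed_hamiltonian,
    diagonalize_pmm,
    read_qm_reference,
    site_potentials,
    write_qm_reference,
)
from cybospec.spectra import (
    Spectrum,
    average_spectra,
    broaden,
    compose_total,
    shift_vs_reference,
    weighted_average,
)
from cybospec.synthetic import gen_qm_reference
from cybospec.units import (
    BOHR_PER_ANGSTROM,
    OSCILLATOR_TO_ABSORPTIVITY,
    nm_to_wavenumber,
)


class TestSitePotentials:
    def test_unit_charge_at_one_bohr(self):
        d = 1.0 / BOHR_PER_ANGSTROM  # 1 bohr expressed in Å
        V = site_potentials(np.array([[d, 0, 0]]), [1.0], np.zeros((1, 3)))
        assert V[0] == pytest.approx(1.0, rel=1e-12)

    def test_opposite_charges_cancel(self):
        pos = np.array([[2.0, 0, 0], [-2.0, 0, 0]])
        V = site_potentials(pos, [0.7, -0.7], np.zeros((1, 3)))
        assert V[0] == pytest.approx(0.0, abs=1e-15)

    def test_matches_double_loop_sum(self):
        rng = np.random.default_rng(9)
        charges = rng.uniform(-1, 1, 20)
        pos_s = rng.uniform(2, 8, (20, 3))
        pos_a = rng.uniform(-1, 1, (5, 3))
        V = site_potentials(pos_s, charges, pos_a)
        expected = np.zeros(5)
        for a in range(5):
            for s in range(20):
                r = np.linalg.norm(pos_a[a] - pos_s[s]) * BOHR_PER_ANGSTROM
                expected[a] += charges[s] / r
        np.testing.assert_allclose(V, expected, rtol=1e-12)

    def test_near_coincident_site_raises(self):
        with pytest.raises(GeometryError, match="site"):
            site_potentials(np.array([[0.05, 0, 0]]), [1.0], np.zeros((1, 3)))


def two_state_reference(e_gap=0.1, coupling=0.02, n_atoms=1):
    q = np.zeros((2, 2, n_atoms))
    q[0, 1, 0] = q[1, 0, 0] = coupling
    q[0, 0, 0] = q[1, 1, 0] = 0.0
    mu = np.zeros((2, 2, 3))
    mu[0, 1] = mu[1, 0] = [1.0, 0.0, 0.0]
    return QMReference(
        energies=np.array([0.0, e_gap]),
        transition_charges=q,
        transition_dipoles=mu,
        reference_potentials=np.zeros(n_atoms),
    )


class TestPerturbedHamiltonian:
    def test_zero_perturbation_is_diagonal(self):
        ref = gen_qm_reference(6, 4, 0.05, seed=1)
        H = build_perturbed_hamiltonian(ref, ref.reference_potentials)
        np.testing.assert_allclose(H, np.diag(ref.energies), atol=1e-15)

    def test_two_state_closed_form(self):
        ref = two_state_reference(e_gap=0.1, coupling=0.02)
        dv = 0.3
        H = build_perturbed_hamiltonian(ref, np.array([dv]))
        res = diagonalize_pmm(H, ref)
        mean = 0.5 * (H[0, 0] + H[1, 1])
        half_gap = 0.5 * (H[1, 1] - H[0, 0])
        c = H[0, 1]
        e_minus = mean - np.sqrt(half_gap**2 + c**2)
        e_plus = mean + np.sqrt(half_gap**2 + c**2)
        np.testing.assert_allclose(res.eigenvalues, [e_minus, e_plus], rtol=1e-12)

    def test_off_diagonal_scales_linearly(self):
        ref = gen_qm_reference(5, 3, 0.05, seed=2)
        dv = np.array([0.1, -0.2, 0.05])
        H1 = build_perturbed_hamiltonian(ref, ref.reference_potentials + dv)
        H3 = build_perturbed_hamiltonian(ref, ref.reference_potentials + 3 * dv)
        off1 = H1 - np.diag(np.diag(H1))
        off3 = H3 - np.diag(np.diag(H3))
        np.testing.assert_allclose(off3, 3 * off1, rtol=1e-10, atol=1e-14)

    def test_dimension_mismatch_raises(self):
        ref = gen_qm_reference(4, 3, 0.05, seed=3)
        with pytest.raises(CybospecError):
            build_perturbed_hamiltonian(ref, np.zeros(5))


class TestDiagonalize:
    def test_zero_perturbation_identity(self):
        ref = gen_qm_reference(11, 6, 0.05, seed=4)
        H = build_perturbed_hamiltonian(ref, ref.reference_potentials)
        res = diagonalize_pmm(H, ref)
        np.testing.assert_allclose(
            res.excitation_energies, ref.energies[1:] - ref.energies[0], atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_weyl_bound_and_trace(self, seed):
        ref = gen_qm_reference(8, 5, 0.05, seed=seed)
        rng = np.random.default_rng(1000 + seed)
        V = ref.reference_potentials + rng.normal(0, 0.1, ref.n_atoms)
        H = build_perturbed_hamiltonian(ref, V)
        res = diagonalize_pmm(H, ref)
        dH = H - np.diag(ref.energies)
        bound = np.linalg.norm(dH, 2)
        assert np.all(np.abs(res.eigenvalues - ref.energies) <= bound + 1e-12)
        assert np.trace(H) == pytest.approx(res.eigenvalues.sum(), rel=1e-10)
        G = res.eigenvectors.T @ res.eigenvectors
        np.testing.assert_allclose(G, np.eye(ref.n_states), atol=1e-9)

    def test_oscillator_strengths_nonnegative(self):
        ref = gen_qm_reference(7, 4, 0.08, seed=6)
        V = ref.reference_potentials + 0.2
        res = diagonalize_pmm(build_perturbed_hamiltonian(ref, V), ref)
        assert np.all(res.oscillator_strengths >= 0)

    def test_nonsymmetric_input_rejected(self):
        ref = gen_qm_reference(3, 2, 0.05, seed=7)
        H = np.array([[0.0, 1.0, 0], [0, 1, 0], [0, 0, 2.0]])
        with pytest.raises(CybospecError):
            diagonalize_pmm(H, ref)


class TestQMReferenceIO:
    def test_round_trip(self, tmp_path):
        ref = gen_qm_reference(5, 4, 0.05, seed=8)
        path = tmp_path / "qmref.dat"
        write_qm_reference(ref, path)
        back = read_qm_reference(path)
        np.testing.assert_allclose(back.energies, ref.energies, atol=1e-12)
        np.testing.assert_allclose(back.transition_charges, ref.transition_charges,
                                   atol=1e-12)
        np.testing.assert_allclose(back.transition_dipoles, ref.transition_dipoles,
                                   atol=1e-12)
        np.testing.assert_allclose(back.reference_potentials,
                                   ref.reference_potentials, atol=1e-12)

    def test_invariants_enforced(self):
        with pytest.raises(CybospecError):
            QMReference(
                energies=np.array([0.0, 0.1]),
                transition_charges=np.array([[[0.5], [0.1]], [[0.2], [0.5]]]),
                transition_dipoles=np.zeros((2, 2, 3)),
                reference_potentials=np.zeros(1),
            )  # asymmetric in (i, j)


class TestBroaden:
    def test_single_transition_centered(self):
        nu = nm_to_wavenumber(464.0)
        spec = broaden([(float(nu), 0.01)], hwhm=600.0)
        assert spec.lambda_max == pytest.approx(464.0, abs=0.1)

    def test_two_far_transitions_equal_heights(self):
        s = broaden(
            [(float(nm_to_wavenumber(300.0)), 0.01),
             (float(nm_to_wavenumber(700.0)), 0.01)],
            hwhm=600.0,
        )
        nu = nm_to_wavenumber(s.grid)
        i1 = np.argmin(np.abs(nu - nm_to_wavenumber(300.0)))
        i2 = np.argmin(np.abs(nu - nm_to_wavenumber(700.0)))
        assert s.epsilon[i1] == pytest.approx(s.epsilon[i2], rel=1e-9)

    def test_band_area_recovers_oscillator_strength(self):
        f = 0.0123
        nu0 = float(nm_to_wavenumber(464.0))
        spec = broaden([(nu0, f)], hwhm=600.0)
        nu = nm_to_wavenumber(spec.grid)[::-1]
        eps = spec.epsilon[::-1]
        area = np.trapezoid(eps, nu)
        assert area == pytest.approx(f / OSCILLATOR_TO_ABSORPTIVITY, rel=1e-3)

    def test_empty_transitions_warn_zero(self):
        with pytest.warns(UserWarning):
            spec = broaden([], hwhm=600.0)
        assert np.all(spec.epsilon == 0)

    def test_lambda_max_converges_with_grid(self):
        nu = float(nm_to_wavenumber(464.05))
        coarse = broaden([(nu, 0.01)], grid=np.arange(400, 500, 1.0))
        fine = broaden([(nu, 0.01)], grid=np.arange(400, 500, 0.01))
        assert abs(fine.lambda_max - 464.05) < abs(coarse.lambda_max - 464.05) + 1e-12
        assert fine.lambda_max == pytest.approx(464.05, abs=0.01)


class TestAverageSpectra:
    def make(self, center_nm, hwhm=600.0):
        return broaden([(float(nm_to_wavenumber(center_nm)), 0.01)], hwhm=hwhm)

    def test_idempotent_on_identical(self):
        s = self.make(450.0)
        out = average_spectra([s, s], [0.3, 0.7])
        np.testing.assert_allclose(out.epsilon, s.epsilon, rtol=1e-12, atol=1e-300)

    def test_degenerate_weights_select(self):
        s1, s2 = self.make(430.0), self.make(470.0)
        out = average_spectra([s1, s2], [1.0, 0.0])
        np.testing.assert_allclose(out.epsilon, s1.epsilon)

    def test_pointwise_mean(self):
        s1, s2 = self.make(430.0), self.make(470.0)
        out = average_spectra([s1, s2], [0.5, 0.5])
        np.testing.assert_allclose(out.epsilon,
                                   0.5 * s1.epsilon + 0.5 * s2.epsilon, rtol=1e-12)

    def test_grid_mismatch_raises(self):
        s1 = self.make(430.0)
        s2 = Spectrum(grid=np.arange(300, 400, 0.5), epsilon=np.zeros(200), hwhm=600)
        with pytest.raises(CybospecError):
            average_spectra([s1, s2], [0.5, 0.5])


class TestShiftArithmetic:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            ((432.8, 436.9, 441.2, 444.3, 436.4), 436.4),
            ((462.5, 448.3, 455.3, 466.6, 458.1), 464.0),
            ((437.7, 418.8, 425.4, 439.1, 431.6), 438.6),
            ((471.2, 449.8, 466.6, 478.4, 469.3), 463.5),
        ],
    )
    def test_composition_rule(self, rows, expected):
        assert compose_total(*rows) == pytest.approx(expected, abs=0.05)

    def test_equal_arguments_cancel(self):
        assert compose_total(450.0, 450.0, 450.0, 450.0, 450.0) == 450.0

    @pytest.mark.parametrize(
        "values,weights,expected",
        [
            ((494.9, 463.5, 490.7), (0.49, 0.36, 0.15), 483.0),
            ((464.0, 463.2), (0.56, 0.44), 463.6),
        ],
    )
    def test_weighted_average(self, values, weights, expected):
        assert weighted_average(values, weights) == pytest.approx(expected, abs=0.05)

    def test_weighted_average_of_constant(self):
        assert weighted_average([450.0, 450.0], [0.3, 0.7]) == pytest.approx(450.0)

    def test_weights_must_normalise(self):
        with pytest.raises(CybospecError):
            weighted_average([1.0, 2.0], [0.5, 0.6])

    def test_shift_vs_reference(self):
        shifts = shift_vs_reference(
            {"DMF": 483.0, "CH3OH": 463.648}, "DMF"
        )
        assert shifts["DMF"] == 0.0
        assert shifts["CH3OH"] == pytest.approx(-19.4, abs=0.05)
        with pytest.raises(CybospecError):
            shift_vs_reference({"A": 1.0}, "B")
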
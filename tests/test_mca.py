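import numpy as np
import pytest

from conftest import classification_from_model, internal_E_and_N
from thermomca.errors import SingularSystemError, ValidationError
from thermomca.mca import (
    FCCResult,
    flux_control_coefficients,
    link_matrix,
    monte_carlo_fcc,
    theorem_checks,
)
from thermomca.model_core import decompose
from thermomca.synthetic_data import (
    build_default_kinetic_model,
    simulate_steady_state,
    true_fcc_finite_difference,
)


def chain_setup(eps1=-1.0, eps2=1.0):
    """Two-enzyme chain over one balanced metabolite X."""
    N = np.array([[1.0, -1.0]])
    E = np.array([[eps1], [eps2]])
    v0 = np.array([1.0, 1.0])
    X0 = np.array([1.0])
    return N, E, v0, X0


class TestLinkMatrix:
    def test_identity_without_conservation(self):
        N = np.array([[1.0, -1.0], [0.0, 1.0]])
        dec = decompose(N)
        L0 = link_matrix(N, dec, np.array([1.0, 2.0]))
        assert np.allclose(L0, np.eye(2))

    def test_moiety_pair_with_equal_concentrations(self):
        # A + B conserved (2x1 stoichiometry), equal reference levels
        N = np.array([[-1.0], [1.0]])
        dec = decompose(N)
        L0 = link_matrix(N, dec, np.array([1.0, 1.0]))
        assert np.allclose(L0, [[1.0], [-1.0]])

    def test_pseudoinverse_reconstruction_random(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            N = rng.integers(-2, 3, size=(rng.integers(2, 7),
                                          rng.integers(1, 6))).astype(float)
            if not np.any(N):
                continue
            dec = decompose(N)
            assert np.abs(N @ np.linalg.pinv(dec.NR) @ dec.NR - N).max() < 1e-9

    def test_zero_concentration_rejected(self):
        N = np.array([[1.0, -1.0]])
        dec = decompose(N)
        with pytest.raises(ValidationError):
            link_matrix(N, dec, np.array([0.0]))


class TestPointFCC:
    def test_symmetric_chain_closed_form(self):
        N, E, v0, X0 = chain_setup(-1.0, 1.0)
        res = flux_control_coefficients(E, N, v0, X0)
        assert res.C == pytest.approx(0.5 * np.ones((2, 2)))

    def test_asymmetric_chain_closed_form(self):
        # C1 = eps2 / (eps2 - eps1) = 1/3 for eps = (-2, +1)
        N, E, v0, X0 = chain_setup(-2.0, 1.0)
        res = flux_control_coefficients(E, N, v0, X0)
        assert res.C[:, 0] == pytest.approx([1 / 3, 2 / 3])

    def test_as_printed_variant_lacks_summation(self):
        """The concentration-response part E*K alone does not satisfy the
        summation theorem; the identity term completes it."""
        N, E, v0, X0 = chain_setup(-1.0, 1.0)
        res = flux_control_coefficients(E, N, v0, X0)
        assert res.C_response.sum(axis=0) != pytest.approx([1.0, 1.0])
        assert res.C.sum(axis=0) == pytest.approx([1.0, 1.0])

    def test_singular_inner_matrix_reports_condition(self):
        N, E, v0, X0 = chain_setup(1.0, 1.0)  # both rates rise with X
        with pytest.raises(SingularSystemError, match="condition"):
            flux_control_coefficients(E, N, v0, X0)

    def test_invariance_under_common_rescaling(self, trp_toy):
        E, N = internal_E_and_N(trp_toy)
        ref = simulate_steady_state(trp_toy)
        base = flux_control_coefficients(E, N, ref.v0, ref.X0)
        v_scaled = flux_control_coefficients(E, N, 3.0 * ref.v0, ref.X0)
        x_scaled = flux_control_coefficients(E, N, ref.v0, 2.0 * ref.X0)
        assert np.allclose(base.C, v_scaled.C)
        assert np.allclose(base.C, x_scaled.C)


class TestTheorems:
    def test_residuals_small_for_valid_point(self, trp_toy):
        E, N = internal_E_and_N(trp_toy)
        ref = simulate_steady_state(trp_toy)
        res = flux_control_coefficients(E, N, ref.v0, ref.X0)
        assert res.diagnostics["summation_residual"] < 1e-6
        assert res.diagnostics["connectivity_residual"] < 1e-6

    def test_chain_connectivity_exact(self):
        N, E, v0, X0 = chain_setup(-1.0, 1.0)
        res = flux_control_coefficients(E, N, v0, X0)
        # C1*eps1 + C2*eps2 = 0
        assert res.C.T @ E == pytest.approx(np.zeros((2, 1)))

    def test_corrupted_elasticity_keeps_summation_but_breaks_oracle(self, trp_toy):
        """A 10% error in one elasticity leaves the summation theorem intact
        (it holds for any E at a steady v0) while the oracle mismatch grows —
        the theorem alone cannot certify correctness."""
        E, N = internal_E_and_N(trp_toy)
        ref = simulate_steady_state(trp_toy)
        truth = true_fcc_finite_difference(trp_toy)
        good = flux_control_coefficients(E, N, ref.v0, ref.X0)
        good_err = np.abs(good.C - truth).max()
        E_bad = E.copy()
        j = trp_toy.network.rxn_idx("ans")
        i = int(np.flatnonzero(E_bad[j])[0])
        E_bad[j, i] *= 1.1
        bad = flux_control_coefficients(E_bad, N, ref.v0, ref.X0)
        assert bad.diagnostics["summation_residual"] < 1e-6
        assert np.abs(bad.C - truth).max() > 10 * max(good_err, 1e-6)


class TestOracleEquivalence:
    @pytest.mark.parametrize("preset", ["linear2", "linear3", "branch",
                                        "moiety", "trp_toy"])
    def test_eq4_matches_finite_difference_with_true_elasticities(self, preset):
        model = build_default_kinetic_model(preset, seed=1)
        E, N = internal_E_and_N(model)
        ref = simulate_steady_state(model)
        v0 = ref.v0
        X0 = ref.X0[model.balanced_idx]
        res = flux_control_coefficients(E, N, v0, X0)
        truth = true_fcc_finite_difference(model)
        assert np.abs(res.C - truth).max() < 1e-2


class TestMonteCarlo:
    def test_zero_width_ranges_reproduce_point_estimate(self, trp_toy):
        E, N = internal_E_and_N(trp_toy)
        ref = simulate_steady_state(trp_toy)
        X0 = ref.X0[trp_toy.balanced_idx]
        point = flux_control_coefficients(E, N, ref.v0, X0)

        def builder(v0, x0, drg):
            return E

        flux_ranges = np.column_stack([ref.v0, ref.v0])
        conc_ranges = np.column_stack([X0, X0])
        res = monte_carlo_fcc(builder, N, flux_ranges, conc_ranges, {},
                              n_cycles=20, seed=5)
        assert res.n_cycles == 20
        assert res.n_dropped == 0
        assert np.allclose(res.summary["sd"], 0.0)
        assert np.allclose(res.C, point.C)

    def test_seed_determinism(self, trp_toy):
        E, N = internal_E_and_N(trp_toy)
        ref = simulate_steady_state(trp_toy)
        X0 = ref.X0[trp_toy.balanced_idx]
        flux_ranges = np.column_stack([ref.v0 * 0.95, ref.v0 * 1.05])
        conc_ranges = np.column_stack([X0 * 0.9, X0 * 1.1])

        def builder(v0, x0, drg):
            return E

        a = monte_carlo_fcc(builder, N, flux_ranges, conc_ranges, {},
                            n_cycles=50, seed=11)
        b = monte_carlo_fcc(builder, N, flux_ranges, conc_ranges, {},
                            n_cycles=50, seed=11)
        assert np.array_equal(a.C, b.C)
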
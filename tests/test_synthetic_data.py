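import numpy as np
import pytest

from thermomca.errors import SteadyStateError, ValidationError
from thermomca.synthetic_data import (
    PerturbationDesign,
    build_default_kinetic_model,
    generate_perturbation_dataset,
    simulate_steady_state,
    true_fcc_finite_difference,
    write_dataset,
)

PRESET_NAMES = ["linear2", "linear3", "branch", "moiety", "trp_toy"]


class TestPresets:
    def test_unknown_preset(self):
        with pytest.raises(ValidationError, match="unknown preset"):
            build_default_kinetic_model("nope")

    def test_linear2_textbook_elasticities(self):
        m = build_default_kinetic_model("linear2")
        net = m.network
        iX = net.met_idx("X")
        assert m.elasticities[net.rxn_idx("r1"), iX] == -1.0
        assert m.elasticities[net.rxn_idx("r2"), iX] == +1.0

    @pytest.mark.parametrize("preset", PRESET_NAMES + ["ecoli_trp"])
    def test_reference_is_steady(self, preset):
        m = build_default_kinetic_model(preset, seed=1)
        st = simulate_steady_state(m)
        assert m.steady_state_residual(st) < 1e-8
        assert np.all(st.X0 > 0)

    def test_seed_determinism(self):
        a = build_default_kinetic_model("trp_toy", seed=1)
        b = build_default_kinetic_model("trp_toy", seed=1)
        assert np.array_equal(a.elasticities, b.elasticities)
        assert np.array_equal(a.v_ref, b.v_ref)

    def test_reference_thermodynamics_match_targets(self, trp_toy):
        from thermomca.synthetic_data import TOY_DRG_TARGETS

        for rid, mag in TOY_DRG_TARGETS.items():
            assert trp_toy.drg_ref[rid] == pytest.approx(-mag)


class TestSimulate:
    def test_identity_at_unit_multipliers(self, trp_toy):
        st = simulate_steady_state(trp_toy)
        assert np.allclose(st.v0, trp_toy.v_ref, atol=1e-10)
        assert np.allclose(st.X0, trp_toy.x_ref)

    def test_linear2_supply_closed_form(self):
        """Scaling the boundary substrate by s shifts the 1-metabolite
        lin-log balance to y = ln(s)/2, so v = v*(1 + ln(s)/2)."""
        m = build_default_kinetic_model("linear2")
        for s in (0.5, 2.0, 3.0):
            st = simulate_steady_state(m, supply_multiplier=s)
            expected = 1.0 + np.log(s) / 2
            assert st.v0 == pytest.approx([expected, expected], abs=1e-10)

    def test_fixed_rate_supply_scales_fluxes_exactly(self, trp_toy):
        """Doubling every feed doubles the supply fluxes exactly (feeds are
        rate-limited), and the network re-balances."""
        st = simulate_steady_state(trp_toy, supply_multiplier=2.0)
        for rid, base in trp_toy.supply_rates.items():
            assert st.flux(rid) == pytest.approx(2 * base)
        assert trp_toy.steady_state_residual(st) < 1e-8

    def test_blocked_supplied_pool_has_no_steady_state(self, trp_toy):
        with pytest.raises(SteadyStateError):
            simulate_steady_state(
                trp_toy,
                enzyme_levels={"glyc_low": 0.0, "ppp": 0.0, "igps_trps": 0.0},
            )

    def test_negative_enzyme_level_rejected(self, trp_toy):
        with pytest.raises(ValidationError):
            simulate_steady_state(trp_toy, enzyme_levels={"ans": -1.0})


class TestDataset:
    def test_default_design_yields_13_states(self, toy_dataset_noisy):
        assert len(toy_dataset_noisy.states) == 13
        assert sum(s.is_reference for s in toy_dataset_noisy.states) == 1
        assert PerturbationDesign().n_states == 13

    def test_zero_noise_equals_noiseless_simulation(self, trp_toy, toy_dataset_clean):
        ref = simulate_steady_state(trp_toy)
        assert np.allclose(toy_dataset_clean.reference.v0, ref.v0)
        for st in toy_dataset_clean.states:
            assert trp_toy.steady_state_residual(st) < 1e-8

    def test_bit_reproducible_for_fixed_seed(self, trp_toy):
        d1 = generate_perturbation_dataset(trp_toy, noise_cv=0.1, seed=7)
        d2 = generate_perturbation_dataset(trp_toy, noise_cv=0.1, seed=7)
        for a, b in zip(d1.states, d2.states):
            assert np.array_equal(a.v0, b.v0)
            assert np.array_equal(a.X0, b.X0)

    def test_noise_keeps_concentrations_positive(self, toy_dataset_noisy):
        for st in toy_dataset_noisy.states:
            assert np.all(st.X0 > 0)

    def test_full_network_metabolome_panel_has_45_entries(self, tmp_path):
        import pandas as pd

        model = build_default_kinetic_model("ecoli_trp", seed=1)
        ds = generate_perturbation_dataset(model, noise_cv=0.1, seed=1)
        paths = write_dataset(ds, tmp_path)
        metab = pd.read_csv(paths["metabolome"], sep="\t", index_col=0)
        assert metab.shape == (13, 45)
        rates = pd.read_csv(paths["rates"], sep="\t", index_col=0)
        assert rates.shape[0] == 13


class TestFiniteDifferenceOracle:
    def test_linear2_closed_form(self):
        m = build_default_kinetic_model("linear2")
        C = true_fcc_finite_difference(m)
        assert C == pytest.approx(0.5 * np.ones((2, 2)), abs=1e-4)

    @pytest.mark.parametrize("preset", PRESET_NAMES)
    def test_summation_theorem(self, preset):
        m = build_default_kinetic_model(preset, seed=1)
        C = true_fcc_finite_difference(m, delta=0.01)
        per_flux = C.sum(axis=0)
        assert np.abs(per_flux - 1.0).max() < 1e-3

    def test_richardson_convergence(self, trp_toy):
        C1 = true_fcc_finite_difference(trp_toy, delta=0.01)
        C2 = true_fcc_finite_difference(trp_toy, delta=0.001)
        assert np.abs(C1 - C2).max() < 1e-2

    def test_delta_bounds(self, trp_toy):
        with pytest.raises(ValidationError):
            true_fcc_finite_difference(trp_toy, delta=0.2)
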
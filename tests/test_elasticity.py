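import numpy as np
import pytest

from conftest import classification_from_model
from thermomca.constants import R, RT_DEFAULT, T_DEFAULT
from thermomca.elasticity import (
    EffectorMap,
    assemble_elasticity_matrix,
    linlog_elasticities,
    linlog_elasticity_matrix,
    thermokinetic_elasticity,
)
from thermomca.errors import ValidationError
from thermomca.synthetic_data import (
    TOY_EFFECTORS,
    build_default_kinetic_model,
    generate_perturbation_dataset,
)


class TestThermokinetic:
    def test_cancellation_at_minus_rt(self):
        assert thermokinetic_elasticity(-1.0, -RT_DEFAULT) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # eps = -n R T / A = RT/5 = 0.51575 for A = 5 kJ/mol at 310.15 K
        assert thermokinetic_elasticity(-1.0, -5.0) == pytest.approx(
            0.51575, abs=5e-5)

    def test_substrate_product_antisymmetry(self):
        assert thermokinetic_elasticity(+1.0, -5.0) == pytest.approx(
            -0.51575, abs=5e-5)

    def test_undefined_at_equilibrium(self):
        with pytest.raises(ValidationError, match="equilibrium"):
            thermokinetic_elasticity(-1.0, 0.0)

    @pytest.mark.parametrize("n,drg,k", [(-1, -4.0, 2.0), (2, -7.0, 0.5)])
    def test_scaling_linear_in_n_inverse_in_drg(self, n, drg, k):
        base = thermokinetic_elasticity(n, drg)
        assert thermokinetic_elasticity(k * n, drg) == pytest.approx(k * base)
        assert thermokinetic_elasticity(n, k * drg) == pytest.approx(base / k)

    def test_orientation_invariance(self):
        """Flipping both the stoichiometric sign and the reaction energy
        (writing the reaction in its net direction) leaves eps unchanged."""
        assert thermokinetic_elasticity(-1, -5.0) == pytest.approx(
            thermokinetic_elasticity(+1, +5.0))

    def test_midpoint_perturbation_closed_form(self):
        """Perturbing deltarG' by +-10% rescales eps by A/(A -+ 0.1A)."""
        base = thermokinetic_elasticity(-1.0, -5.0)
        up = thermokinetic_elasticity(-1.0, -5.0 * 1.1)
        assert up == pytest.approx(base / 1.1)


class TestLinLogRegression:
    def test_exact_recovery_noise_free(self, trp_toy, toy_dataset_clean):
        net = trp_toy.network
        cls = classification_from_model(trp_toy)
        emap = EffectorMap(effectors=dict(TOY_EFFECTORS))
        E = linlog_elasticity_matrix(
            net, toy_dataset_clean.states, toy_dataset_clean.reference,
            effectors=emap, classification=cls,
            skip_reactions=set(trp_toy.supply_rates),
            drg_values=dict(trp_toy.drg_ref),
        )
        err = np.abs(E.values - trp_toy.elasticities).max()
        assert err < 1e-8

    def test_constant_metabolite_flagged_unidentifiable(self, trp_toy,
                                                        toy_dataset_clean):
        states = toy_dataset_clean.states
        ref = toy_dataset_clean.reference
        frozen = []
        for s in states:
            s2 = type(s)(
                id=s.id, reaction_ids=s.reaction_ids,
                metabolite_ids=s.metabolite_ids,
                v0=s.v0, X0=np.where(
                    [m == "trp" for m in s.metabolite_ids], ref.X0, s.X0),
                e0=s.e0, is_reference=s.is_reference,
            )
            frozen.append(s2)
        fit = linlog_elasticities(frozen, ref, "trp_export", ["trp"])
        assert fit.unidentifiable == ["trp"]
        assert np.isnan(fit.elasticities["trp"])

    def test_zero_reference_flux_rejected(self, toy_dataset_clean):
        ref = toy_dataset_clean.reference
        broken = type(ref)(
            id=ref.id, reaction_ids=ref.reaction_ids,
            metabolite_ids=ref.metabolite_ids,
            v0=np.zeros_like(ref.v0), X0=ref.X0, e0=ref.e0,
            is_reference=True,
        )
        with pytest.raises(ValidationError, match="zero"):
            linlog_elasticities(
                toy_dataset_clean.states, broken, "ans", ["chor"])

    def test_noisy_recovery_is_unbiased_enough(self):
        """Median elasticity error over noisy replicate datasets stays small
        for the two-unknown middle reaction of a three-step chain."""
        model = build_default_kinetic_model("linear3")
        net = model.network
        errs = []
        for seed in range(30):
            ds = generate_perturbation_dataset(model, noise_cv=0.1, seed=seed)
            fit = linlog_elasticities(ds.states, ds.reference, "r2",
                                      ["X1", "X2"])
            errs.append(abs(fit.elasticities["X1"] - 0.8))
            errs.append(abs(fit.elasticities["X2"] + 0.5))
        assert np.median(errs) < 0.3


class TestAssembly:
    def test_all_near_matrix_matches_formula(self):
        model = build_default_kinetic_model("linear2")
        net = model.network
        drg_ranges = {"r1": (-6.0, -4.0), "r2": (-6.0, -4.0)}
        ds = generate_perturbation_dataset(model, noise_cv=0.0, seed=1)
        E = assemble_elasticity_matrix(net, drg_ranges, ds.states,
                                       ds.reference)
        for rid in ("r1", "r2"):
            j = net.rxn_idx(rid)
            for mid, n in net.reaction(rid).stoich.items():
                expected = n * R * T_DEFAULT / -5.0
                assert E.values[j, net.met_idx(mid)] == pytest.approx(expected)
                assert E.provenance[j, net.met_idx(mid)] == "thermokinetic"

    def test_provenance_recorded_for_toy(self, trp_toy, toy_dataset_noisy):
        drg_ranges = {rid: (g - 1, g + 1) for rid, g in trp_toy.drg_ref.items()}
        emap = EffectorMap(effectors=dict(TOY_EFFECTORS))
        E = assemble_elasticity_matrix(
            trp_toy.network, drg_ranges, toy_dataset_noisy.states,
            toy_dataset_noisy.reference, effectors=emap,
            skip_reactions=set(trp_toy.supply_rates),
        )
        nz = E.values != 0
        assert nz.any()
        assert set(E.provenance[nz]) <= {"thermokinetic", "linlog"}
        assert (E.provenance[~nz] == "zero").all()
        j = trp_toy.network.rxn_idx("igps_trps")
        i = trp_toy.network.met_idx("anth")
        assert E.values[j, i] < 0  # inhibiting effector recovered as negative


class TestEffectorMap:
    def test_duplicate_effector_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            EffectorMap(effectors={"r": [("a", "inhibitor"), ("a", "activator")]})

    def test_unknown_role_rejected(self):
        with pytest.raises(ValidationError, match="role"):
            EffectorMap(effectors={"r": [("a", "blocker")]})

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "eff.yaml"
        path.write_text(
            "effectors:\n  igps:\n    - {metabolite: anth, role: inhibitor}\n")
        emap = EffectorMap.from_yaml(path)
        assert emap.for_reaction("igps") == [("anth", "inhibitor")]
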
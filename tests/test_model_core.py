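import json

import numpy as np
import pytest

from thermomca.errors import SchemaError, ValidationError
from thermomca.model_core import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    decompose,
    load_network,
    stoichiometric_matrix,
    write_network,
)

PATHWAYS = {"GLYC&GLYK", "TCA", "PPP", "L-ser", "CHOR", "L-phe/L-tyr", "L-trp"}


def toy_net(rxns, mets, require_biomass=False):
    net = MetabolicNetwork(
        metabolites=[Metabolite(id=m, conc_ref=1.0) for m in mets],
        reactions=[
            Reaction(id=rid, stoich=st, pathway_tag=tag)
            for rid, st, tag in rxns
        ],
    )
    net.validate(require_biomass=require_biomass)
    return net


class TestDefaultNetwork:
    def test_pinned_dimensions(self, default_net):
        assert len(default_net.model_reactions) == 50
        assert len(default_net.metabolites) == 57
        assert sum(m.measured for m in default_net.metabolites) == 45

    def test_pathway_coverage(self, default_net):
        tags = {r.pathway_tag for r in default_net.reactions}
        assert PATHWAYS <= tags
        assert sum(r.pathway_tag == "biomass" for r in default_net.reactions) == 1

    def test_stoichiometric_matrix_shape(self, default_net):
        N = stoichiometric_matrix(default_net)
        assert N.shape == (57, len(default_net.reactions))

    def test_thermodynamic_annotation_consistency(self, default_net):
        """Reaction energies at the curated reference concentrations oppose
        every flux direction the network was curated around (second law at
        the reference point)."""
        from thermomca.constants import RT_DEFAULT
        from thermomca.synthetic_data import build_default_kinetic_model

        model = build_default_kinetic_model("ecoli_trp", seed=1)
        N = stoichiometric_matrix(default_net)
        lnx = np.log(model.x_ref * 1e-3)
        for rid, drg_ref in model.drg_ref.items():
            j = default_net.rxn_idx(rid)
            drg0 = default_net.reaction_drg0(default_net.reactions[j])
            assert drg0 + RT_DEFAULT * (N[:, j] @ lnx) == pytest.approx(drg_ref)
            assert np.sign(drg_ref) == -np.sign(model.v_ref[j])


class TestModelIO:
    def test_round_trip_identity(self, default_net, tmp_path):
        path = tmp_path / "net.json"
        write_network(default_net, path)
        reloaded = load_network(path)
        assert reloaded.metabolite_ids == default_net.metabolite_ids
        assert reloaded.reaction_ids == default_net.reaction_ids
        assert np.allclose(
            stoichiometric_matrix(reloaded), stoichiometric_matrix(default_net)
        )
        path2 = tmp_path / "net2.json"
        write_network(reloaded, path2)
        assert json.loads(path.read_text()) == json.loads(path2.read_text())

    def test_dangling_metabolite_reference(self, tmp_path):
        doc = {
            "metabolites": [{"id": "a"}],
            "reactions": [{"id": "r", "stoich": {"xyz": 1.0},
                           "pathway_tag": "biomass"}],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match="xyz"):
            load_network(path)

    def test_schema_violation_names_field(self, tmp_path):
        doc = {
            "metabolites": [{"id": "a", "bogus_field": 1}],
            "reactions": [],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="bogus_field"):
            load_network(path)

    def test_missing_stoich_is_schema_error(self, tmp_path):
        doc = {"metabolites": [{"id": "a"}], "reactions": [{"id": "r"}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="stoich"):
            load_network(path)


class TestStoichiometricMatrix:
    def test_single_conversion_column(self):
        net = toy_net([("r", {"A": -1, "B": 1}, "GLYC&GLYK")], ["A", "B"])
        N = stoichiometric_matrix(net)
        assert N[:, 0].tolist() == [-1.0, 1.0]

    def test_balanced_chain_columns_sum_to_zero(self):
        net = toy_net(
            [("r1", {"A": -1, "B": 1}, "GLYC&GLYK"),
             ("r2", {"B": -1, "C": 1}, "GLYC&GLYK")],
            ["A", "B", "C"],
        )
        N = stoichiometric_matrix(net)
        assert np.allclose(N.sum(axis=0), 0.0)


class TestDecompose:
    def test_closed_two_species_system(self):
        N = np.array([[-1.0], [1.0]])
        dec = decompose(N)
        assert len(dec.independent_idx) == 1
        assert dec.independent_idx[0] == 0  # first row wins
        assert np.allclose(dec.conservation_basis @ dec.NR, N[[1]])

    def test_internal_chain_reduction(self):
        # S -> X -> P with only X balanced internally
        N_X = np.array([[1.0, -1.0]])
        dec = decompose(N_X)
        assert np.allclose(dec.NR, [[1.0, -1.0]])
        assert len(dec.dependent_idx) == 0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError, match="empty network"):
            decompose(np.zeros((3, 2)))

    def test_default_network_rank_preserved(self, default_net):
        N = stoichiometric_matrix(default_net)
        dec = decompose(N)
        assert np.linalg.matrix_rank(dec.NR) == np.linalg.matrix_rank(N)
        # adenylate, NAD(H) and NADP(H) pools are the conserved moieties
        assert len(dec.dependent_idx) == 3

    def test_random_networks_reconstruction(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m, n = rng.integers(2, 8), rng.integers(1, 6)
            N = rng.integers(-2, 3, size=(m, n)).astype(float)
            if not np.any(N):
                continue
            dec = decompose(N)
            if len(dec.dependent_idx):
                resid = np.abs(
                    dec.conservation_basis @ dec.NR - N[dec.dependent_idx]
                ).max()
                assert resid < 1e-9
            assert np.linalg.matrix_rank(N) == len(dec.independent_idx)
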
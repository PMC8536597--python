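import numpy as np
import pytest

from oracle_tfa import (
    brute_force_optimum,
    brute_force_variability,
    make_tfa_fixture_network,
)
from thermomca.constants import R, RT_DEFAULT
from thermomca.errors import InfeasibleError, ValidationError
from thermomca.model_core import MetabolicNetwork, Metabolite, Reaction
from thermomca.tfa import (
    build_tfa_problem,
    classify_equilibrium,
    sample_solutions,
    solve_tfa,
    variability,
    widen_point_measurements,
)


def two_species_net(drg_target=0.0, reversible=True, conc=(1.0, 1.0),
                    conc_width=1.0):
    """A <-> B plus supply/drain so that flux can circulate."""
    lnterm = RT_DEFAULT * (np.log(conc[1] * 1e-3) - np.log(conc[0] * 1e-3))
    mets = [
        Metabolite(id="A", conc_lb=conc[0] / conc_width,
                   conc_ub=conc[0] * conc_width, measured=True),
        Metabolite(id="B", conc_lb=conc[1] / conc_width,
                   conc_ub=conc[1] * conc_width, measured=True),
    ]
    rxns = [
        Reaction(id="upt", stoich={"A": 1}, flux_lb=0, flux_ub=2,
                 pathway_tag="exchange"),
        Reaction(id="r", stoich={"A": -1, "B": 1}, reversible=reversible,
                 flux_lb=-10 if reversible else 0, flux_ub=10,
                 pathway_tag="GLYC&GLYK", drg0=drg_target - lnterm),
        Reaction(id="drain", stoich={"B": -1}, flux_lb=0, flux_ub=10,
                 pathway_tag="biomass"),
    ]
    net = MetabolicNetwork(metabolites=mets, reactions=rxns)
    net.validate()
    return net


class TestBuild:
    def test_equilibrium_boundary_admits_both_directions(self):
        """deltarG'0 = 0 with both concentrations pinned at 1 mM puts the
        reaction exactly at equilibrium: deltarG' = 0, each direction
        admissible at the boundary (flux may still be zero)."""
        net = two_species_net(drg_target=0.0, conc_width=1.0 + 1e-12)
        prob = build_tfa_problem(net, measured_rates={"upt": (0.0, 2.0)})
        sol = variability(prob, gamma=1e-9)
        lo, hi = sol.drg_ranges["r"]
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(0.0, abs=1e-6)
        assert sol.flux_ranges["r"][1] > 1.0  # forward flux allowed at drg=0

    def test_uphill_reaction_with_bounded_correction_infeasible(self):
        """With deltarG' referenced to 1 M and concentrations confined to
        0.01-100 mM, the log-ratio term contributes at most RT ln(1e4) ~ 23.7
        kJ/mol downhill, so a +30 kJ/mol standard energy cannot be overcome
        and forcing forward flux is infeasible."""
        net = two_species_net(drg_target=0.0, conc_width=100.0)
        for m in net.metabolites:
            m.conc_lb, m.conc_ub = 0.01, 100.0
        j = net.rxn_idx("r")
        net.reactions[j].drg0 = 30.0  # vs at most RT ln(1e4) of ratio help
        assert RT_DEFAULT * np.log(1e4) < 30.0
        prob = build_tfa_problem(net, measured_rates={"upt": (0.5, 1.0)})
        with pytest.raises(InfeasibleError):
            solve_tfa(prob)

    def test_measured_tables_validate_ids(self, default_net):
        with pytest.raises(ValidationError, match="unknown"):
            build_tfa_problem(default_net, measured_rates={"nope": (0, 1)})

    def test_missing_drg_warns_flux_only(self, default_net):
        with pytest.warns(UserWarning, match="flux-only"):
            prob = build_tfa_problem(default_net)
        assert "oxphos" not in prob.thermo_rxns
        assert "gapd" in prob.thermo_rxns

    def test_widen_point_measurements(self):
        out = widen_point_measurements({"a": 2.0, "b": -1.0}, rel=0.1)
        assert out["a"] == (pytest.approx(1.8), pytest.approx(2.2))
        assert out["b"][0] == pytest.approx(-1.1)  # ordered for negatives


class TestSolve:
    def test_bound_limited_chain(self):
        net = two_species_net(drg_target=-5.0, reversible=False,
                              conc_width=2.0)
        prob = build_tfa_problem(net)
        opt = solve_tfa(prob)
        assert opt.optimum == pytest.approx(2.0, abs=1e-8)

    def test_second_law_on_returned_solution(self):
        net = make_tfa_fixture_network()
        prob = build_tfa_problem(net, measured_rates={"upt": (0.9, 1.1)})
        opt = solve_tfa(prob)
        for rid in prob.thermo_rxns:
            v, g = opt.v[rid], opt.drg[rid]
            if abs(v) >= prob.epsilon_flux:
                assert np.sign(v) * g <= 1e-9


class TestVariability:
    def test_fully_pinned_toy_has_zero_width_flux_ranges(self):
        net = two_species_net(drg_target=-5.0, reversible=False,
                              conc_width=2.0)
        prob = build_tfa_problem(net, measured_rates={"upt": (1.0, 1.0)})
        sol = variability(prob, gamma=1.0)
        for rid, (lo, hi) in sol.flux_ranges.items():
            assert hi - lo < 1e-7

    def test_gamma_monotonicity(self):
        net = make_tfa_fixture_network()
        prob = build_tfa_problem(net, measured_rates={"upt": (0.5, 1.5)})
        tight = variability(prob, gamma=1.0)
        loose = variability(prob, gamma=0.999)
        for rid in tight.flux_ranges:
            lo_t, hi_t = tight.flux_ranges[rid]
            lo_l, hi_l = loose.flux_ranges[rid]
            assert lo_l <= lo_t + 1e-7
            assert hi_l >= hi_t - 1e-7

    def test_matches_direction_pattern_enumeration(self):
        """MILP optimum and every variability range against the exhaustive
        direction-pattern oracle (one LP per pattern)."""
        net = make_tfa_fixture_network()
        prob = build_tfa_problem(net, measured_rates={"upt": (0.5, 1.5)})
        opt = solve_tfa(prob)
        oracle_opt, oracle_ranges = brute_force_variability(prob)
        assert opt.optimum == pytest.approx(oracle_opt, abs=1e-6)
        sol = variability(prob)
        for rid, rng in sol.flux_ranges.items():
            assert rng == pytest.approx(oracle_ranges[("flux", rid)], abs=1e-6)
        for rid, rng in sol.drg_ranges.items():
            assert rng == pytest.approx(oracle_ranges[("drg", rid)], abs=1e-6)
        for mid, rng in sol.lnc_ranges.items():
            assert rng == pytest.approx(oracle_ranges[("lnc", mid)], abs=1e-6)


class TestClassification:
    def test_rules(self):
        ranges = {
            "near_narrow": (-3.0, -1.0),
            "far": (-24.0, -15.0),
            "boundary": (-30.0, -10.0),
            "spanning": (-24.0, -5.0),
        }
        labels = classify_equilibrium(ranges, threshold=10.0)
        assert labels["near_narrow"] == "near"
        assert labels["far"] == "far"
        assert labels["boundary"] == "far"  # closed comparison at -10
        assert labels["spanning"] == "near"


@pytest.fixture(scope="module")
def fixture_problem():
    net = make_tfa_fixture_network()
    return build_tfa_problem(net, measured_rates={"upt": (0.5, 1.5)})


class TestSampling:

    def test_sample_count_and_determinism(self, fixture_problem):
        s1 = sample_solutions(fixture_problem, n=200, seed=3)
        s2 = sample_solutions(fixture_problem, n=200, seed=3)
        assert s1.points.shape[0] == 200
        assert np.array_equal(s1.points, s2.points)

    def test_second_law_on_all_samples(self, fixture_problem):
        s = sample_solutions(fixture_problem, n=500, seed=1)
        eps = fixture_problem.epsilon_flux
        for rid in fixture_problem.thermo_rxns:
            v = s.v[:, s.v_columns.index(rid)]
            g = s.drg[:, s.drg_columns.index(rid)]
            active = np.abs(v) >= eps
            assert np.all(np.sign(v[active]) * g[active] <= 1e-9)

    def test_samples_satisfy_balances(self, fixture_problem):
        from thermomca.model_core import stoichiometric_matrix

        s = sample_solutions(fixture_problem, n=100, seed=2)
        N = stoichiometric_matrix(fixture_problem.network)
        assert np.abs(N @ s.v.T).max() < 1e-7

    def test_segment_mean_near_midpoint(self):
        """With every direction fixed and one degree of freedom, samples are
        uniform on a segment: the mean approaches the midpoint."""
        net = two_species_net(drg_target=-5.0, reversible=False,
                              conc_width=2.0)
        prob = build_tfa_problem(net, measured_rates={"upt": (0.5, 1.5)})
        s = sample_solutions(prob, n=4000, seed=7, gamma=1e-9)
        v = s.v[:, s.v_columns.index("upt")]
        lo, hi = v.min(), v.max()
        se = (hi - lo) / np.sqrt(12 * len(v))
        assert abs(v.mean() - 1.0) < 5 * se + 0.01

    def test_degenerate_polytope_returns_vertex(self):
        net = two_species_net(drg_target=-5.0, reversible=False,
                              conc_width=1.0)
        prob = build_tfa_problem(net, measured_rates={"upt": (1.0, 1.0)})
        with pytest.warns(UserWarning, match="degenerate"):
            s = sample_solutions(prob, n=25, seed=1)
        assert s.points.shape == (25, prob.n_continuous)
        assert np.allclose(s.points, s.points[0])
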
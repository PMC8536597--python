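"""Independent brute-force oracle for TFA: exhaustive direction-pattern
enumeration with one LP per pattern.

Every thermodynamically annotated reaction is assigned a state from
{forward, reverse, off} (reverse only if admissible); for each of the
(up to 3^r) joint patterns an LP with the corresponding sign constraints on
flux and deltarG' is solved. The MILP optimum must equal the best pattern's
optimum, and every variability range the min/max across patterns that reach
gamma times the global optimum.
"""

from itertools import product

import numpy as np
from scipy.optimize import linprog

from thermomca.constants import R
from thermomca.model_core import stoichiometric_matrix


def _pattern_lp(problem, pattern, c, extra=None):
    """LP for one direction pattern; returns optimum of min c^T x or None."""
    nc = problem.n_continuous
    net = problem.network
    n = len(net.reactions)
    lo = problem.bounds_lo[:nc].copy()
    hi = problem.bounds_hi[:nc].copy()
    eps, tol = problem.epsilon_flux, problem.drg_tol
    for rid, state in pattern.items():
        j = problem.v_index(rid)
        g = problem.g_index(rid)
        if state == "fwd":
            lo[j] = max(lo[j], eps)
            hi[g] = min(hi[g], -tol)
        elif state == "rev":
            hi[j] = min(hi[j], -eps)
            lo[g] = max(lo[g], tol)
        else:
            lo[j] = hi[j] = 0.0
    A_eq = problem.A_eq[:, :nc].toarray()
    b_eq = problem.b_eq
    A_ub = b_ub = None
    if extra is not None:
        A_ub, b_ub = extra
    res = linprog(c[:nc], A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=list(zip(lo, hi)), method="highs")
    return res.fun if res.success else None


def enumerate_patterns(problem):
    states = []
    for rid in problem.thermo_rxns:
        r = problem.network.reaction(rid)
        if r.reversible or r.flux_lb < 0:
            states.append([(rid, "fwd"), (rid, "rev"), (rid, "off")])
        else:
            states.append([(rid, "fwd"), (rid, "off")])
    for combo in product(*states):
        yield dict(combo)


def brute_force_optimum(problem):
    """Global optimum of the objective over all direction patterns."""
    nc = problem.n_continuous
    c = np.zeros(nc)
    c[problem.v_index(problem.objective)] = -1.0
    best = None
    for pattern in enumerate_patterns(problem):
        val = _pattern_lp(problem, pattern, c)
        if val is not None and (best is None or -val > best):
            best = -val
    return best


def brute_force_variability(problem, gamma=None):
    """Min/max of every flux, deltarG' and log-concentration across all
    patterns reaching gamma * the global optimum."""
    if gamma is None:
        gamma = problem.gamma
    nc = problem.n_continuous
    opt = brute_force_optimum(problem)
    cut = np.zeros(nc)
    cut[problem.v_index(problem.objective)] = -1.0
    extra = (cut[None, :], np.array([-gamma * opt]))
    net = problem.network
    targets = [("flux", rid, problem.v_index(rid)) for rid in net.reaction_ids]
    targets += [("drg", rid, problem.g_index(rid)) for rid in problem.thermo_rxns]
    targets += [("lnc", mid, problem.l_index(mid)) for mid in problem.lnc_mets]
    ranges = {}
    for kind, name, idx in targets:
        lo_best, hi_best = None, None
        for pattern in enumerate_patterns(problem):
            c = np.zeros(nc)
            c[idx] = 1.0
            v = _pattern_lp(problem, pattern, c, extra)
            if v is None:
                continue
            lo_best = v if lo_best is None else min(lo_best, v)
            c[idx] = -1.0
            v = _pattern_lp(problem, pattern, c, extra)
            hi = -v
            hi_best = hi if hi_best is None else max(hi_best, hi)
        ranges[(kind, name)] = (lo_best, hi_best)
    return opt, ranges


def make_tfa_fixture_network():
    """Small thermodynamically annotated network for oracle comparisons:
    supply -> A, reversible A<->B<->C plus a shortcut A<->C, drain C."""
    from thermomca.model_core import MetabolicNetwork, Metabolite, Reaction

    RT = R * 310.15
    mets = [
        Metabolite(id=m, name=m, measured=True, conc_lb=0.05, conc_ub=5.0,
                   conc_ref=1.0)
        for m in ("A", "B", "C")
    ]
    lnref = np.log(1e-3)

    def drg0_for(target, stoich):
        return target - RT * sum(stoich.values()) * lnref

    rxns = [
        Reaction(id="upt", stoich={"A": 1}, flux_lb=0, flux_ub=2.0,
                 pathway_tag="exchange"),
        Reaction(id="r_ab", stoich={"A": -1, "B": 1}, reversible=True,
                 flux_lb=-10, flux_ub=10, pathway_tag="GLYC&GLYK",
                 drg0=drg0_for(-1.0, {"A": -1, "B": 1})),
        Reaction(id="r_bc", stoich={"B": -1, "C": 1}, reversible=True,
                 flux_lb=-10, flux_ub=10, pathway_tag="GLYC&GLYK",
                 drg0=drg0_for(-2.0, {"B": -1, "C": 1})),
        Reaction(id="r_ac", stoich={"A": -1, "C": 1}, reversible=True,
                 flux_lb=-10, flux_ub=10, pathway_tag="PPP",
                 drg0=drg0_for(-3.0, {"A": -1, "C": 1})),
        Reaction(id="drain", stoich={"C": -1}, flux_lb=0, flux_ub=10,
                 pathway_tag="biomass", drg0=drg0_for(-20.0, {"C": -1})),
    ]
    net = MetabolicNetwork(metabolites=mets, reactions=rxns, name="tfa_fixture")
    net.validate()
    return net
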
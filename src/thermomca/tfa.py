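"""Thermodynamics-based flux variability analysis (TFA).

A mixed-integer linear program couples fluxes v, transformed Gibbs reaction
energies deltarG', log-concentrations and direction binaries over the
stoichiometric network:

    N v = 0
    deltarG'_j = deltarG'0_j + R T sum_i n_ij ln x_i        (x in mol/L)
    z_f = 1  =>  v_j >= eps   and  deltarG'_j <= 0          (big-M linking)
    z_r = 1  =>  v_j <= -eps  and  deltarG'_j >= 0
    z_f + z_r <= 1,  z_f = z_r = 0  =>  v_j = 0

so every thermodynamically annotated active reaction runs downhill
(second law: sign(v_j) * deltarG'_j <= 0). Measured extracellular rates and
intracellular concentrations restrict the solution space; the objective
(growth by default) is maximised, then per-variable minima/maxima are solved
under the constraint objective >= gamma * optimum (gamma = 0.999: routes
fulfilling 99.9% of the optimum). The residual solution space is explored
with a hit-and-run sampler after fixing the optimal direction pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import null_space
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .constants import MM_TO_M, R
from .errors import InfeasibleError, ValidationError
from .model_core import (
    DEFAULT_CONC_LB,
    DEFAULT_CONC_UB,
    MetabolicNetwork,
    stoichiometric_matrix,
)

#: |deltarG'| (kJ/mol) separating near- from far-from-equilibrium reactions
FAR_THRESHOLD = 10.0


def widen_point_measurements(values: dict[str, float],
                             rel: float = 0.05) -> dict[str, tuple[float, float]]:
    """Turn point measurements into (lb, ub) bounds by +-rel relative width."""
    out = {}
    for key, val in values.items():
        lo, hi = val * (1 - rel), val * (1 + rel)
        out[key] = (min(lo, hi), max(lo, hi))
    return out


@dataclass
class TFAProblem:
    """Assembled TFA constraint system over one network."""

    network: MetabolicNetwork
    measured_rates: dict[str, tuple[float, float]]
    measured_conc: dict[str, tuple[float, float]]
    objective: str
    gamma: float = 0.999
    bigM: float = 1000.0
    epsilon_flux: float = 1e-6
    drg_tol: float = 0.0
    # filled by the builder
    thermo_rxns: list[str] = field(default_factory=list)
    lnc_mets: list[str] = field(default_factory=list)
    n_vars: int = 0
    bounds_lo: np.ndarray | None = None
    bounds_hi: np.ndarray | None = None
    integrality: np.ndarray | None = None
    A_eq: sparse.csr_matrix | None = None
    b_eq: np.ndarray | None = None
    A_ub: sparse.csr_matrix | None = None
    b_ub: np.ndarray | None = None

    # variable-layout helpers -------------------------------------------------
    def v_index(self, rxn_id: str) -> int:
        return self.network.rxn_idx(rxn_id)

    def g_index(self, rxn_id: str) -> int:
        return len(self.network.reactions) + self.thermo_rxns.index(rxn_id)

    def l_index(self, met_id: str) -> int:
        return (len(self.network.reactions) + len(self.thermo_rxns)
                + self.lnc_mets.index(met_id))

    @property
    def n_continuous(self) -> int:
        return len(self.network.reactions) + len(self.thermo_rxns) + len(self.lnc_mets)


@dataclass
class TFAOptimum:
    """MILP optimum with one feasible solution."""

    optimum: float
    v: dict[str, float]
    drg: dict[str, float]
    lnc: dict[str, float]
    z_forward: dict[str, int]
    z_reverse: dict[str, int]


@dataclass
class ThermoSolution:
    """Variability output: per-variable feasible ranges and directions."""

    optimum: float
    flux_ranges: dict[str, tuple[float, float]]
    drg_ranges: dict[str, tuple[float, float]]
    lnc_ranges: dict[str, tuple[float, float]]
    directions: dict[str, str]

    def affinity_ranges(self) -> dict[str, tuple[float, float]]:
        """Thermodynamic driving forces A = -deltarG' per reaction."""
        return {r: (-hi, -lo) for r, (lo, hi) in self.drg_ranges.items()}

    def to_dict(self) -> dict:
        return {
            "optimum": self.optimum,
            "flux_ranges": {k: list(v) for k, v in self.flux_ranges.items()},
            "drg_ranges": {k: list(v) for k, v in self.drg_ranges.items()},
            "lnc_ranges": {k: list(v) for k, v in self.lnc_ranges.items()},
            "directions": self.directions,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ThermoSolution":
        return cls(
            optimum=doc["optimum"],
            flux_ranges={k: tuple(v) for k, v in doc["flux_ranges"].items()},
            drg_ranges={k: tuple(v) for k, v in doc["drg_ranges"].items()},
            lnc_ranges={k: tuple(v) for k, v in doc["lnc_ranges"].items()},
            directions=dict(doc["directions"]),
        )


# ---------------------------------------------------------------------------
# Problem construction
# ---------------------------------------------------------------------------

def build_tfa_problem(
    net: MetabolicNetwork,
    measured_rates: dict[str, tuple[float, float]] | None = None,
    measured_conc: dict[str, tuple[float, float]] | None = None,
    objective: str | None = None,
    gamma: float = 0.999,
    bigM: float = 1000.0,
    epsilon_flux: float = 1e-6,
) -> TFAProblem:
    """Assemble the TFA MILP for a network and measurement tables.

    Rates in mmol/gCDW/h, concentrations in mM (converted to mol/L inside the
    log terms). Reactions without a transformed standard Gibbs energy are
    treated flux-only (with a warning for non-exchange reactions); unmeasured
    metabolite concentrations default to [1e-4, 50] mM.
    """
    measured_rates = dict(measured_rates or {})
    measured_conc = dict(measured_conc or {})
    if not (0 < gamma <= 1):
        raise ValidationError("gamma must be in (0, 1]")
    for rid in measured_rates:
        if rid not in net._rxn_index:
            raise ValidationError(f"measured rate references unknown reaction {rid}")
    for mid in measured_conc:
        if mid not in net._met_index:
            raise ValidationError(
                f"measured concentration references unknown metabolite {mid}"
            )
    if objective is None:
        objective = next(
            r.id for r in net.reactions if r.pathway_tag == "biomass"
        )
    if objective not in net._rxn_index:
        raise ValidationError(f"objective reaction {objective!r} not in network")

    prob = TFAProblem(
        network=net, measured_rates=measured_rates, measured_conc=measured_conc,
        objective=objective, gamma=gamma, bigM=bigM, epsilon_flux=epsilon_flux,
    )
    thermo, flux_only = [], []
    for r in net.reactions:
        if net.reaction_drg0(r) is not None:
            thermo.append(r.id)
        elif r.pathway_tag not in ("exchange", "biomass"):
            flux_only.append(r.id)
    if flux_only:
        warnings.warn(
            f"reactions without deltarG'0 treated flux-only: {flux_only}"
        )
    prob.thermo_rxns = thermo
    lnc = []
    for rid in thermo:
        for mid in net.reaction(rid).stoich:
            if mid not in lnc:
                lnc.append(mid)
    prob.lnc_mets = lnc

    n = len(net.reactions)
    nt, nl = len(thermo), len(lnc)
    rev_thermo = [rid for rid in thermo if net.reaction(rid).reversible
                  or net.reaction(rid).flux_lb < 0]
    prob.n_vars = n + nt + nl + nt + len(rev_thermo)
    zf_ofs = n + nt + nl
    zr_pos = {rid: zf_ofs + nt + k for k, rid in enumerate(rev_thermo)}

    lo = np.full(prob.n_vars, -np.inf)
    hi = np.full(prob.n_vars, np.inf)
    integrality = np.zeros(prob.n_vars)
    RT = R * net.temperature

    for j, r in enumerate(net.reactions):
        lo[j], hi[j] = r.flux_lb, r.flux_ub
        if r.id in measured_rates:
            mlo, mhi = measured_rates[r.id]
            lo[j], hi[j] = max(lo[j], mlo), min(hi[j], mhi)
            if lo[j] > hi[j]:
                raise ValidationError(
                    f"measured rate bounds for {r.id} conflict with model bounds"
                )
    for k, rid in enumerate(thermo):
        lo[n + k], hi[n + k] = -bigM, bigM
    for k, mid in enumerate(lnc):
        met = net.metabolite(mid)
        clo, chi = met.conc_lb, met.conc_ub
        if mid in measured_conc:
            clo, chi = measured_conc[mid]
        if not (0 < clo <= chi):
            raise ValidationError(f"bad concentration bounds for {mid}")
        lo[n + nt + k] = np.log(clo * MM_TO_M)
        hi[n + nt + k] = np.log(chi * MM_TO_M)
    for k in range(nt + len(rev_thermo)):
        lo[zf_ofs + k], hi[zf_ofs + k] = 0, 1
        integrality[zf_ofs + k] = 1

    # equalities: N v = 0 ; g - RT * sum n ln x = drg0
    N = stoichiometric_matrix(net)
    rows_eq = [sparse.hstack([
        sparse.csr_matrix(N), sparse.csr_matrix((N.shape[0], prob.n_vars - n))
    ])]
    b_eq = [np.zeros(N.shape[0])]
    eq = sparse.lil_matrix((nt, prob.n_vars))
    beq2 = np.zeros(nt)
    for k, rid in enumerate(thermo):
        r = net.reaction(rid)
        eq[k, n + k] = 1.0
        for mid, n_ij in r.stoich.items():
            eq[k, prob.l_index(mid)] += -RT * n_ij
        beq2[k] = net.reaction_drg0(r)
    rows_eq.append(eq.tocsr())
    b_eq.append(beq2)
    prob.A_eq = sparse.vstack(rows_eq).tocsr()
    prob.b_eq = np.concatenate(b_eq)

    # inequalities (A x <= b): big-M direction coupling
    ub_rows, ub_b = [], []

    def add_row(entries: dict[int, float], rhs: float) -> None:
        row = sparse.lil_matrix((1, prob.n_vars))
        for idx, val in entries.items():
            row[0, idx] = val
        ub_rows.append(row.tocsr())
        ub_b.append(rhs)

    eps, M, tol = epsilon_flux, bigM, prob.drg_tol
    for k, rid in enumerate(thermo):
        r = net.reaction(rid)
        j = net.rxn_idx(rid)
        gj = n + k
        zf = zf_ofs + k
        vub = hi[j] if np.isfinite(hi[j]) else M
        vlb = lo[j] if np.isfinite(lo[j]) else -M
        if rid in zr_pos:
            zr = zr_pos[rid]
            add_row({zf: 1.0, zr: 1.0}, 1.0)             # one direction at a time
            add_row({j: 1.0, zf: -vub, zr: eps}, 0.0)    # v <= ub zf - eps zr
            add_row({j: -1.0, zf: eps, zr: vlb}, 0.0)    # v >= eps zf + lb zr
            add_row({gj: 1.0, zf: M}, M - tol)           # zf=1 => g <= -tol
            add_row({gj: -1.0, zr: M}, M - tol)          # zr=1 => g >= tol
        else:
            add_row({j: 1.0, zf: -vub}, 0.0)             # v <= ub zf
            add_row({j: -1.0, zf: eps}, 0.0)             # v >= eps zf
            add_row({gj: 1.0, zf: M}, M - tol)           # zf=1 => g <= -tol
    prob.A_ub = sparse.vstack(ub_rows).tocsr() if ub_rows else None
    prob.b_ub = np.array(ub_b)
    prob.bounds_lo, prob.bounds_hi = lo, hi
    prob.integrality = integrality
    return prob


def _milp_solve(prob: TFAProblem, c: np.ndarray,
                extra_constraints: list[LinearConstraint] | None = None):
    cons = [LinearConstraint(prob.A_eq, prob.b_eq, prob.b_eq)]
    if prob.A_ub is not None:
        cons.append(LinearConstraint(prob.A_ub, -np.inf, prob.b_ub))
    if extra_constraints:
        cons.extend(extra_constraints)
    res = milp(
        c=c, constraints=cons, integrality=prob.integrality,
        bounds=Bounds(prob.bounds_lo, prob.bounds_hi),
    )
    return res


def solve_tfa(problem: TFAProblem) -> TFAOptimum:
    """Maximise the objective flux; returns the optimum and one feasible
    solution (fluxes, reaction energies, log-concentrations, directions)."""
    c = np.zeros(problem.n_vars)
    c[problem.v_index(problem.objective)] = -1.0
    res = _milp_solve(problem, c)
    if res.status != 0 or res.x is None:
        raise InfeasibleError(
            f"TFA problem infeasible or unbounded (solver status {res.status}: "
            f"{res.message})"
        )
    net = problem.network
    n, nt = len(net.reactions), len(problem.thermo_rxns)
    x = res.x
    zf_ofs = n + nt + len(problem.lnc_mets)
    rev = [rid for rid in problem.thermo_rxns
           if net.reaction(rid).reversible or net.reaction(rid).flux_lb < 0]
    return TFAOptimum(
        optimum=-res.fun,
        v={r.id: float(x[j]) for j, r in enumerate(net.reactions)},
        drg={rid: float(x[problem.g_index(rid)]) for rid in problem.thermo_rxns},
        lnc={mid: float(x[problem.l_index(mid)]) for mid in problem.lnc_mets},
        z_forward={rid: int(round(x[zf_ofs + k]))
                   for k, rid in enumerate(problem.thermo_rxns)},
        z_reverse={rid: int(round(x[zf_ofs + nt + k]))
                   for k, rid in enumerate(rev)},
    )


def variability(problem: TFAProblem, gamma: float | None = None,
                variables: str = "all") -> ThermoSolution:
    """Feasible ranges of fluxes, reaction energies and log-concentrations
    over all solutions reaching ``gamma`` of the MILP optimum.

    ``variables`` restricts the sweep ("fluxes", "drg", "lnc" or "all").
    """
    if gamma is None:
        gamma = problem.gamma
    opt = solve_tfa(problem)
    cut = np.zeros(problem.n_vars)
    cut[problem.v_index(problem.objective)] = -1.0
    gamma_con = LinearConstraint(
        sparse.csr_matrix(cut), -np.inf, -gamma * opt.optimum
    )

    def minmax(idx: int, vid: str) -> tuple[float, float]:
        out = []
        for sign in (1.0, -1.0):
            c = np.zeros(problem.n_vars)
            c[idx] = sign
            res = _milp_solve(problem, c, [gamma_con])
            if res.status != 0 or res.x is None:
                raise InfeasibleError(
                    f"variability subproblem failed for {vid} "
                    f"(status {res.status}: {res.message})"
                )
            # clip solver slop back into the variable's own bounds
            val = np.clip(sign * res.fun,
                          problem.bounds_lo[idx], problem.bounds_hi[idx])
            out.append(float(val))
        return (min(out), max(out))

    net = problem.network
    flux_ranges, drg_ranges, lnc_ranges = {}, {}, {}
    if variables in ("all", "fluxes"):
        for j, r in enumerate(net.reactions):
            flux_ranges[r.id] = minmax(j, f"flux {r.id}")
    if variables in ("all", "drg"):
        for rid in problem.thermo_rxns:
            drg_ranges[rid] = minmax(problem.g_index(rid), f"deltarG {rid}")
    if variables in ("all", "lnc"):
        for mid in problem.lnc_mets:
            lnc_ranges[mid] = minmax(problem.l_index(mid), f"ln conc {mid}")
    directions = {}
    for rid, (lov, hiv) in flux_ranges.items():
        if lov >= -problem.epsilon_flux and hiv >= 0:
            directions[rid] = "forward"
        elif hiv <= problem.epsilon_flux and lov <= 0:
            directions[rid] = "reverse"
        else:
            directions[rid] = "either"
    return ThermoSolution(
        optimum=opt.optimum,
        flux_ranges=flux_ranges,
        drg_ranges=drg_ranges,
        lnc_ranges=lnc_ranges,
        directions=directions,
    )


def classify_equilibrium(drg_ranges: dict[str, tuple[float, float]],
                         threshold: float = FAR_THRESHOLD) -> dict[str, str]:
    """Near/far-from-equilibrium labels from feasible deltarG' ranges.

    "near" iff the range intersects (-threshold, 0] or beyond (its upper end
    exceeds -threshold); ranges lying entirely at or below -threshold are
    "far" (closed comparison at the boundary).
    """
    return {
        rid: ("far" if hi <= -threshold else "near")
        for rid, (lo, hi) in drg_ranges.items()
    }


# ---------------------------------------------------------------------------
# Polytope sampling
# ---------------------------------------------------------------------------

@dataclass
class SampleSet:
    """Feasible points from the direction-fixed solution polytope."""

    points: np.ndarray          # n_samples x n_continuous
    v_columns: list[str]
    drg_columns: list[str]
    lnc_columns: list[str]

    @property
    def v(self) -> np.ndarray:
        return self.points[:, : len(self.v_columns)]

    @property
    def drg(self) -> np.ndarray:
        nv = len(self.v_columns)
        return self.points[:, nv: nv + len(self.drg_columns)]

    @property
    def lnc(self) -> np.ndarray:
        ofs = len(self.v_columns) + len(self.drg_columns)
        return self.points[:, ofs:]


def sample_solutions(problem: TFAProblem, n: int = 10_000, seed: int = 0,
                     gamma: float | None = None,
                     warmup_per_dim: int = 100, thinning: int = 10) -> SampleSet:
    """Hit-and-run sampling of the direction-fixed solution polytope.

    The MILP is solved once; its optimal direction pattern fixes the
    binaries, leaving an LP polytope over (v, deltarG', ln x). Points are
    drawn by artificially centered hit-and-run from a Chebyshev-type
    interior start, with ``warmup_per_dim * dim`` warm-up steps and the
    given thinning; deterministic for a fixed seed. A zero-volume polytope
    returns the single feasible vertex n times with a warning.

    ``gamma`` optionally adds the optimality cut (objective >= gamma *
    optimum) to restrict sampling to near-optimal routes; by default the
    whole measured-constrained feasible space of the state is sampled.
    """
    opt = solve_tfa(problem)
    net = problem.network
    nc = problem.n_continuous
    n_rxn = len(net.reactions)

    lo = problem.bounds_lo[:nc].copy()
    hi = problem.bounds_hi[:nc].copy()
    eps, tol = problem.epsilon_flux, problem.drg_tol
    # fix the direction pattern
    for rid in problem.thermo_rxns:
        j = problem.v_index(rid)
        gj = problem.g_index(rid)
        zf = opt.z_forward[rid]
        zr = opt.z_reverse.get(rid, 0)
        if zf:
            lo[j] = max(lo[j], eps)
            hi[gj] = min(hi[gj], -tol)
        elif zr:
            hi[j] = min(hi[j], -eps)
            lo[gj] = max(lo[gj], tol)
        else:
            lo[j], hi[j] = 0.0, 0.0

    A_eq = problem.A_eq[:, :nc].toarray()
    b_eq = list(problem.b_eq)
    eq_rows = [A_eq]
    # variables pinned by the direction pattern join the equality system so
    # they do not flatten the Chebyshev radius of the remaining polytope
    pinned = hi - lo < 1e-12
    for i in np.where(pinned)[0]:
        e = np.zeros(nc)
        e[i] = 1.0
        eq_rows.append(e[None, :])
        b_eq.append(lo[i])
    A_eq = np.vstack(eq_rows)
    b_eq = np.array(b_eq)
    # inequalities: optional gamma cut + finite bounds of free variables
    rows, rhs = [], []
    if gamma is not None:
        cut = np.zeros(nc)
        cut[problem.v_index(problem.objective)] = -1.0
        rows.append(cut)
        rhs.append(-gamma * opt.optimum)
    for i in range(nc):
        if pinned[i]:
            continue
        if np.isfinite(hi[i]):
            e = np.zeros(nc)
            e[i] = 1.0
            rows.append(e)
            rhs.append(hi[i])
        if np.isfinite(lo[i]):
            e = np.zeros(nc)
            e[i] = -1.0
            rows.append(e)
            rhs.append(-lo[i])
    A_in = np.array(rows)
    b_in = np.array(rhs)

    # interior starting point within the affine subspace (Chebyshev-type)
    x0 = np.array(
        [opt.v[r.id] for r in net.reactions]
        + [opt.drg[rid] for rid in problem.thermo_rxns]
        + [opt.lnc[mid] for mid in problem.lnc_mets]
    )
    # Null-space basis built block-wise: the equalities decouple into
    # N v = 0 (fluxes) and deltarG' = deltarG'0 + RT N^T ln x (each
    # log-concentration is a free coordinate that drags its reaction
    # energies along). Axis-aligned concentration moves make the chain mix
    # well in the thermodynamic block.
    RT = R * net.temperature
    N_mat = stoichiometric_matrix(net)
    free = ~pinned
    n_v = n_rxn
    cols_B = []
    v_free = np.where(free[:n_v])[0]
    if len(v_free):
        Bv = null_space(N_mat[:, v_free], rcond=1e-10)
        for k in range(Bv.shape[1]):
            vec = np.zeros(nc)
            vec[v_free] = Bv[:, k]
            cols_B.append(vec)
    for i, mid in enumerate(problem.lnc_mets):
        li = problem.l_index(mid)
        if pinned[li]:
            continue
        vec = np.zeros(nc)
        vec[li] = 1.0
        mrow = net.met_idx(mid)
        for kk, rid in enumerate(problem.thermo_rxns):
            n_ij = N_mat[mrow, net.rxn_idx(rid)]
            if n_ij:
                vec[problem.g_index(rid)] = RT * n_ij
        cols_B.append(vec)
    B = np.array(cols_B).T if cols_B else np.zeros((nc, 0))
    dim = B.shape[1]
    cols = (
        [r.id for r in net.reactions],
        list(problem.thermo_rxns),
        list(problem.lnc_mets),
    )
    if dim == 0:
        warnings.warn("degenerate (zero-volume) polytope; returning the vertex")
        return SampleSet(np.tile(x0, (n, 1)), *cols)

    G = A_in @ B
    h = b_in - A_in @ x0
    norms = np.linalg.norm(G, axis=1)
    res = linprog(
        c=np.concatenate([np.zeros(dim), [-1.0]]),
        A_ub=np.hstack([G, norms[:, None]]),
        b_ub=h,
        bounds=[(None, None)] * dim + [(0, None)],
        method="highs",
    )
    if res.success and res.x[-1] > 1e-12:
        t = res.x[:dim]
        radius = res.x[-1]
    else:
        warnings.warn("degenerate (zero-volume) polytope; returning the vertex")
        return SampleSet(np.tile(x0, (n, 1)), *cols)

    # precondition: rescale each null-space coordinate by its feasible extent
    # (the polytope is strongly anisotropic; without this, coordinate moves
    # are dominated by the tightest constraint and the chain barely mixes)
    extents = np.empty(dim)
    for k in range(dim):
        c_k = np.zeros(dim)
        spans = []
        for sign in (1.0, -1.0):
            c_k[k] = sign
            r = linprog(c_k, A_ub=G, b_ub=h, bounds=[(None, None)] * dim,
                        method="highs")
            spans.append(sign * r.fun if r.success else 0.0)
        extents[k] = max(abs(spans[1] - spans[0]) / 2, 1e-9)
    Bs = B * extents[None, :]
    Gs = G * extents[None, :]
    ts = t / extents

    rng = np.random.default_rng(seed)
    # artificially centered hit-and-run: directions run through the moving
    # centre of the visited points, which handles the strongly elongated
    # polytopes typical of flux spaces
    n_warm = warmup_per_dim * dim
    total = n_warm + thinning * n
    archive = np.empty((total + 1, dim))
    archive[0] = ts
    center = ts.copy()
    t_c = ts.copy()
    slack = h - Gs @ t_c
    samples = np.empty((n, nc))
    kept = 0
    for step in range(total):
        if step < max(2 * dim, 10):
            d = rng.standard_normal(dim)       # initial isotropic phase
        else:
            p = archive[int(rng.integers(step + 1))]
            d = p - center
        nrm = np.linalg.norm(d)
        if nrm < 1e-14:
            d = rng.standard_normal(dim)
            nrm = np.linalg.norm(d)
        d /= nrm
        gd = Gs @ d
        with np.errstate(divide="ignore"):
            ratios = slack / gd
        pos = ratios[gd > 1e-14]
        neg = ratios[gd < -1e-14]
        t_hi = pos.min() if len(pos) else 0.0
        t_lo = neg.max() if len(neg) else 0.0
        step_len = rng.uniform(t_lo, t_hi)
        t_c = t_c + step_len * d
        slack = slack - step_len * gd
        archive[step + 1] = t_c
        center += (t_c - center) / (step + 2)
        if step >= n_warm and (step - n_warm + 1) % thinning == 0:
            if kept < n:
                samples[kept] = x0 + Bs @ t_c
                kept += 1
    while kept < n:       # guard against rounding in the step count
        samples[kept] = x0 + Bs @ t_c
        kept += 1
    return SampleSet(samples, *cols)
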
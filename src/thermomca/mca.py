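"""Metabolic control analysis via the steady-state linearisation approach.

Flux control coefficients (FCCs) quantify how a steady-state flux responds
to a 1% change in one enzyme's activity. Given the scaled elasticity matrix
E (reactions x metabolites), the stoichiometric matrix N with reduced form
N_R over independent metabolites, reference fluxes v0 and concentrations X0,
the concentration-response kernel is

    K = -L0 (N_R [v0] E L0)^(-1) N_R [v0],      L0 = [X0]^(-1) N (N_R)^+ [X0^ind]

and the flux-FCC matrix (fluxes x enzymes) is C_v = I + E K. The identity
term completes the canonical lin-log expression; the product E*K alone is the
concentration-response part and is retained as ``C_response`` for reference
(it does not satisfy the summation theorem on its own).

Uncertainty in the reference fluxes, Gibbs reaction energies and metabolite
concentrations is propagated by Monte Carlo: each cycle redraws them
uniformly and independently within their thermodynamically feasible ranges,
rebuilds E and recomputes C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import SingularSystemError, ValidationError
from .model_core import StructuralDecomposition, decompose

# inner matrices past this condition number are treated as singular: the
# linearised control coefficients at such points are dominated by the
# near-singularity (typical well-posed problems sit around 1e3-1e5)
_MAX_CONDITION = 1e8


@dataclass
class SteadyState:
    """Fluxes, concentrations and enzyme levels of one metabolic steady state.

    ``v0`` is indexed by ``reaction_ids`` (mmol/gCDW/h), ``X0`` by
    ``metabolite_ids`` (mM), ``e0`` by ``reaction_ids`` (dimensionless enzyme
    multipliers, 1 at the reference).
    """

    id: str
    reaction_ids: list[str]
    metabolite_ids: list[str]
    v0: np.ndarray
    X0: np.ndarray
    e0: np.ndarray
    is_reference: bool = False

    def __post_init__(self) -> None:
        self.v0 = np.asarray(self.v0, dtype=float)
        self.X0 = np.asarray(self.X0, dtype=float)
        self.e0 = np.asarray(self.e0, dtype=float)
        if np.any(self.X0 <= 0):
            bad = [m for m, x in zip(self.metabolite_ids, self.X0) if x <= 0]
            raise ValidationError(f"state {self.id}: non-positive concentrations {bad}")

    def flux(self, rxn_id: str) -> float:
        return float(self.v0[self.reaction_ids.index(rxn_id)])

    def conc(self, met_id: str) -> float:
        return float(self.X0[self.metabolite_ids.index(met_id)])


@dataclass
class FCCResult:
    """Flux-control-coefficient matrix with optional Monte Carlo summaries.

    ``C`` is enzymes x fluxes: entry (j, i) is the control of enzyme j on
    flux i, so each flux's column of enzyme FCCs sums to 1 (summation
    theorem). For Monte Carlo runs ``C`` holds entrywise means and
    ``summary`` the spread statistics.
    """

    C: np.ndarray
    L0: np.ndarray
    reaction_ids: list[str]
    C_response: np.ndarray | None = None
    summary: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    n_cycles: int = 0
    n_dropped: int = 0


def link_matrix(N: np.ndarray, decomposition: StructuralDecomposition,
                X0: np.ndarray) -> np.ndarray:
    """Concentration-scaled link matrix L0 = [X0]^-1 N (N_R)^+ [X0^ind].

    Maps scaled deviations of the independent metabolites to all metabolites
    under the network's conservation relations. Rows of L0 belonging to
    independent metabolites form the identity.
    """
    X0 = np.asarray(X0, dtype=float)
    if np.any(X0 <= 0):
        bad = int(np.argmin(X0))
        raise ValidationError(f"zero/negative concentration at metabolite index {bad}")
    ind = decomposition.independent_idx
    pinv_NR = np.linalg.pinv(decomposition.NR)
    return (N @ pinv_NR) * (X0[ind][None, :] / X0[:, None])


def flux_control_coefficients(
    E: np.ndarray,
    N: np.ndarray,
    v0: np.ndarray,
    X0: np.ndarray,
    decomposition: StructuralDecomposition | None = None,
    reaction_ids: list[str] | None = None,
) -> FCCResult:
    """Point estimate of the flux-FCC matrix from the linearised balances.

    Requires the inner Jacobian M = N_R [v0] E L0 to be invertible; its
    condition number is reported on failure. ``E`` is reactions x metabolites
    over the same metabolite ordering as the rows of ``N``.
    """
    N = np.asarray(N, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    if decomposition is None:
        decomposition = decompose(N)
    L0 = link_matrix(N, decomposition, X0)
    NR_V = decomposition.NR * v0[None, :]
    M = NR_V @ E @ L0
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise SingularSystemError(
            f"inner matrix N_R [v0] E L0 is singular (condition number {cond:.3e}); "
            "Monte Carlo perturbation may help but is not applied automatically"
        )
    K = -L0 @ np.linalg.solve(M, NR_V)
    C_flux_enzyme = np.eye(len(v0)) + E @ K
    C_response = E @ K
    result = FCCResult(
        C=C_flux_enzyme.T.copy(),
        L0=L0,
        reaction_ids=list(reaction_ids) if reaction_ids else [],
        C_response=C_response.T.copy(),
    )
    result.diagnostics = theorem_checks(result, E, L0)
    result.diagnostics["condition_number"] = float(cond)
    return result


def theorem_checks(result: FCCResult, E: np.ndarray, L0: np.ndarray | None = None) -> dict:
    """Summation and connectivity residuals of a point FCC computation.

    Summation: for every flux, enzyme FCCs sum to 1. Connectivity: FCCs
    weighted by the elasticities toward each independent metabolite sum to 0
    (evaluated through E L0, which folds conservation relations in).
    """
    C_flux_enzyme = result.C.T
    summation = float(np.abs(C_flux_enzyme.sum(axis=1) - 1.0).max())
    if L0 is None:
        L0 = result.L0
    EL0 = E @ L0
    connectivity = float(np.abs(C_flux_enzyme @ EL0).max()) if EL0.size else 0.0
    return {"summation_residual": summation, "connectivity_residual": connectivity}


def monte_carlo_fcc(
    E_builder: Callable[[np.ndarray, np.ndarray, dict], np.ndarray],
    N: np.ndarray,
    flux_ranges: np.ndarray,
    conc_ranges: np.ndarray,
    drg_ranges: dict[str, tuple[float, float]],
    n_cycles: int = 10_000,
    seed: int = 0,
    decomposition: StructuralDecomposition | None = None,
    reaction_ids: list[str] | None = None,
) -> FCCResult:
    """Monte Carlo propagation of flux / Gibbs-energy / concentration ranges.

    Per cycle, reference fluxes v0, concentrations X0 and reaction energies
    are drawn uniformly and independently within their feasible ranges
    (``flux_ranges``: n x 2, ``conc_ranges``: m x 2 in mM, ``drg_ranges``:
    reaction id -> (lo, hi)), E is rebuilt by ``E_builder(v0, X0, drg_draw)``
    and C recomputed. Cycles with a singular inner matrix are dropped and
    counted; summaries are the entrywise mean, sd and central 90% interval
    over the retained cycles.
    """
    if decomposition is None:
        decomposition = decompose(N)
    rng = np.random.default_rng(seed)
    flux_ranges = np.asarray(flux_ranges, dtype=float)
    conc_ranges = np.asarray(conc_ranges, dtype=float)
    n = flux_ranges.shape[0]
    samples = []
    dropped = 0
    drg_ids = sorted(drg_ranges)
    for _ in range(n_cycles):
        v0 = rng.uniform(flux_ranges[:, 0], flux_ranges[:, 1])
        X0 = rng.uniform(conc_ranges[:, 0], conc_ranges[:, 1])
        drg_draw = {
            rid: float(rng.uniform(*drg_ranges[rid])) for rid in drg_ids
        }
        try:
            E = E_builder(v0, X0, drg_draw)
            res = flux_control_coefficients(
                E, N, v0, X0, decomposition=decomposition,
            )
        except SingularSystemError:
            dropped += 1
            continue
        samples.append(res.C)
    if dropped > 0.5 * n_cycles:
        raise SingularSystemError(
            f"model too ill-conditioned: {dropped}/{n_cycles} Monte Carlo cycles "
            "had a singular inner matrix"
        )
    stack = np.stack(samples)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(samples) > 1 else np.zeros_like(mean)
    q05 = np.quantile(stack, 0.05, axis=0)
    q95 = np.quantile(stack, 0.95, axis=0)
    X0_mid = conc_ranges.mean(axis=1)
    L0 = link_matrix(N, decomposition, X0_mid)
    return FCCResult(
        C=mean,
        L0=L0,
        reaction_ids=list(reaction_ids) if reaction_ids else [],
        summary={"mean": mean, "sd": sd, "q05": q05, "q95": q95},
        diagnostics={"se_mean": sd / np.sqrt(max(len(samples), 1))},
        n_cycles=n_cycles,
        n_dropped=dropped,
    )
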
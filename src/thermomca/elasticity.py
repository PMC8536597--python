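"""Elasticity estimation: thermokinetic and lin-log regression routes.

Scaled elasticities eps_i^j = dln v_j / dln X_i are the local sensitivities
entering metabolic control analysis. Two estimators are combined depending
on a reaction's thermodynamic state:

* near equilibrium (feasible deltarG' range reaching above -threshold): the
  net rate is controlled by the displacement from equilibrium, giving the
  thermokinetic form  eps = -n_ij R T / (A_j - A_j#)  with A_j = -deltarG'_j
  and A_j# = 0, i.e. eps = n_ij R T / deltarG'_j;

* far from equilibrium (entire range at or below -threshold): the reaction
  is assumed actively regulated and product-saturated; elasticities with
  respect to its substrates and literature effectors are estimated by
  regressing the lin-log steady-state relation

      v_j/v_j0 * e_j0/e_j - 1 = sum_i ln(X_i/X_i0) * eps_i

  across the perturbation steady states relative to the reference state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import R, T_DEFAULT
from .errors import ValidationError
from .mca import SteadyState
from .model_core import MetabolicNetwork, stoichiometric_matrix

#: |deltarG'| (kJ/mol) separating near- from far-from-equilibrium reactions
NEAR_EQUILIBRIUM_THRESHOLD = 10.0


@dataclass
class EffectorMap:
    """Per-reaction regulating metabolites (activator/inhibitor roles)."""

    effectors: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, effs in self.effectors.items():
            seen = set()
            for mid, role in effs:
                if role not in ("activator", "inhibitor"):
                    raise ValidationError(
                        f"effector role must be activator/inhibitor, got {role!r}"
                    )
                if mid in seen:
                    raise ValidationError(
                        f"duplicate effector {mid} for reaction {rid}"
                    )
                seen.add(mid)

    def for_reaction(self, rxn_id: str) -> list[tuple[str, str]]:
        return self.effectors.get(rxn_id, [])

    def validate_against(self, net: MetabolicNetwork) -> None:
        for rid, effs in self.effectors.items():
            if rid not in net._rxn_index:
                raise ValidationError(f"effector map references unknown reaction {rid}")
            for mid, _ in effs:
                if mid not in net._met_index:
                    raise ValidationError(
                        f"effector map references unknown metabolite {mid}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "EffectorMap":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        effs = {
            rid: [(e["metabolite"], e["role"]) for e in entries]
            for rid, entries in doc.get("effectors", {}).items()
        }
        return cls(effectors=effs)


@dataclass
class ElasticityMatrix:
    """Reactions x metabolites scaled-elasticity matrix with provenance.

    ``provenance`` holds one of {"thermokinetic", "linlog", "zero"} per
    entry; metabolites neither participating in nor regulating a reaction
    stay zero.
    """

    values: np.ndarray
    provenance: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    reference_state_id: str = ""

    def row(self, rxn_id: str) -> np.ndarray:
        return self.values[self.reaction_ids.index(rxn_id)]


def thermokinetic_elasticity(n_ij: float, drg_prime: float,
                             T: float = T_DEFAULT) -> float:
    """Elasticity of a near-equilibrium reaction from its driving force.

    eps = -n_ij R T / (A - A#) with A = -deltarG' and A# = 0, which reduces
    to n_ij R T / deltarG'. The expression is orientation-invariant (flipping
    both the stoichiometric sign and the reaction energy leaves it unchanged),
    so reactions running net-reverse need no special casing. Undefined at
    equilibrium (deltarG' = 0).
    """
    if drg_prime == 0:
        raise ValidationError("elasticity undefined at equilibrium (deltarG' = 0)")
    return n_ij * R * T / drg_prime


#: prior scale of lin-log elasticities (order-one quantities)
_ELASTICITY_PRIOR_SD = 1.0


def _ridged_bounded_lstsq(G: np.ndarray, y: np.ndarray,
                          lo: np.ndarray | None = None,
                          hi: np.ndarray | None = None) -> np.ndarray:
    """Least squares with an empirical-Bayes ridge and optional sign bounds.

    A first ordinary pass estimates the residual noise level s; the solution
    is then the MAP estimate under an eps ~ N(0, 1) prior with observation
    variance s^2 (penalty s^2 ||eps||^2, realised by row augmentation). On
    noise-free data s -> 0 and the estimate reduces to plain least squares;
    under noise, weakly identified directions are shrunk instead of exploding.
    Sign bounds (substrates >= 0, inhibitors <= 0) are enforced when the
    unconstrained solution violates them.
    """
    sol, *_ = np.linalg.lstsq(G, y, rcond=None)
    s2 = float(np.mean((G @ sol - y) ** 2))
    if s2 > 0:
        k = G.shape[1]
        lam = np.sqrt(s2) / _ELASTICITY_PRIOR_SD
        G_aug = np.vstack([G, lam * np.eye(k)])
        y_aug = np.concatenate([y, np.zeros(k)])
        sol, *_ = np.linalg.lstsq(G_aug, y_aug, rcond=None)
    else:
        G_aug, y_aug = G, y
    if lo is not None and (np.any(sol < lo) or np.any(sol > hi)):
        from scipy.optimize import lsq_linear

        sol = lsq_linear(G_aug, y_aug, bounds=(lo, hi)).x
    return sol


@dataclass
class LinLogFit:
    """Result of a per-reaction lin-log regression."""

    elasticities: dict[str, float]
    residual_rms: float
    n_states: int
    unidentifiable: list[str] = field(default_factory=list)


def linlog_elasticities(
    states: list[SteadyState],
    reference: SteadyState,
    reaction: str,
    regressor_mets: list[str],
    min_variation: float = 1e-12,
    sign_bounds: dict[str, tuple[float, float]] | None = None,
    allow_underdetermined: bool = False,
    offset_terms: list[tuple[str, float]] | None = None,
) -> LinLogFit:
    """Least-squares lin-log elasticities of one reaction.

    Rows are built from every non-reference state: response
    (v/v0)*(e0/e) - 1, regressors ln(X_i/X_i0) over ``regressor_mets``.
    Metabolites that do not vary across the states are flagged
    unidentifiable and dropped; a rank-deficient system among the remaining
    regressors is an error naming the collinear metabolites.

    ``sign_bounds`` constrains individual coefficients (e.g. substrates of
    the net direction >= 0, inhibiting effectors <= 0); near-collinear noisy
    designs otherwise produce wildly compensating estimates. ``offset_terms``
    are known (metabolite, elasticity) contributions — e.g. the thermodynamic
    product sensitivities of a far-from-equilibrium reaction — subtracted
    from the response before the kinetic part is regressed.
    """
    j = reference.reaction_ids.index(reaction)
    v0 = reference.v0[j]
    if v0 == 0:
        raise ValidationError(f"reference flux of {reaction} is zero")
    used = [s for s in states if not s.is_reference]
    rows, resp = [], []
    for s in used:
        ratio = (s.v0[j] / v0) * (reference.e0[j] / s.e0[j])
        y_val = ratio - 1.0
        for mid, coeff in offset_terms or ():
            y_val -= coeff * np.log(
                s.X0[s.metabolite_ids.index(mid)]
                / reference.X0[reference.metabolite_ids.index(mid)]
            )
        resp.append(y_val)
        rows.append([
            np.log(s.X0[s.metabolite_ids.index(m)]
                   / reference.X0[reference.metabolite_ids.index(m)])
            for m in regressor_mets
        ])
    G = np.array(rows, dtype=float)
    y = np.array(resp, dtype=float)
    if G.size == 0:
        raise ValidationError(f"no regressors for reaction {reaction}")
    span = np.abs(G).max(axis=0) if len(G) else np.zeros(len(regressor_mets))
    unident = [m for m, s in zip(regressor_mets, span) if s < min_variation]
    keep = [k for k, m in enumerate(regressor_mets) if m not in unident]
    est = {m: np.nan for m in unident}
    residual = float(np.sqrt(np.mean(y ** 2)))
    if keep:
        Gk = G[:, keep]
        rank = np.linalg.matrix_rank(Gk, tol=1e-9 * max(np.abs(Gk).max(), 1.0))
        if rank < len(keep) or len(used) < len(keep):
            msg = (
                f"reaction {reaction}: regressor matrix rank-deficient "
                f"(rank {rank} < {len(keep)} unknowns over {len(used)} "
                f"states); collinear metabolites among "
                f"{[regressor_mets[k] for k in keep]}"
            )
            if not allow_underdetermined:
                raise ValidationError(msg)
            warnings.warn(msg + "; returning the regularised minimum-norm fit")
        lo = hi = None
        if sign_bounds:
            lo = np.array([sign_bounds.get(regressor_mets[k],
                                           (-np.inf, np.inf))[0]
                           for k in keep])
            hi = np.array([sign_bounds.get(regressor_mets[k],
                                           (-np.inf, np.inf))[1]
                           for k in keep])
        sol = _ridged_bounded_lstsq(Gk, y, lo, hi)
        for k, c in zip(keep, sol):
            est[regressor_mets[k]] = float(c)
        residual = float(np.sqrt(np.mean((Gk @ sol - y) ** 2)))
    return LinLogFit(
        elasticities=est,
        residual_rms=residual,
        n_states=len(used),
        unidentifiable=unident,
    )


def default_regressors(
    net: MetabolicNetwork,
    rxn_id: str,
    effectors: EffectorMap | None,
    far_from_equilibrium: bool,
    v_ref_sign: float = 1.0,
    measured_only: bool = True,
) -> list[str]:
    """Regressor metabolites of a reaction's lin-log row.

    Near-equilibrium: all participating (measured) metabolites. Far from
    equilibrium: substrates of the net direction plus effectors — products
    are treated as saturating.
    """
    rxn = net.reaction(rxn_id)
    mets = []
    for mid, n_ij in rxn.stoich.items():
        if far_from_equilibrium and v_ref_sign * n_ij >= 0:
            continue
        if measured_only and not net.metabolite(mid).measured:
            continue
        mets.append(mid)
    if effectors is not None:
        for mid, _ in effectors.for_reaction(rxn_id):
            if mid not in mets:
                mets.append(mid)
    return mets


def regressor_sign_bounds(
    net: MetabolicNetwork,
    rxn_id: str,
    effectors: EffectorMap | None,
    mets: list[str],
    v_ref_sign: float = 1.0,
    drg: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Admissible bounds for regression coefficients.

    The total elasticity splits into a kinetic part (non-negative toward
    substrates of the net direction, non-positive toward products) and the
    thermodynamic part n_ij R T / deltarG'. With the reaction energy known,
    the thermodynamic part therefore bounds the coefficient from the inside:
    substrates satisfy eps >= n RT/deltarG' (> 0), products
    eps <= n RT/deltarG' (< 0). Activators are non-negative, inhibitors
    non-positive.
    """
    rxn = net.reaction(rxn_id)
    roles = dict(effectors.for_reaction(rxn_id)) if effectors else {}
    out: dict[str, tuple[float, float]] = {}
    for mid in mets:
        n_ij = rxn.stoich.get(mid)
        if n_ij is not None:
            floor = (thermokinetic_elasticity(n_ij, drg, net.temperature)
                     if drg else 0.0)
            if v_ref_sign * n_ij < 0:
                out[mid] = (max(floor, 0.0), np.inf)
            else:
                out[mid] = (-np.inf, min(floor, 0.0))
        elif mid in roles:
            out[mid] = ((0.0, np.inf) if roles[mid] == "activator"
                        else (-np.inf, 0.0))
    return out


def far_product_terms(
    net: MetabolicNetwork,
    rxn_id: str,
    drg: float,
    v_ref_sign: float,
    reference: SteadyState | None = None,
    covered: set[str] | None = None,
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Thermodynamic sensitivities of a far-from-equilibrium reaction's
    participants that the kinetic regression does not cover.

    Kinetically the products saturate and unmeasured substrates cannot be
    regressed, but the net rate keeps the thermodynamic sensitivity
    n_ij R T / deltarG' toward every participant; it serves as the baseline
    for all participants outside ``covered``. Returns (all_terms,
    measured_terms); the measured terms can be subtracted from a regression
    response, the rest only enter the elasticity matrix.
    """
    rxn = net.reaction(rxn_id)
    covered = covered or set()
    all_terms, measured_terms = [], []
    for mid, n_ij in rxn.stoich.items():
        if mid in covered:
            continue
        coeff = thermokinetic_elasticity(n_ij, drg, net.temperature)
        all_terms.append((mid, coeff))
        if net.metabolite(mid).measured and (
            reference is None or mid in reference.metabolite_ids
        ):
            measured_terms.append((mid, coeff))
    return all_terms, measured_terms


def linlog_elasticity_matrix(
    net: MetabolicNetwork,
    states: list[SteadyState],
    reference: SteadyState,
    effectors: EffectorMap | None = None,
    classification: dict[str, str] | None = None,
    skip_reactions: set[str] | None = None,
    drg_values: dict[str, float] | None = None,
) -> ElasticityMatrix:
    """Full regression-based elasticity matrix (every reaction via lin-log).

    ``classification`` maps reaction id -> "near"/"far" and controls each
    row's regressor support (defaults to "far" when absent); reactions in
    ``skip_reactions`` (e.g. feed-limited supplies) keep zero rows. For far
    rows with a known reaction energy (``drg_values``), the thermodynamic
    product sensitivities are filled in and subtracted from the response
    before the kinetic part is regressed.
    """
    n, m = len(net.reactions), len(net.metabolites)
    values = np.zeros((n, m))
    prov = np.full((n, m), "zero", dtype=object)
    skip = skip_reactions or set()
    for j, rxn in enumerate(net.reactions):
        if rxn.id in skip:
            continue
        v0 = reference.v0[reference.reaction_ids.index(rxn.id)]
        if v0 == 0:
            continue
        far = (classification or {}).get(rxn.id, "far") == "far"
        regr = default_regressors(net, rxn.id, effectors, far,
                                  v_ref_sign=np.sign(v0))
        offsets: list[tuple[str, float]] = []
        if far and drg_values and rxn.id in drg_values:
            all_terms, offsets = far_product_terms(
                net, rxn.id, drg_values[rxn.id], np.sign(v0), reference,
                covered=set(regr))
            for mid, coeff in all_terms:
                values[j, net.met_idx(mid)] = coeff
                prov[j, net.met_idx(mid)] = "thermokinetic"
        if not regr:
            if any(np.sign(v0) * n < 0 for n in rxn.stoich.values()):
                warnings.warn(
                    f"reaction {rxn.id}: no measured participants or effectors; "
                    "elasticity row left zero"
                )
            continue
        fit = linlog_elasticities(
            states, reference, rxn.id, regr,
            sign_bounds=regressor_sign_bounds(
                net, rxn.id, effectors, regr, np.sign(v0),
                drg=(drg_values or {}).get(rxn.id) if far else None),
            offset_terms=offsets,
        )
        for mid, val in fit.elasticities.items():
            if np.isfinite(val):
                i = net.met_idx(mid)
                values[j, i] = val
                prov[j, i] = "linlog"
    return ElasticityMatrix(
        values=values, provenance=prov,
        reaction_ids=net.reaction_ids, metabolite_ids=net.metabolite_ids,
        reference_state_id=reference.id,
    )


def assemble_elasticity_matrix(
    net: MetabolicNetwork,
    drg_ranges: dict[str, tuple[float, float]],
    states: list[SteadyState],
    reference: SteadyState,
    effectors: EffectorMap | None = None,
    threshold: float = NEAR_EQUILIBRIUM_THRESHOLD,
    drg_values: dict[str, float] | None = None,
    skip_reactions: set[str] | None = None,
) -> ElasticityMatrix:
    """Mixed thermokinetic / lin-log elasticity matrix.

    Near-equilibrium rows (feasible deltarG' range reaching above
    ``-threshold``) are filled from the thermokinetic formula at the range
    midpoint (or at ``drg_values`` when given, e.g. Monte Carlo draws);
    far-from-equilibrium rows by lin-log regression over substrates and
    effectors. Reactions without a deltarG' range are treated as far;
    ``skip_reactions`` (feed-limited supplies) keep zero rows.
    """
    from .tfa import classify_equilibrium

    classification = classify_equilibrium(drg_ranges, threshold)
    n, m = len(net.reactions), len(net.metabolites)
    values = np.zeros((n, m))
    prov = np.full((n, m), "zero", dtype=object)
    skip = skip_reactions or set()
    for j, rxn in enumerate(net.reactions):
        if rxn.id in skip:
            continue
        v0 = reference.v0[reference.reaction_ids.index(rxn.id)]
        label = classification.get(rxn.id)
        if label == "near":
            if drg_values and rxn.id in drg_values:
                drg = drg_values[rxn.id]
            else:
                lo, hi = drg_ranges[rxn.id]
                drg = 0.5 * (lo + hi)
            if drg == 0:
                warnings.warn(
                    f"reaction {rxn.id}: midpoint deltarG' is zero, row left zero"
                )
                continue
            for mid, n_ij in rxn.stoich.items():
                i = net.met_idx(mid)
                values[j, i] = thermokinetic_elasticity(n_ij, drg, net.temperature)
                prov[j, i] = "thermokinetic"
        else:
            if v0 == 0:
                continue
            regr = default_regressors(net, rxn.id, effectors, True,
                                      v_ref_sign=np.sign(v0))
            offsets: list[tuple[str, float]] = []
            drg = None
            if drg_values and rxn.id in drg_values:
                drg = drg_values[rxn.id]
            elif rxn.id in drg_ranges:
                lo, hi = drg_ranges[rxn.id]
                drg = 0.5 * (lo + hi)
            if drg:
                all_terms, offsets = far_product_terms(
                    net, rxn.id, drg, np.sign(v0), reference,
                    covered=set(regr))
                for mid, coeff in all_terms:
                    values[j, net.met_idx(mid)] = coeff
                    prov[j, net.met_idx(mid)] = "thermokinetic"
            if not regr:
                if any(np.sign(v0) * n < 0 for n in rxn.stoich.values()):
                    warnings.warn(
                        f"reaction {rxn.id}: far from equilibrium with no "
                        "measured participants or effectors; row left zero"
                    )
                continue
            fit = linlog_elasticities(
                states, reference, rxn.id, regr,
                sign_bounds=regressor_sign_bounds(net, rxn.id, effectors,
                                                  regr, np.sign(v0),
                                                  drg=drg),
                allow_underdetermined=True,
                offset_terms=offsets,
            )
            for mid, val in fit.elasticities.items():
                if np.isfinite(val):
                    i = net.met_idx(mid)
                    values[j, i] = val
                    prov[j, i] = "linlog"
    return ElasticityMatrix(
        values=values, provenance=prov,
        reaction_ids=net.reaction_ids, metabolite_ids=net.metabolite_ids,
        reference_state_id=reference.id,
    )


def write_elasticities(E: ElasticityMatrix, path) -> None:
    """TSV of nonzero elasticities with provenance."""
    import pandas as pd

    rows = []
    for j, rid in enumerate(E.reaction_ids):
        for i, mid in enumerate(E.metabolite_ids):
            if E.values[j, i] != 0.0:
                rows.append({
                    "reaction": rid, "metabolite": mid,
                    "elasticity": E.values[j, i],
                    "provenance": E.provenance[j, i],
                })
    pd.DataFrame(rows, columns=["reaction", "metabolite", "elasticity",
                                "provenance"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")
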
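"""Synthetic perturbation datasets with known ground truth.

The study design being emulated: a reference fed-batch L-tryptophan
production state plus four parallel perturbation regimes (glycerol; glucose;
glycerol+shikimate; glucose+shikimate), each run at three substrate feeding
levels — 13 metabolic steady states in total. Cells are modelled with
lin-log kinetics around the reference state:

    v_j = e_j * v_j^* * (1 + sum_i eps*_ij ln(X_i / X_i^*))

with fixed-rate supply steps for the fed substrates (uptake is feed-limited,
so the supplied rate, not a rate law, sets the flux). Reactions operating
near thermodynamic equilibrium carry thermokinetic true elasticities derived
from their reference driving force; far-from-equilibrium reactions are
treated as saturated in their products (substrate and effector elasticities
only), which is also what makes the rate laws identifiable from the
perturbation design. Multiplicative log-normal measurement noise is applied
to rates and concentrations. The true flux control coefficients of every
generated model are available by brute-force enzyme perturbation (central
finite differences), which serves as the oracle for the analysis pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

from .constants import RT_DEFAULT
from .errors import SteadyStateError, ValidationError
from .mca import SteadyState
from .model_core import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    decompose,
    load_default_network,
    stoichiometric_matrix,
)

# ---------------------------------------------------------------------------
# Kinetic model
# ---------------------------------------------------------------------------


@dataclass
class KineticModel:
    """Lin-log kinetic model around a reference steady state.

    ``elasticities`` holds the true scaled elasticities eps*_ij
    (reactions x metabolites, aligned with the network ordering);
    ``supply_rates`` maps fixed-rate (feed-limited) reactions to their
    reference rates; those reactions ignore their elasticity row.
    ``boundary`` metabolites have clamped concentrations and are excluded
    from the balance equations.
    """

    network: MetabolicNetwork
    v_ref: np.ndarray
    x_ref: np.ndarray
    elasticities: np.ndarray
    supply_rates: dict[str, float]
    boundary: set[str] = field(default_factory=set)
    drg_ref: dict[str, float] = field(default_factory=dict)
    mirror_exchanges: dict[str, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        self.v_ref = np.asarray(self.v_ref, dtype=float)
        self.x_ref = np.asarray(self.x_ref, dtype=float)
        if np.any(self.x_ref <= 0):
            raise ValidationError("reference concentrations must be positive")
        net = self.network
        self.balanced_idx = np.array(
            [i for i, m in enumerate(net.metabolites) if m.id not in self.boundary],
            dtype=int,
        )
        self.supply_idx = np.array(
            [net.rxn_idx(r) for r in self.supply_rates], dtype=int
        )
        self._N = stoichiometric_matrix(net)
        self._N_bal = self._N[self.balanced_idx]
        # left-null vectors of the balanced stoichiometry define conserved pools
        dec = decompose(self._N_bal) if np.any(self._N_bal) else None
        self._pools = []
        if dec is not None and len(dec.dependent_idx):
            for k, d in enumerate(dec.dependent_idx):
                w = np.zeros(len(self.balanced_idx))
                w[d] = 1.0
                w[dec.independent_idx] -= dec.conservation_basis[k]
                self._pools.append(w)
        self._NR_bal = dec.NR if dec is not None else self._N_bal

    @property
    def n_reactions(self) -> int:
        return len(self.network.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.network.metabolites)

    def rates(self, x: np.ndarray, e: np.ndarray,
              supply: dict[str, float] | None = None) -> np.ndarray:
        """Reaction rates at concentrations x (mM) and enzyme levels e."""
        y = np.log(x / self.x_ref)
        v = e * self.v_ref * (1.0 + self.elasticities @ y)
        for rid, base in self.supply_rates.items():
            j = self.network.rxn_idx(rid)
            rate = supply.get(rid, base) if supply else base
            v[j] = e[j] * rate
        # mirror exchanges track the implied production/consumption of their
        # freely exchanged boundary species (respiration, nitrogen uptake)
        for rid, mid in self.mirror_exchanges.items():
            j = self.network.rxn_idx(rid)
            i = self.network.met_idx(mid)
            row = self._N[i]
            n_j = row[j]
            v[j] = -(row @ v - n_j * v[j]) / n_j
        return v

    def near_equilibrium(self, threshold: float = 10.0) -> list[str]:
        """Reactions whose reference |deltarG'| is below the threshold."""
        return [r for r, g in self.drg_ref.items() if abs(g) < threshold]

    def steady_state_residual(self, state: SteadyState) -> float:
        return float(np.abs(self._N_bal @ state.v0).max())


# ---------------------------------------------------------------------------
# Perturbation design
# ---------------------------------------------------------------------------


@dataclass
class PerturbationDesign:
    """Substrate regimes x feeding levels (+ reference) of the experiment."""

    regimes: list[str] = field(default_factory=lambda: [
        "glycerol", "glucose", "glycerol+shikimate", "glucose+shikimate",
    ])
    levels_per_regime: int = 3
    include_reference: bool = True
    supply_multipliers: tuple[float, ...] = (0.77, 1.15, 1.65)

    def __post_init__(self) -> None:
        if len(self.supply_multipliers) != self.levels_per_regime:
            raise ValidationError(
                "supply_multipliers length must equal levels_per_regime"
            )

    @property
    def n_states(self) -> int:
        return len(self.regimes) * self.levels_per_regime + int(self.include_reference)


@dataclass
class SyntheticDataset:
    """Generated steady states with noise and attached ground truth."""

    states: list[SteadyState]
    noise_cv: float
    seed: int
    model: KineticModel
    true_fcc: np.ndarray
    design: PerturbationDesign

    @property
    def reference(self) -> SteadyState:
        return next(s for s in self.states if s.is_reference)

    @property
    def perturbed(self) -> list[SteadyState]:
        return [s for s in self.states if not s.is_reference]


# ---------------------------------------------------------------------------
# Reference flux distribution (shared with model curation)
# ---------------------------------------------------------------------------

def reference_flux_distribution(
    net: MetabolicNetwork,
    pinned: dict[str, float],
    balanced: list[str] | None = None,
) -> np.ndarray:
    """An L1-minimal steady flux distribution with pinned measured rates.

    Solves min ||v||_1 subject to N v = 0 (over ``balanced`` metabolites, all
    by default), reaction bounds, and v_j = value for pinned reactions.
    Deterministic (HiGHS).
    """
    N = stoichiometric_matrix(net)
    if balanced is not None:
        rows = [net.met_idx(m) for m in balanced]
        N = N[rows]
    n = len(net.reactions)
    # variables: v (n), t (n) with t >= |v|
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([N, np.zeros_like(N)])
    b_eq = np.zeros(N.shape[0])
    A_ub = np.block([
        [np.eye(n), -np.eye(n)],
        [-np.eye(n), -np.eye(n)],
    ])
    b_ub = np.zeros(2 * n)
    bounds = []
    for r in net.reactions:
        if r.id in pinned:
            val = pinned[r.id]
            bounds.append((val, val))
        else:
            bounds.append((r.flux_lb, r.flux_ub))
    bounds += [(0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:
        raise SteadyStateError(
            f"no steady reference flux distribution: {res.message}"
        )
    return res.x[:n]


# ---------------------------------------------------------------------------
# Preset construction
# ---------------------------------------------------------------------------

def _toy_network(mets, rxns) -> MetabolicNetwork:
    metabolites = [
        Metabolite(id=m, name=m, measured=True, conc_ref=c,
                   conc_lb=1e-4, conc_ub=50.0)
        for m, c in mets
    ]
    reactions = []
    for rid, stoich, tag, rev in rxns:
        reactions.append(Reaction(
            id=rid, stoich=stoich, reversible=rev, pathway_tag=tag,
            flux_lb=-100.0 if rev else 0.0, flux_ub=100.0,
        ))
    net = MetabolicNetwork(metabolites=metabolites, reactions=reactions)
    net.validate()
    return net


def _assign_drg0(net: MetabolicNetwork, model: KineticModel,
                 targets: dict[str, float]) -> None:
    """Back out drg0 so that the reference concentrations give the target
    reaction-energy magnitudes, with sign opposing the reference flux."""
    lnx = np.log(model.x_ref * 1e-3)  # mM -> M
    N = stoichiometric_matrix(net)
    for rid, mag in targets.items():
        j = net.rxn_idx(rid)
        sign = -1.0 if model.v_ref[j] >= 0 else 1.0
        drg_ref = sign * abs(mag)
        net.reactions[j].drg0 = float(drg_ref - RT_DEFAULT * (N[:, j] @ lnx))
        model.drg_ref[rid] = drg_ref


def _thermokinetic_rows(net, model, near_ids):
    """True elasticities of near-equilibrium reactions follow from their
    reference driving force (thermodynamic control of the net rate)."""
    for rid in near_ids:
        j = net.rxn_idx(rid)
        drg = model.drg_ref[rid]
        for mid, n_ij in net.reactions[j].stoich.items():
            i = net.met_idx(mid)
            model.elasticities[j, i] = n_ij * RT_DEFAULT / drg


def _random_far_rows(net, model, far_ids, effectors, rng):
    """Substrate and effector elasticities of far-from-equilibrium reactions.

    Substrates of the net direction carry kinetic elasticities (drawn once);
    products are kinetically saturating, but retain the thermodynamic part of
    the sensitivity, n_ij RT / deltarG' — small far from equilibrium yet
    nonzero, which also pins the absolute levels of pools that
    near-equilibrium spans only constrain relatively.
    """
    for rid in far_ids:
        j = net.rxn_idx(rid)
        sign = 1.0 if model.v_ref[j] >= 0 else -1.0
        drg_ref = model.drg_ref.get(rid)
        for mid, n_ij in net.reactions[j].stoich.items():
            i = net.met_idx(mid)
            if mid in model.boundary:
                continue
            if sign * n_ij < 0:
                model.elasticities[j, i] = rng.uniform(0.4, 1.0) * sign
            elif drg_ref:
                model.elasticities[j, i] = n_ij * RT_DEFAULT / drg_ref
    for rid, effs in (effectors or {}).items():
        j = net.rxn_idx(rid)
        for mid, role in effs:
            i = net.met_idx(mid)
            mag = rng.uniform(0.3, 0.6)
            model.elasticities[j, i] = mag if role == "activator" else -mag


def _thermo_product_rows(net, model, far_ids):
    """Thermodynamic product sensitivities (n_ij RT / deltarG') of
    far-from-equilibrium reactions — the part of the rate response that
    survives kinetic product saturation."""
    for rid in far_ids:
        j = net.rxn_idx(rid)
        sign = 1.0 if model.v_ref[j] >= 0 else -1.0
        drg_ref = model.drg_ref.get(rid)
        if not drg_ref:
            continue
        for mid, n_ij in net.reactions[j].stoich.items():
            if sign * n_ij > 0 and mid not in model.boundary:
                i = net.met_idx(mid)
                model.elasticities[j, i] = n_ij * RT_DEFAULT / drg_ref


def _build_linear2() -> KineticModel:
    """Two-enzyme chain S -> X -> P with boundary S, P; eps1,X=-1, eps2,X=+1."""
    net = _toy_network(
        mets=[("S", 1.0), ("X", 1.0), ("P", 1.0)],
        rxns=[
            ("r1", {"S": -1, "X": 1}, "GLYC&GLYK", False),
            ("r2", {"X": -1, "P": 1}, "biomass", False),
        ],
    )
    model = KineticModel(
        network=net,
        v_ref=np.array([1.0, 1.0]),
        x_ref=np.array([1.0, 1.0, 1.0]),
        elasticities=np.zeros((2, 3)),
        supply_rates={},
        boundary={"S", "P"},
        name="linear2",
    )
    E = model.elasticities
    E[0, net.met_idx("S")] = 1.0
    E[0, net.met_idx("X")] = -1.0
    E[1, net.met_idx("X")] = 1.0
    _assign_drg0(net, model, {"r1": 5.0, "r2": 5.0})
    return model


def _build_linear3() -> KineticModel:
    """Three-enzyme chain; the middle (near-equilibrium) reaction has two
    unknown elasticities, the committed steps sense their substrate only."""
    net = _toy_network(
        mets=[("S", 1.0), ("X1", 1.0), ("X2", 1.0), ("P", 1.0)],
        rxns=[
            ("r1", {"S": -1, "X1": 1}, "GLYC&GLYK", False),
            ("r2", {"X1": -1, "X2": 1}, "GLYC&GLYK", False),
            ("r3", {"X2": -1, "P": 1}, "biomass", False),
        ],
    )
    model = KineticModel(
        network=net,
        v_ref=np.ones(3),
        x_ref=np.ones(4),
        elasticities=np.zeros((3, 4)),
        supply_rates={},
        boundary={"S", "P"},
        name="linear3",
    )
    E = model.elasticities
    E[0, net.met_idx("S")] = 1.0
    E[1, net.met_idx("X1")] = 0.8
    E[1, net.met_idx("X2")] = -0.5
    E[2, net.met_idx("X2")] = 1.0
    _assign_drg0(net, model, {"r1": 12.0, "r2": 8.0, "r3": 15.0})
    _thermo_product_rows(net, model, ["r1", "r3"])
    return model


def _build_branch() -> KineticModel:
    """Branch point: S -> X, X -> P1, X -> P2 (all committed steps)."""
    net = _toy_network(
        mets=[("S", 1.0), ("X", 1.0), ("P1", 1.0), ("P2", 1.0)],
        rxns=[
            ("r1", {"S": -1, "X": 1}, "GLYC&GLYK", False),
            ("r2", {"X": -1, "P1": 1}, "biomass", False),
            ("r3", {"X": -1, "P2": 1}, "L-trp", False),
        ],
    )
    model = KineticModel(
        network=net,
        v_ref=np.array([1.0, 0.6, 0.4]),
        x_ref=np.ones(4),
        elasticities=np.zeros((3, 4)),
        supply_rates={},
        boundary={"S", "P1", "P2"},
        name="branch",
    )
    E = model.elasticities
    E[0, net.met_idx("S")] = 1.0
    E[1, net.met_idx("X")] = 1.0
    E[2, net.met_idx("X")] = 0.7
    _assign_drg0(net, model, {"r1": 12.0, "r2": 15.0, "r3": 15.0})
    _thermo_product_rows(net, model, ["r1", "r2", "r3"])
    return model


def _build_moiety() -> KineticModel:
    """Chain with a conserved cofactor pair (ATP + ADP = const).

    The payoff step regenerates two ATP per X and a maintenance reaction
    dissipates the surplus; this leaves the adenylate sum as the only
    conservation relation, so the cofactor levels still vary independently
    of the pathway intermediate (identifiable from the perturbation data).
    """
    net = _toy_network(
        mets=[("S", 1.0), ("X", 1.0), ("atp", 2.0), ("adp", 0.5), ("P", 1.0)],
        rxns=[
            ("r1", {"S": -1, "atp": -1, "X": 1, "adp": 1}, "GLYC&GLYK", False),
            ("r2", {"X": -1, "adp": -2, "atp": 2, "P": 1}, "biomass", False),
            ("r3", {"atp": -1, "adp": 1}, "GLYC&GLYK", False),
        ],
    )
    model = KineticModel(
        network=net,
        v_ref=np.ones(3),
        x_ref=np.array([1.0, 1.0, 2.0, 0.5, 1.0]),
        elasticities=np.zeros((3, 5)),
        supply_rates={},
        boundary={"S", "P"},
        name="moiety",
    )
    E = model.elasticities
    E[0, net.met_idx("S")] = 1.0
    E[0, net.met_idx("atp")] = 0.6
    E[1, net.met_idx("X")] = 1.0
    E[1, net.met_idx("adp")] = 0.5
    E[2, net.met_idx("atp")] = 0.9
    _assign_drg0(net, model, {"r1": 18.0, "r2": 20.0, "r3": 25.0})
    _thermo_product_rows(net, model, ["r1", "r2", "r3"])
    return model


#: reference supply rates of the trp_toy preset, mmol/gCDW/h; glycerol is the
#: production substrate, glucose and shikimate are trace at the reference.
TOY_SUPPLY_REF = {"upt_glyc": 2.6, "upt_glc": 0.01, "upt_shik": 0.01}

#: per-regime base supply rates as (rate, scaled-by-level?) pairs. Magnitudes
#: follow the printed uptake rates: glycerol 2.0-4.3, glucose 0.7-1.4,
#: shikimate about 0.26 mmol/gCDW/h.
TOY_REGIMES = {
    "glycerol": {"upt_glyc": (2.6, True), "upt_glc": (0.01, False), "upt_shik": (0.01, False)},
    "glucose": {"upt_glyc": (0.05, False), "upt_glc": (0.9, True), "upt_shik": (0.01, False)},
    "glycerol+shikimate": {"upt_glyc": (2.6, True), "upt_glc": (0.01, False), "upt_shik": (0.26, True)},
    "glucose+shikimate": {"upt_glyc": (0.05, False), "upt_glc": (0.9, True), "upt_shik": (0.26, True)},
}

#: reference |deltarG'| targets of the toy reactions, kJ/mol; the three
#: interconversion steps sit near equilibrium, committed steps far from it.
TOY_DRG_TARGETS = {
    "glyc_low": 3.0, "ppp": 2.0, "ser_syn": 4.0,
    "pep_drain": 20.0, "ser_drain": 15.0, "dahps": 40.0, "chor_syn": 30.0,
    "phetyr": 35.0, "ans": 40.0, "anprt": 25.0, "igps_trps": 35.0,
}

#: default effector map: anthranilate feed-forward-inhibits the lumped
#: IGPS / tryptophan-synthase step (known igps regulation).
TOY_EFFECTORS = {"igps_trps": [("anth", "inhibitor")]}

TOY_REFERENCE_PINS = {
    "upt_glyc": 2.6, "upt_glc": 0.01, "upt_shik": 0.01,
    "trp_export": 0.30, "ser_drain": 0.2, "phetyr": 0.01,
}


def _build_trp_toy(seed: int) -> KineticModel:
    """Coarse-grained L-trp production network (15 reactions, 10 metabolites).

    Topology mirrors the real pathway layout: substrate entry into the triose
    pool (glucose also feeding the PPP branch), a lumped PPP supplying E4P and
    PRPP, serine biosynthesis, the chorismate route fed by PEP+E4P with a
    shikimate entry point, and the anthranilate -> L-trp branch with ANTH
    feed-forward inhibition of the lumped IGPS/tryptophan-synthase step.
    """
    mets = [
        ("trio", 0.5), ("pep", 0.4), ("e4p", 0.05), ("prpp", 0.3),
        ("ser", 1.0), ("shik", 0.2), ("chor", 0.1), ("anth", 0.02),
        ("cdrp", 0.05), ("trp", 1.5),
    ]
    rxns = [
        ("upt_glyc", {"trio": 1}, "exchange", False),
        ("upt_glc", {"trio": 1.7, "e4p": 0.15, "prpp": 0.15}, "exchange", False),
        ("upt_shik", {"shik": 1}, "exchange", False),
        ("glyc_low", {"trio": -1, "pep": 1}, "GLYC&GLYK", True),
        ("ppp", {"trio": -1, "e4p": 1, "prpp": 1}, "PPP", True),
        ("pep_drain", {"pep": -1}, "biomass", False),
        ("ser_syn", {"pep": -1, "ser": 1}, "L-ser", True),
        ("ser_drain", {"ser": -1}, "L-ser", False),
        ("dahps", {"pep": -1, "e4p": -1, "shik": 1}, "CHOR", False),
        ("chor_syn", {"shik": -1, "pep": -1, "chor": 1}, "CHOR", False),
        ("phetyr", {"chor": -1}, "L-phe/L-tyr", False),
        ("ans", {"chor": -1, "anth": 1}, "L-trp", False),
        ("anprt", {"anth": -1, "prpp": -1, "cdrp": 1}, "L-trp", False),
        ("igps_trps", {"cdrp": -1, "ser": -1, "trp": 1, "trio": 1}, "L-trp", False),
        ("trp_export", {"trp": -1}, "exchange", False),
    ]
    net = _toy_network(mets, rxns)
    v_ref = reference_flux_distribution(net, TOY_REFERENCE_PINS)
    x_ref = np.array([c for _, c in mets])
    model = KineticModel(
        network=net, v_ref=v_ref, x_ref=x_ref,
        elasticities=np.zeros((len(rxns), len(mets))),
        supply_rates=dict(TOY_SUPPLY_REF),
        boundary=set(),
        name="trp_toy",
    )
    rng = np.random.default_rng(seed)
    _assign_drg0(net, model, TOY_DRG_TARGETS)
    near = [r for r, m in TOY_DRG_TARGETS.items() if m < 10.0]
    far = [r for r, m in TOY_DRG_TARGETS.items() if m >= 10.0]
    _thermokinetic_rows(net, model, near)
    _random_far_rows(net, model, far, TOY_EFFECTORS, rng)
    # the export step responds to its substrate
    model.elasticities[net.rxn_idx("trp_export"), net.met_idx("trp")] = 1.0
    return model


#: reference supply rates of the full curated network, mmol/gCDW/h
FULL_SUPPLY_REF = {"EX_glyc": 2.6, "EX_glc": 0.02, "EX_shik": 0.01}

FULL_REGIMES = {
    "glycerol": {"EX_glyc": (2.6, True), "EX_glc": (0.02, False), "EX_shik": (0.01, False)},
    "glucose": {"EX_glyc": (0.05, False), "EX_glc": (0.9, True), "EX_shik": (0.01, False)},
    "glycerol+shikimate": {"EX_glyc": (2.6, True), "EX_glc": (0.02, False), "EX_shik": (0.26, True)},
    "glucose+shikimate": {"EX_glyc": (0.05, False), "EX_glc": (0.9, True), "EX_shik": (0.26, True)},
}

FULL_EFFECTORS = {"igps": [("anth", "inhibitor")]}

#: supply pairs: the transport (or PTS) step is feed-limited together with
#: its exchange and carries the same rate.
FULL_SUPPLY_PAIRS = {"EX_glyc": "glyct", "EX_glc": "glcpts", "EX_shik": "shikt"}

#: reference rates pinned when solving the reference flux distribution
#: (mmol/gCDW/h; biomass in 1/h); pfk keeps a small futile pairing with the
#: fructose bisphosphatase so every reaction carries flux at the reference.
FULL_REFERENCE_PINS = {
    "EX_glyc": 2.6, "glyct": 2.6, "EX_glc": 0.02, "glcpts": 0.02,
    "EX_shik": 0.01, "shikt": 0.01, "EX_trp": 0.30, "EX_phe": 0.02,
    "biomass": 0.05, "pfk": 0.05,
}

FULL_BOUNDARY = {"co2", "o2", "nh4", "glyc_e", "glc_e", "shik_e"}

#: exchanges that track the net production/consumption of their species
FULL_MIRRORS = {"EX_co2": "co2", "EX_o2": "o2", "EX_nh4": "nh4"}


def close_external_exchanges(net: MetabolicNetwork, v: np.ndarray,
                             mirrors: dict[str, str] | None = None) -> np.ndarray:
    """Set mirror-exchange fluxes so that their boundary species balance."""
    N = stoichiometric_matrix(net)
    v = v.copy()
    for rid, mid in (mirrors or FULL_MIRRORS).items():
        j = net.rxn_idx(rid)
        row = N[net.met_idx(mid)]
        v[j] = -(row @ v - row[j] * v[j]) / row[j]
    return v


def _build_full(seed: int, net: MetabolicNetwork | None = None) -> KineticModel:
    """Lin-log kinetics over the packaged 50-reaction / 57-metabolite network.

    The reference flux distribution reproduces the production process
    (glycerol uptake 2.6, L-trp export 0.30 mmol/gCDW/h, growth 0.05 1/h);
    near-equilibrium reactions carry thermokinetic true elasticities, the
    rest seeded substrate/effector elasticities. Freely exchanged small
    species (CO2, O2, NH4+, extracellular substrates) are boundary.
    """
    if net is None:
        net = load_default_network()
    balanced = [m.id for m in net.metabolites if m.id not in FULL_BOUNDARY]
    v_ref = reference_flux_distribution(net, FULL_REFERENCE_PINS, balanced=balanced)
    v_ref = close_external_exchanges(net, v_ref)
    x_ref = net.reference_concentrations()
    supply = dict(FULL_SUPPLY_REF)
    for ex, pair in FULL_SUPPLY_PAIRS.items():
        supply[pair] = FULL_SUPPLY_REF[ex]
    model = KineticModel(
        network=net, v_ref=v_ref, x_ref=x_ref,
        elasticities=np.zeros((len(net.reactions), len(net.metabolites))),
        supply_rates=supply,
        boundary=set(FULL_BOUNDARY),
        mirror_exchanges=dict(FULL_MIRRORS),
        name="ecoli_trp",
    )
    # reaction energies at the reference follow from the curated drg0
    N = stoichiometric_matrix(net)
    lnx = np.log(x_ref * 1e-3)
    near, far = [], []
    for j, r in enumerate(net.reactions):
        if r.pathway_tag in ("exchange", "biomass") or r.id in supply:
            continue
        drg0 = net.reaction_drg0(r)
        if drg0 is None:
            far.append(r.id)  # flux-only reactions treated as committed steps
            continue
        drg_ref = float(drg0 + RT_DEFAULT * (N[:, j] @ lnx))
        model.drg_ref[r.id] = drg_ref
        (near if abs(drg_ref) < 10.0 else far).append(r.id)
    rng = np.random.default_rng(seed)
    _thermokinetic_rows(net, model, near)
    _random_far_rows(net, model, far, FULL_EFFECTORS, rng)
    # exports, maintenance and the biomass drain respond to their substrates
    for rid in ("EX_trp", "EX_phe", "atpm"):
        j = net.rxn_idx(rid)
        for mid, n_ij in net.reactions[j].stoich.items():
            if n_ij < 0 and mid not in FULL_BOUNDARY:
                model.elasticities[j, net.met_idx(mid)] = 1.0
    j = net.rxn_idx("biomass")
    for mid, n_ij in net.reactions[j].stoich.items():
        if n_ij < 0 and mid not in FULL_BOUNDARY:
            model.elasticities[j, net.met_idx(mid)] = 0.1
    return model


PRESETS = {
    "linear2": lambda seed: _build_linear2(),
    "linear3": lambda seed: _build_linear3(),
    "branch": lambda seed: _build_branch(),
    "moiety": lambda seed: _build_moiety(),
    "trp_toy": _build_trp_toy,
    "ecoli_trp": _build_full,
}


def build_default_kinetic_model(config: str | dict = "trp_toy",
                                seed: int = 1) -> KineticModel:
    """Build a preset kinetic model; deterministic for a given seed.

    ``config`` names a topology preset (``linear2``, ``linear3``, ``branch``,
    ``moiety``, ``trp_toy``, ``ecoli_trp``) or is a dict with a ``preset``
    key. The reference point of every preset is verified to be a steady
    state of the rate laws before the model is returned.
    """
    preset = config.get("preset", "trp_toy") if isinstance(config, dict) else config
    if preset not in PRESETS:
        raise ValidationError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    model = PRESETS[preset](seed)
    resid = np.abs(model._N_bal @ model.v_ref).max() if model._N_bal.size else 0.0
    if resid > 1e-9:
        raise SteadyStateError(
            f"preset {preset}: reference not steady (residual {resid:.2e})"
        )
    return model


# ---------------------------------------------------------------------------
# Steady-state simulation
# ---------------------------------------------------------------------------


def simulate_steady_state(
    model: KineticModel,
    enzyme_levels: np.ndarray | dict[str, float] | None = None,
    supply_multiplier: float | dict[str, float] | None = None,
    supply_override: dict[str, float] | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
    state_id: str = "state",
    conserve_pools: bool | str = True,
) -> SteadyState:
    """Solve the lin-log balances for a perturbed steady state.

    Enzyme levels multiply reaction rates; the supply multiplier scales
    fixed-rate supply reactions and, for presets with a boundary substrate
    ``S``, its clamped concentration. The lin-log balances are linear in the
    log-concentration deviations and solved exactly; conserved-pool totals
    are then enforced by a damped Newton (Powell hybrid) iteration in the
    null space of the balances, started from the reference point.

    ``conserve_pools=False`` treats the state as an independent culture whose
    cofactor totals are free (minimum-norm log-deviation solution);
    ``"auto"`` conserves the reference totals when a solution exists and
    falls back to the free-pool solution otherwise — large cross-regime
    shifts can make the reference culture's totals unattainable.
    """
    net = model.network
    n = model.n_reactions
    e = np.ones(n)
    if enzyme_levels is not None:
        if isinstance(enzyme_levels, dict):
            for rid, lvl in enzyme_levels.items():
                e[net.rxn_idx(rid)] = lvl
        else:
            e = np.asarray(enzyme_levels, dtype=float).copy()
    if np.any(e < 0):
        raise ValidationError("enzyme levels must be >= 0")

    supply = dict(model.supply_rates)
    x_boundary = model.x_ref.copy()
    if supply_multiplier is not None:
        if isinstance(supply_multiplier, dict):
            for rid, mult in supply_multiplier.items():
                supply[rid] = model.supply_rates[rid] * mult
        else:
            for rid in supply:
                supply[rid] *= supply_multiplier
            if "S" in model.boundary:
                x_boundary[net.met_idx("S")] *= supply_multiplier
    if supply_override:
        for rid, rate in supply_override.items():
            supply[rid] = rate

    bal = model.balanced_idx
    pools = model._pools
    NR = model._NR_bal
    x_ref_bal = model.x_ref[bal]
    scale = max(np.abs(model.v_ref).max(), 1.0)

    def full_x(y_bal: np.ndarray) -> np.ndarray:
        x = x_boundary.copy()
        x[bal] = x_ref_bal * np.exp(y_bal)
        return x

    # the lin-log balances are linear in the log-deviations y:
    #   NR diag(e v*) E y = -NR v(y=0)
    dvdy = (e * model.v_ref)[:, None] * model.elasticities[:, bal]
    if len(model.supply_idx):
        dvdy[model.supply_idx] = 0.0
    A = NR @ dvdy
    c = NR @ model.rates(full_x(np.zeros(len(bal))), e, supply)
    y_p, *_ = np.linalg.lstsq(A, -c, rcond=None)
    lin_resid = np.linalg.norm(A @ y_p + c)
    if lin_resid > tol ** 0.5 * scale:
        raise SteadyStateError(
            f"no steady state: flux balances inconsistent "
            f"(residual {lin_resid:.3e}, min enzyme level {e.min():.3g})"
        )
    from scipy.linalg import null_space

    B = null_space(A, rcond=1e-12)
    y = y_p
    if B.shape[1] and pools and conserve_pools:
        # conserved-pool constraints within the null space of the linear
        # balances (dimension = number of pools); Powell-hybrid damped
        # Newton, deterministic start at the reference point
        from scipy.optimize import root as _root

        W = np.array(pools)
        target = W @ x_ref_bal
        gscale = max(np.abs(target).max(), 1.0)

        def g(t: np.ndarray) -> np.ndarray:
            with np.errstate(over="ignore", invalid="ignore"):
                vals = W @ (x_ref_bal * np.exp(y_p + B @ t)) - target
            return np.where(np.isfinite(vals), vals, 1e30)

        sol = _root(g, np.zeros(B.shape[1]), method="hybr")
        if not sol.success or np.abs(sol.fun).max() > 1e-8 * gscale:
            sol = _root(g, np.zeros(B.shape[1]), method="lm")
        if not sol.success or np.abs(sol.fun).max() > 1e-8 * gscale:
            if conserve_pools == "auto":
                warnings.warn(
                    f"state {state_id}: reference pool totals unattainable; "
                    "treating it as an independent culture (free pools)"
                )
            else:
                raise SteadyStateError(
                    "no steady state: conserved-pool equations unsolved "
                    f"(residual {np.abs(sol.fun).max():.3e})"
                )
        else:
            y = y_p + B @ sol.x
    x = full_x(y)
    v = model.rates(x, e, supply)
    final = np.abs(NR @ v).max() if NR.size else 0.0
    if final > 1e-8 * scale:
        raise SteadyStateError(
            f"no steady state: final residual {final:.3e}"
        )
    return SteadyState(
        id=state_id,
        reaction_ids=net.reaction_ids,
        metabolite_ids=net.metabolite_ids,
        v0=v, X0=x, e0=e,
    )


# ---------------------------------------------------------------------------
# Dataset generation and the finite-difference oracle
# ---------------------------------------------------------------------------

def _regime_supplies(model: KineticModel, regime: str, mult: float) -> dict[str, float]:
    table = TOY_REGIMES if model.name == "trp_toy" else FULL_REGIMES
    if regime not in table:
        raise ValidationError(f"unknown regime {regime!r} for preset {model.name}")
    out = {}
    for rid, (base, scaled) in table[regime].items():
        rate = base * mult if scaled else base
        out[rid] = rate
        pair = FULL_SUPPLY_PAIRS.get(rid)
        if pair and pair in model.supply_rates:
            out[pair] = rate
    return out


def _apply_noise(state: SteadyState, cv: float, rng: np.random.Generator) -> SteadyState:
    """Mean-preserving multiplicative log-normal noise on rates and
    concentrations."""
    if cv == 0:
        return state
    sigma = np.sqrt(np.log1p(cv ** 2))
    fac_v = np.exp(sigma * rng.standard_normal(len(state.v0)) - sigma ** 2 / 2)
    fac_x = np.exp(sigma * rng.standard_normal(len(state.X0)) - sigma ** 2 / 2)
    return SteadyState(
        id=state.id,
        reaction_ids=state.reaction_ids,
        metabolite_ids=state.metabolite_ids,
        v0=state.v0 * fac_v,
        X0=state.X0 * fac_x,
        e0=state.e0.copy(),
        is_reference=state.is_reference,
    )


def generate_perturbation_dataset(
    model: KineticModel,
    design: PerturbationDesign | None = None,
    noise_cv: float = 0.1,
    seed: int = 1,
) -> SyntheticDataset:
    """Simulate the full perturbation experiment (default 4x3 + reference).

    Presets with named supplies follow the substrate-regime tables; the small
    auxiliary topologies have a single boundary substrate, so each regime
    additionally perturbs one enzyme (a standard modulation experiment) to
    keep the design informative.
    """
    if design is None:
        design = PerturbationDesign()
    rng = np.random.default_rng(seed)
    states: list[SteadyState] = []
    if design.include_reference:
        ref = simulate_steady_state(model, state_id="reference")
        ref.is_reference = True
        states.append(_apply_noise(ref, noise_cv, rng))
    for k, regime in enumerate(design.regimes):
        for lvl, mult in enumerate(design.supply_multipliers, start=1):
            sid = f"{regime}:{lvl}"
            if model.supply_rates:
                supplies = _regime_supplies(model, regime, mult)
                st = simulate_steady_state(
                    model, supply_override=supplies, state_id=sid,
                    conserve_pools="auto",
                )
            else:
                e = np.ones(model.n_reactions)
                e[k % model.n_reactions] = mult
                st = simulate_steady_state(
                    model, enzyme_levels=e, supply_multiplier=mult,
                    state_id=sid, conserve_pools="auto",
                )
            states.append(_apply_noise(st, noise_cv, rng))
    true_fcc = true_fcc_finite_difference(model)
    return SyntheticDataset(
        states=states, noise_cv=noise_cv, seed=seed, model=model,
        true_fcc=true_fcc, design=design,
    )


def true_fcc_finite_difference(model: KineticModel, delta: float = 0.01) -> np.ndarray:
    """Ground-truth FCC matrix by brute-force enzyme perturbation.

    C[j, i] = (e_j / v_i) dv_i/de_j, via central differences with relative
    enzyme change ``delta`` (default the 1% definition scale). Returned as
    enzymes x fluxes; per-flux sums over enzymes approach 1 as delta -> 0
    (summation theorem).
    """
    if not (0 < delta <= 0.05):
        raise ValidationError("delta must be in (0, 0.05]")
    n = model.n_reactions
    base = simulate_steady_state(model)
    C = np.zeros((n, n))
    for j in range(n):
        e_hi = np.ones(n)
        e_hi[j] = 1 + delta
        e_lo = np.ones(n)
        e_lo[j] = 1 - delta
        hi = simulate_steady_state(model, enzyme_levels=e_hi)
        lo = simulate_steady_state(model, enzyme_levels=e_lo)
        C[j] = (hi.v0 - lo.v0) / (2 * delta * base.v0)
    return C


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write rates.tsv (state x reaction), metabolome.tsv (state x measured
    metabolite, mM) and truth.json to ``outdir``."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = dataset.model.network
    state_ids = [s.id for s in dataset.states]
    rates = pd.DataFrame(
        [s.v0 for s in dataset.states], index=state_ids, columns=net.reaction_ids
    )
    measured = [m.id for m in net.metabolites if m.measured]
    midx = [net.met_idx(m) for m in measured]
    metab = pd.DataFrame(
        [s.X0[midx] for s in dataset.states], index=state_ids, columns=measured
    )
    rates_path = outdir / "rates.tsv"
    metab_path = outdir / "metabolome.tsv"
    truth_path = outdir / "truth.json"
    rates.to_csv(rates_path, sep="\t", float_format="%.10g", index_label="state")
    metab.to_csv(metab_path, sep="\t", float_format="%.10g", index_label="state")
    truth = {
        "preset": dataset.model.name,
        "seed": dataset.seed,
        "noise_cv": dataset.noise_cv,
        "reaction_ids": net.reaction_ids,
        "true_fcc_enzymes_by_fluxes": dataset.true_fcc.tolist(),
        "true_elasticities": dataset.model.elasticities.tolist(),
        "v_ref": dataset.model.v_ref.tolist(),
        "x_ref_mM": dataset.model.x_ref.tolist(),
    }
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
        fh.write("\n")
    return {"rates": rates_path, "metabolome": metab_path, "truth": truth_path}
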
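"""Reduced metabolic network: representation, I/O and structural decomposition.

The central object is :class:`MetabolicNetwork`, a stoichiometric model of
E. coli central carbon metabolism plus the aromatic-amino-acid pathway with
thermodynamic annotations (transformed standard Gibbs energies of reaction,
concentration bounds). The packaged default network has 50 non-exchange
reactions and 57 metabolites, covering glycolysis/glycerol metabolism, the
TCA cycle, the pentose-phosphate pathway, L-serine biosynthesis and the
chorismate / L-phe / L-tyr / L-trp branches.

Structural decomposition separates independent from dependent (conserved-
moiety) metabolites and yields the reduced stoichiometric matrix N_R used by
the control-analysis linearisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import SchemaError, ValidationError

PATHWAY_TAGS = {
    "GLYC&GLYK",
    "TCA",
    "PPP",
    "L-ser",
    "CHOR",
    "L-phe/L-tyr",
    "L-trp",
    "exchange",
    "biomass",
}

#: Default concentration bounds for unmeasured metabolites, mM
DEFAULT_CONC_LB = 1e-4
DEFAULT_CONC_UB = 50.0


@dataclass
class Metabolite:
    """One chemical species.

    Concentrations are in mM and must be strictly positive so that
    log-concentrations exist. ``dfg0`` is the transformed standard Gibbs
    energy of formation (kJ/mol) and may be ``None`` when reaction-level
    energies are supplied directly.
    """

    id: str
    name: str = ""
    measured: bool = False
    conc_lb: float = DEFAULT_CONC_LB
    conc_ub: float = DEFAULT_CONC_UB
    conc_ref: float | None = None
    dfg0: float | None = None

    def validate(self) -> None:
        if not self.id:
            raise ValidationError("metabolite with empty id")
        if not (self.conc_lb > 0 and self.conc_ub > 0):
            raise ValidationError(
                f"metabolite {self.id}: concentration bounds must be > 0"
            )
        if self.conc_lb > self.conc_ub:
            raise ValidationError(
                f"metabolite {self.id}: conc_lb > conc_ub"
            )


@dataclass
class Reaction:
    """One reaction with stoichiometry and thermodynamic annotation.

    ``stoich`` maps metabolite id to the stoichiometric coefficient n_ij
    (negative = consumed). ``drg0`` is the transformed standard Gibbs energy
    of reaction (kJ/mol); it may be ``None`` when it is either derivable from
    the participants' ``dfg0`` or the reaction is treated flux-only.
    """

    id: str
    stoich: dict[str, float]
    name: str = ""
    reversible: bool = False
    drg0: float | None = None
    flux_lb: float = 0.0
    flux_ub: float = 100.0
    pathway_tag: str = "exchange"
    source: str = ""

    def validate(self) -> None:
        if not self.stoich:
            raise ValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.flux_lb > self.flux_ub:
            raise ValidationError(f"reaction {self.id}: flux_lb > flux_ub")
        if self.pathway_tag not in PATHWAY_TAGS:
            raise ValidationError(
                f"reaction {self.id}: unknown pathway tag {self.pathway_tag!r}"
            )


@dataclass
class MetabolicNetwork:
    """Ordered metabolite and reaction lists plus process conditions."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    name: str = ""
    temperature: float = 310.15
    ionic_strength: float = 0.15
    ph_in: float = 7.5
    ph_ex: float = 7.0

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def met_idx(self, met_id: str) -> int:
        return self._met_index[met_id]

    def rxn_idx(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    @property
    def model_reactions(self) -> list[Reaction]:
        """Reactions that count toward the model proper (non-exchange)."""
        return [r for r in self.reactions if r.pathway_tag != "exchange"]

    def validate(self, require_biomass: bool = True) -> None:
        seen = set()
        for m in self.metabolites:
            m.validate()
            if m.id in seen:
                raise ValidationError(f"duplicate metabolite id {m.id}")
            seen.add(m.id)
        seen = set()
        for r in self.reactions:
            r.validate()
            if r.id in seen:
                raise ValidationError(f"duplicate reaction id {r.id}")
            seen.add(r.id)
            for met_id in r.stoich:
                if met_id not in self._met_index:
                    raise ValidationError(
                        f"reaction {r.id} references unknown metabolite {met_id!r}"
                    )
        if require_biomass:
            n_bio = sum(1 for r in self.reactions if r.pathway_tag == "biomass")
            if n_bio != 1:
                raise ValidationError(
                    f"expected exactly one biomass-tagged reaction, found {n_bio}"
                )

    # -- derived quantities ------------------------------------------------
    def reference_concentrations(self) -> np.ndarray:
        """Reference concentrations (mM); geometric mean of bounds if unset."""
        out = np.empty(len(self.metabolites))
        for i, m in enumerate(self.metabolites):
            out[i] = (
                m.conc_ref
                if m.conc_ref is not None
                else float(np.sqrt(m.conc_lb * m.conc_ub))
            )
        return out

    def reaction_drg0(self, rxn: Reaction) -> float | None:
        """drg0 of a reaction, derived from participant dfg0 if needed."""
        if rxn.drg0 is not None:
            return rxn.drg0
        dfg = [self.metabolite(m).dfg0 for m in rxn.stoich]
        if any(v is None for v in dfg):
            return None
        return float(
            sum(n * self.metabolite(m).dfg0 for m, n in rxn.stoich.items())
        )


@dataclass
class StructuralDecomposition:
    """Independent-metabolite split of the stoichiometric matrix.

    ``independent_idx`` lists the rows of N forming the first maximal
    linearly independent row set in input order; ``NR`` is the reduced
    stoichiometric matrix over those rows and ``conservation_basis`` expresses
    every dependent row as a linear combination of independent rows.
    """

    independent_idx: np.ndarray
    dependent_idx: np.ndarray
    NR: np.ndarray
    conservation_basis: np.ndarray


# ---------------------------------------------------------------------------
# JSON model format
# ---------------------------------------------------------------------------

_MET_FIELDS = {"id", "name", "measured", "conc_lb", "conc_ub", "conc_ref", "dfg0"}
_RXN_FIELDS = {
    "id", "name", "stoich", "reversible", "drg0", "flux_lb", "flux_ub",
    "pathway_tag", "source",
}


def _network_from_dict(doc: dict) -> MetabolicNetwork:
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise SchemaError(f"model file missing required object {key!r}")
    mets = []
    for raw in doc["metabolites"]:
        if "id" not in raw:
            raise SchemaError("metabolite entry missing field 'id'")
        unknown = set(raw) - _MET_FIELDS
        if unknown:
            raise SchemaError(
                f"metabolite {raw['id']}: unknown field(s) {sorted(unknown)}"
            )
        mets.append(Metabolite(**raw))
    rxns = []
    for raw in doc["reactions"]:
        if "id" not in raw:
            raise SchemaError("reaction entry missing field 'id'")
        if "stoich" not in raw or not isinstance(raw["stoich"], dict):
            raise SchemaError(f"reaction {raw['id']}: missing field 'stoich'")
        unknown = set(raw) - _RXN_FIELDS
        if unknown:
            raise SchemaError(
                f"reaction {raw['id']}: unknown field(s) {sorted(unknown)}"
            )
        rxns.append(Reaction(**raw))
    cond = doc.get("conditions", {})
    net = MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        name=doc.get("name", ""),
        temperature=cond.get("temperature", 310.15),
        ionic_strength=cond.get("ionic_strength", 0.15),
        ph_in=cond.get("ph_in", 7.5),
        ph_ex=cond.get("ph_ex", 7.0),
    )
    net.validate()
    return net


def _network_to_dict(net: MetabolicNetwork) -> dict:
    def met_entry(m: Metabolite) -> dict:
        d = {"id": m.id, "name": m.name, "measured": m.measured,
             "conc_lb": m.conc_lb, "conc_ub": m.conc_ub}
        if m.conc_ref is not None:
            d["conc_ref"] = m.conc_ref
        if m.dfg0 is not None:
            d["dfg0"] = m.dfg0
        return d

    def rxn_entry(r: Reaction) -> dict:
        d = {"id": r.id, "name": r.name, "stoich": dict(r.stoich),
             "reversible": r.reversible, "flux_lb": r.flux_lb,
             "flux_ub": r.flux_ub, "pathway_tag": r.pathway_tag}
        if r.drg0 is not None:
            d["drg0"] = r.drg0
        if r.source:
            d["source"] = r.source
        return d

    return {
        "name": net.name,
        "conditions": {
            "temperature": net.temperature,
            "ionic_strength": net.ionic_strength,
            "ph_in": net.ph_in,
            "ph_ex": net.ph_ex,
        },
        "metabolites": [met_entry(m) for m in net.metabolites],
        "reactions": [rxn_entry(r) for r in net.reactions],
    }


def load_network(path: str | Path) -> MetabolicNetwork:
    """Load a network from the package JSON model format."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"not valid JSON: {exc}") from exc
    return _network_from_dict(doc)


def write_network(net: MetabolicNetwork, path: str | Path) -> None:
    """Write a network to the package JSON model format."""
    with open(path, "w") as fh:
        json.dump(_network_to_dict(net), fh, indent=1, sort_keys=False)
        fh.write("\n")


def load_default_network() -> MetabolicNetwork:
    """The packaged reduced E. coli L-trp network (50 reactions, 57 metabolites)."""
    ref = resources.files("thermomca.data").joinpath("ecoli_trp_reduced.json")
    with resources.as_file(ref) as path:
        return load_network(path)


# ---------------------------------------------------------------------------
# Structural operations
# ---------------------------------------------------------------------------

def stoichiometric_matrix(net: MetabolicNetwork) -> np.ndarray:
    """Dense stoichiometric matrix N (metabolites x reactions)."""
    N = np.zeros((len(net.metabolites), len(net.reactions)))
    for j, rxn in enumerate(net.reactions):
        for met_id, coeff in rxn.stoich.items():
            N[net.met_idx(met_id), j] = coeff
    return N


def export_stoichiometric_matrix(net: MetabolicNetwork, path: str | Path) -> None:
    """TSV export of N with metabolite/reaction ids as index/header."""
    import pandas as pd

    pd.DataFrame(
        stoichiometric_matrix(net),
        index=net.metabolite_ids,
        columns=net.reaction_ids,
    ).to_csv(path, sep="\t")


def decompose(N: np.ndarray | MetabolicNetwork,
              rtol: float = 1e-10) -> StructuralDecomposition:
    """Split metabolites into independent and dependent (conserved) rows.

    Rows are scanned in input order; a row joins the independent set iff it
    increases the rank of the rows accepted so far (Gaussian elimination with
    partial pivoting). Dependent rows are reconstructed from the independent
    ones via least squares; the reconstruction residual is checked.
    """
    if isinstance(N, MetabolicNetwork):
        N = stoichiometric_matrix(N)
    N = np.asarray(N, dtype=float)
    if N.size == 0 or not np.any(N):
        raise ValidationError("empty network: stoichiometric matrix is all zero")

    m, _ = N.shape
    scale = np.linalg.norm(N)
    independent: list[int] = []
    basis_rows: list[np.ndarray] = []  # orthonormalised accepted rows
    for i in range(m):
        row = N[i].copy()
        for q in basis_rows:
            row -= np.dot(q, N[i]) * q
        nrm = np.linalg.norm(row)
        if nrm > rtol * max(scale, 1.0):
            basis_rows.append(row / nrm)
            independent.append(i)
    dependent = [i for i in range(m) if i not in set(independent)]
    NR = N[independent]
    if dependent:
        sol, *_ = np.linalg.lstsq(NR.T, N[dependent].T, rcond=None)
        conservation = sol.T
        resid = np.abs(conservation @ NR - N[dependent]).max()
        if resid > 1e-9 * max(scale, 1.0):
            raise ValidationError(
                f"dependent-row reconstruction residual {resid:.2e} too large"
            )
    else:
        conservation = np.zeros((0, len(independent)))
    return StructuralDecomposition(
        independent_idx=np.array(independent, dtype=int),
        dependent_idx=np.array(dependent, dtype=int),
        NR=NR,
        conservation_basis=conservation,
    )
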
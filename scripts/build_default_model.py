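"""Curate and write the packaged reduced E. coli L-tryptophan network.

The network covers glycolysis + glycerol metabolism, the TCA cycle, the
pentose-phosphate pathway, L-serine biosynthesis and the chorismate /
L-phe / L-tyr / L-trp branches: exactly 50 non-exchange reactions and 57
metabolites, of which the 45 pathway intermediates are flagged as measured
(the LC-MS panel). Reaction sources are noted per entry; a few standard
lumpings keep the network at its pinned size (lactonase folded into zwf,
PRAI into igps, CoA/AMP carriers omitted, nitrogen entering as free NH4+).

Transformed standard Gibbs energies are synthetic-but-consistent: per
reaction a target |deltarG'| magnitude at the reference concentrations is
chosen to match the qualitative thermodynamic profile of E. coli central
metabolism (interconversions of glycolysis/TCA/PPP near equilibrium;
kinases, decarboxylations and the aromatic pathway far from it; gly3pdh at
-14 kJ/mol), the sign is set to oppose the reference flux direction, and
deltarG'0 is backed out via deltarG' = deltarG'0 + RT sum n ln x.

Run from the repository root:  python scripts/build_default_model.py
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from thermomca.constants import RT_DEFAULT
from thermomca.model_core import (
    MetabolicNetwork, Metabolite, Reaction, stoichiometric_matrix, write_network,
)
from thermomca.synthetic_data import (
    FULL_BOUNDARY, FULL_REFERENCE_PINS, close_external_exchanges,
    reference_flux_distribution,
)

# id, name, measured, reference concentration (mM)
METS = [
    # glycolysis + glycerol metabolism (13)
    ("glyc", "glycerol (intracellular)", True, 2.0),
    ("glyc3p", "sn-glycerol 3-phosphate", True, 0.5),
    ("dhap", "dihydroxyacetone phosphate", True, 0.6),
    ("gap", "glyceraldehyde 3-phosphate", True, 0.08),
    ("fbp", "fructose 1,6-bisphosphate", True, 1.7),
    ("f6p", "fructose 6-phosphate", True, 0.35),
    ("g6p", "glucose 6-phosphate", True, 1.2),
    ("13dpg", "1,3-bisphosphoglycerate", True, 0.05),
    ("3pg", "3-phospho-D-glycerate", True, 1.5),
    ("2pg", "2-phospho-D-glycerate", True, 0.2),
    ("pep", "phosphoenolpyruvate", True, 0.4),
    ("pyr", "pyruvate", True, 0.9),
    ("accoa", "acetyl-CoA", True, 0.3),
    # TCA cycle (8)
    ("cit", "citrate", True, 1.5),
    ("icit", "isocitrate", True, 0.1),
    ("akg", "2-oxoglutarate", True, 0.5),
    ("succoa", "succinyl-CoA", True, 0.2),
    ("succ", "succinate", True, 0.8),
    ("fum", "fumarate", True, 0.3),
    ("mal", "L-malate", True, 1.8),
    ("oaa", "oxaloacetate", True, 0.05),
    # pentose-phosphate pathway (7)
    ("6pgc", "6-phosphogluconate", True, 0.8),
    ("ru5p", "ribulose 5-phosphate", True, 0.3),
    ("xu5p", "xylulose 5-phosphate", True, 0.4),
    ("r5p", "ribose 5-phosphate", True, 0.6),
    ("s7p", "sedoheptulose 7-phosphate", True, 0.9),
    ("e4p", "erythrose 4-phosphate", True, 0.05),
    ("prpp", "5-phospho-alpha-D-ribose 1-diphosphate", True, 0.3),
    # L-serine biosynthesis (3)
    ("3php", "3-phosphohydroxypyruvate", True, 0.05),
    ("pser", "O-phospho-L-serine", True, 0.1),
    ("ser", "L-serine", True, 1.0),
    # chorismate biosynthesis (7)
    ("dahp", "3-deoxy-D-arabino-heptulosonate 7-phosphate", True, 0.2),
    ("3dhq", "3-dehydroquinate", True, 0.1),
    ("3dhs", "3-dehydroshikimate", True, 0.3),
    ("shik", "shikimate", True, 0.2),
    ("shik3p", "shikimate 3-phosphate", True, 0.05),
    ("eps", "5-enolpyruvylshikimate 3-phosphate", True, 0.05),
    ("chor", "chorismate", True, 0.1),
    # L-phe / L-tyr branch (2)
    ("pphn", "prephenate", True, 0.05),
    ("phe", "L-phenylalanine", True, 0.5),
    # L-trp branch (5)
    ("anth", "anthranilate", True, 0.02),
    ("pran", "N-(5-phospho-D-ribosyl)anthranilate", True, 0.01),
    ("igp", "indole-3-glycerol phosphate", True, 0.05),
    ("ind", "indole", True, 0.02),
    ("trp", "L-tryptophan", True, 1.5),
    # cofactors and freely exchanged species (9, unmeasured; physiological
    # concentration ranges from the E. coli literature)
    ("atp", "ATP", False, 3.0, (1.0, 10.0)),
    ("adp", "ADP", False, 0.8, (0.2, 2.0)),
    ("nad", "NAD+", False, 1.5, (0.5, 3.0)),
    ("nadh", "NADH", False, 0.15, (0.02, 0.4)),
    ("nadp", "NADP+", False, 0.1, (0.02, 0.4)),
    ("nadph", "NADPH", False, 0.25, (0.05, 0.8)),
    ("co2", "CO2 (dissolved)", False, 1.5, (0.5, 5.0)),
    ("o2", "O2 (dissolved)", False, 0.2, (0.01, 0.3)),
    ("nh4", "ammonium", False, 5.0, (1.0, 20.0)),
    # extracellular substrates (3, unmeasured)
    ("glyc_e", "glycerol (extracellular)", False, 1.0),
    ("glc_e", "D-glucose (extracellular)", False, 0.01),
    ("shik_e", "shikimate (extracellular)", False, 0.05),
]

# id, name, stoich, reversible, tag, |target deltarG'| at reference (kJ/mol,
# None = flux-only), source note
RXNS = [
    # glycolysis and glycerol metabolism (14)
    ("glcpts", "glucose PTS uptake",
     {"glc_e": -1, "pep": -1, "g6p": 1, "pyr": 1}, False, "GLYC&GLYK", 45.0,
     "PTS; committed, strongly downhill"),
    ("glyk", "glycerol kinase (glpK)",
     {"glyc": -1, "atp": -1, "glyc3p": 1, "adp": 1}, False, "GLYC&GLYK", 20.0,
     "pathway map; classified far from equilibrium"),
    ("gly3pdh", "glycerol-3-phosphate dehydrogenase",
     {"glyc3p": -1, "nad": -1, "dhap": 1, "nadh": 1}, False, "GLYC&GLYK", 14.0,
     "pathway map; reported reaction energies -24..-5 kJ/mol"),
    ("tpi", "triose-phosphate isomerase",
     {"dhap": -1, "gap": 1}, True, "GLYC&GLYK", 2.0, "near equilibrium"),
    ("fba", "fructose-bisphosphate aldolase",
     {"fbp": -1, "dhap": 1, "gap": 1}, True, "GLYC&GLYK", 2.5,
     "near equilibrium; gluconeogenic direction on glycerol"),
    ("fbp", "fructose-1,6-bisphosphatase",
     {"fbp": -1, "f6p": 1}, False, "GLYC&GLYK", 12.0,
     "committed gluconeogenic step; far from equilibrium"),
    ("pfk", "phosphofructokinase",
     {"f6p": -1, "atp": -1, "fbp": 1, "adp": 1}, False, "GLYC&GLYK", 18.0,
     "committed glycolytic step; far from equilibrium"),
    ("pgi", "glucose-6-phosphate isomerase",
     {"g6p": -1, "f6p": 1}, True, "GLYC&GLYK", 1.5, "near equilibrium"),
    ("gapd", "glyceraldehyde-3-phosphate dehydrogenase",
     {"gap": -1, "nad": -1, "13dpg": 1, "nadh": 1}, True, "GLYC&GLYK", 1.5,
     "near equilibrium (phosphate lumped into the transformed energy)"),
    ("pgk", "phosphoglycerate kinase",
     {"13dpg": -1, "adp": -1, "3pg": 1, "atp": 1}, True, "GLYC&GLYK", 2.0,
     "near equilibrium"),
    ("pgm", "phosphoglycerate mutase",
     {"3pg": -1, "2pg": 1}, True, "GLYC&GLYK", 1.0, "near equilibrium"),
    ("eno", "enolase", {"2pg": -1, "pep": 1}, True, "GLYC&GLYK", 1.5,
     "near equilibrium"),
    ("pyk", "pyruvate kinase",
     {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}, False, "GLYC&GLYK", 25.0,
     "committed step; far from equilibrium"),
    ("pdh", "pyruvate dehydrogenase",
     {"pyr": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1}, False,
     "GLYC&GLYK", 35.0, "decarboxylation; far from equilibrium (CoA lumped)"),
    # TCA cycle + oxidative phosphorylation (10)
    ("cs", "citrate synthase",
     {"accoa": -1, "oaa": -1, "cit": 1}, False, "TCA", 35.0,
     "committed step (CoA lumped)"),
    ("acont", "aconitase",
     {"cit": -1, "icit": 1}, True, "TCA", 1.0, "near equilibrium"),
    ("icd", "isocitrate dehydrogenase",
     {"icit": -1, "nadp": -1, "akg": 1, "co2": 1, "nadph": 1}, False, "TCA",
     4.0, "operates close to equilibrium under production conditions"),
    ("akgdh", "2-oxoglutarate dehydrogenase",
     {"akg": -1, "nad": -1, "succoa": 1, "co2": 1, "nadh": 1}, False, "TCA",
     30.0, "decarboxylation; far from equilibrium (CoA lumped)"),
    ("sucoas", "succinyl-CoA synthetase",
     {"succoa": -1, "adp": -1, "succ": 1, "atp": 1}, True, "TCA", 0.8,
     "near equilibrium; the one invertible TCA step"),
    ("sucdh", "succinate dehydrogenase",
     {"succ": -1, "nad": -1, "fum": 1, "nadh": 1}, False, "TCA", 12.0,
     "quinone pool represented by NAD in this reduced model"),
    ("fum", "fumarase", {"fum": -1, "mal": 1}, True, "TCA", 1.2,
     "near equilibrium"),
    ("mdh", "malate dehydrogenase",
     {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1}, True, "TCA", 0.8,
     "near equilibrium"),
    ("ppc", "PEP carboxylase",
     {"pep": -1, "co2": -1, "oaa": 1}, False, "TCA", 25.0,
     "anaplerosis; far from equilibrium"),
    ("oxphos", "oxidative phosphorylation (lumped)",
     {"nadh": -1, "o2": -0.5, "adp": -2, "nad": 1, "atp": 2}, False, "TCA",
     None, "lumped respiratory chain + ATP synthase; flux-only"),
    # pentose-phosphate pathway (8)
    ("zwf", "glucose-6-phosphate dehydrogenase (+lactonase)",
     {"g6p": -1, "nadp": -1, "6pgc": 1, "nadph": 1}, False, "PPP", 15.0,
     "oxidative branch; 6-phosphogluconolactonase lumped in"),
    ("gnd", "6-phosphogluconate dehydrogenase",
     {"6pgc": -1, "nadp": -1, "ru5p": 1, "co2": 1, "nadph": 1}, False, "PPP",
     11.0, "decarboxylation; far from equilibrium"),
    ("rpe", "ribulose-5-phosphate 3-epimerase",
     {"ru5p": -1, "xu5p": 1}, True, "PPP", 0.5, "near equilibrium"),
    ("rpi", "ribose-5-phosphate isomerase",
     {"ru5p": -1, "r5p": 1}, True, "PPP", 0.6, "near equilibrium"),
    ("tkt1", "transketolase 1",
     {"xu5p": -1, "r5p": -1, "s7p": 1, "gap": 1}, True, "PPP", 1.0,
     "near equilibrium, reversible"),
    ("tala", "transaldolase",
     {"s7p": -1, "gap": -1, "e4p": 1, "f6p": 1}, True, "PPP", 0.8,
     "near equilibrium, reversible"),
    ("tkt2", "transketolase 2",
     {"xu5p": -1, "e4p": -1, "f6p": 1, "gap": 1}, True, "PPP", 0.9,
     "near equilibrium, reversible"),
    ("prpps", "PRPP synthetase",
     {"r5p": -1, "atp": -1, "prpp": 1, "adp": 1}, False, "PPP", 30.0,
     "AMP product represented by ADP in this reduced model"),
    # L-serine biosynthesis (3)
    ("pgdh", "3-phosphoglycerate dehydrogenase (serA)",
     {"3pg": -1, "nad": -1, "3php": 1, "nadh": 1}, True, "L-ser", 3.0,
     "operates close to thermodynamic equilibrium"),
    ("psert", "phosphoserine transaminase (serC)",
     {"3php": -1, "nh4": -1, "pser": 1}, False, "L-ser", 55.0,
     "glutamate transamination written with free NH4+; strongly downhill"),
    ("psp_L", "phosphoserine phosphatase (serB)",
     {"pser": -1, "ser": 1}, False, "L-ser", 52.0,
     "strongly downhill phosphatase"),
    # chorismate biosynthesis (7)
    ("dahpts", "DAHP synthase (aroF)",
     {"pep": -1, "e4p": -1, "dahp": 1}, False, "CHOR", 48.0,
     "exceptionally negative reaction energy"),
    ("dhqs", "3-dehydroquinate synthase (aroB)",
     {"dahp": -1, "3dhq": 1}, False, "CHOR", 50.0,
     "exceptionally negative reaction energy"),
    ("dhqd", "3-dehydroquinate dehydratase",
     {"3dhq": -1, "3dhs": 1}, False, "CHOR", 5.0, "near equilibrium"),
    ("shikdh", "shikimate dehydrogenase (aroE)",
     {"3dhs": -1, "nadph": -1, "shik": 1, "nadp": 1}, False, "CHOR", 6.0,
     "near equilibrium"),
    ("shikk", "shikimate kinase (aroL)",
     {"shik": -1, "atp": -1, "shik3p": 1, "adp": 1}, False, "CHOR", 25.0,
     "kinase; far from equilibrium"),
    ("epsps", "EPSP synthase (aroA)",
     {"shik3p": -1, "pep": -1, "eps": 1}, False, "CHOR", 15.0,
     "far from equilibrium"),
    ("chors", "chorismate synthase (aroC)",
     {"eps": -1, "chor": 1}, False, "CHOR", 50.0,
     "exceptionally negative reaction energy"),
    # L-phe / L-tyr branch (2)
    ("chorm", "chorismate mutase",
     {"chor": -1, "pphn": 1}, False, "L-phe/L-tyr", 45.0,
     "exceptionally negative reaction energy"),
    ("ppndh", "prephenate dehydratase",
     {"pphn": -1, "phe": 1, "co2": 1}, False, "L-phe/L-tyr", 40.0,
     "decarboxylation; far from equilibrium (transamination lumped)"),
    # L-trp branch (5)
    ("ans", "anthranilate synthase (trpE)",
     {"chor": -1, "nh4": -1, "anth": 1, "pyr": 1}, False, "L-trp", 42.0,
     "glutamine amide donor written with free NH4+; far from equilibrium"),
    ("anprt", "anthranilate phosphoribosyltransferase (trpD)",
     {"anth": -1, "prpp": -1, "pran": 1}, False, "L-trp", 25.0,
     "far from equilibrium"),
    ("igps", "indole-3-glycerol-phosphate synthase (trpC, +PRAI)",
     {"pran": -1, "igp": 1, "co2": 1}, False, "L-trp", 32.0,
     "PRAI lumped in; far from equilibrium"),
    ("trps1", "tryptophan synthase alpha (trpA)",
     {"igp": -1, "ind": 1, "gap": 1}, False, "L-trp", 12.0,
     "far from equilibrium"),
    ("trps2", "tryptophan synthase beta (trpB)",
     {"ind": -1, "ser": -1, "trp": 1}, False, "L-trp", 40.0,
     "far from equilibrium; strongest L-trp control point"),
    # biomass (1): precursor demands per gCDW scaled to growth-rate flux
    ("biomass", "biomass formation",
     {"g6p": -0.205, "f6p": -0.071, "r5p": -0.898, "e4p": -0.361,
      "gap": -0.129, "3pg": -1.496, "pep": -0.519, "pyr": -2.833,
      "accoa": -3.748, "oaa": -1.787, "akg": -1.079, "ser": -0.4,
      "prpp": -0.2, "nh4": -8.0, "atp": -41.0, "adp": 41.0,
      "nadph": -13.0, "nadp": 13.0, "nad": -3.547, "nadh": 3.547},
     False, "biomass", None,
     "standard E. coli precursor demands (mmol/gCDW); flux unit 1/h"),
    # exchange and transport (not counted toward the 50 model reactions)
    ("EX_glyc", "glycerol feed", {"glyc_e": 1}, False, "exchange", None,
     "feed-limited supply"),
    ("glyct", "glycerol uptake (diffusion)",
     {"glyc_e": -1, "glyc": 1}, False, "exchange", None,
     "facilitated diffusion"),
    ("EX_glc", "glucose feed", {"glc_e": 1}, False, "exchange", None,
     "feed-limited supply"),
    ("EX_shik", "shikimate feed", {"shik_e": 1}, False, "exchange", None,
     "feed-limited supply"),
    ("shikt", "shikimate transporter (shiA)",
     {"shik_e": -1, "shik": 1}, False, "exchange", None,
     "heterologous shikimate/H+ symporter"),
    ("EX_trp", "L-tryptophan export", {"trp": -1}, False, "exchange", None,
     "product export"),
    ("EX_phe", "L-phenylalanine export", {"phe": -1}, False, "exchange", None,
     "by-product export"),
    ("EX_co2", "CO2 evolution", {"co2": -1}, False, "exchange", None,
     "respiration (CPR)"),
    ("EX_o2", "O2 uptake", {"o2": 1}, False, "exchange", None,
     "respiration (OUR)"),
    ("EX_nh4", "ammonium uptake", {"nh4": 1}, False, "exchange", None,
     "nitrogen source"),
    ("atpm", "non-growth-associated maintenance",
     {"atp": -1, "adp": 1}, False, "exchange", None,
     "energy-dissipation pseudo-reaction (like the exchanges, not part of "
     "the enzymatic network)"),
]


def build() -> MetabolicNetwork:
    metabolites = []
    for entry in METS:
        i, n, m, c = entry[:4]
        lb, ub = entry[4] if len(entry) > 4 else (1e-4, 50.0)
        metabolites.append(Metabolite(id=i, name=n, measured=m, conc_ref=c,
                                      conc_lb=lb, conc_ub=ub))
    reactions = []
    for rid, name, stoich, rev, tag, _, source in RXNS:
        ub = 100.0
        lb = -100.0 if rev else 0.0
        if rid == "biomass":
            ub = 0.5
        reactions.append(Reaction(
            id=rid, name=name, stoich=stoich, reversible=rev,
            flux_lb=lb, flux_ub=ub, pathway_tag=tag, source=source,
        ))
    net = MetabolicNetwork(
        metabolites=metabolites, reactions=reactions,
        name="ecoli_trp_reduced",
        temperature=310.15, ionic_strength=0.15, ph_in=7.5, ph_ex=7.0,
    )
    net.validate()

    n_model = len(net.model_reactions)
    n_meas = sum(m.measured for m in net.metabolites)
    assert n_model == 50, f"model reactions: {n_model}"
    assert len(net.metabolites) == 57, f"metabolites: {len(net.metabolites)}"
    assert n_meas == 45, f"measured metabolites: {n_meas}"

    # reference flux distribution fixes the deltarG' signs
    balanced = [m.id for m in net.metabolites if m.id not in FULL_BOUNDARY]
    v_ref = reference_flux_distribution(net, FULL_REFERENCE_PINS, balanced=balanced)
    v_ref = close_external_exchanges(net, v_ref)
    x_ref = net.reference_concentrations()
    lnx = np.log(x_ref * 1e-3)
    N = stoichiometric_matrix(net)
    print("reference fluxes (nonzero):")
    for j, r in enumerate(net.reactions):
        if abs(v_ref[j]) > 1e-9:
            print(f"  {r.id:10s} {v_ref[j]:10.4f}")
        else:
            print(f"  {r.id:10s} {'ZERO':>10s}  <-- check")
    for (rid, _, _, _, _, mag, _) in RXNS:
        if mag is None:
            continue
        j = net.rxn_idx(rid)
        sign = -1.0 if v_ref[j] >= 0 else 1.0
        drg_ref = sign * abs(mag)
        net.reactions[j].drg0 = float(drg_ref - RT_DEFAULT * (N[:, j] @ lnx))
    out = Path(__file__).resolve().parents[1] / "src" / "thermomca" / "data"
    out.mkdir(parents=True, exist_ok=True)
    write_network(net, out / "ecoli_trp_reduced.json")
    print(f"\nwrote {out / 'ecoli_trp_reduced.json'}")
    return net


if __name__ == "__main__":
    build()
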
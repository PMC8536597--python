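"""Assemble the elasticity matrices.

Near-equilibrium reactions get thermokinetic elasticities from the feasible
Gibbs-energy ranges (eps = n RT / deltarG' at the midpoint); far-from-
equilibrium reactions are regressed with the lin-log model over their
measured substrates and literature effectors (anthranilate inhibiting IGPS),
with the thermodynamic sensitivities of the remaining participants filled
in. Writes elasticities.tsv with a provenance column per entry.
"""

import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from thermomca.pipeline import (
    PipelineConfig, stage_elasticity, stage_simulate, stage_tfa,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

for preset, tag in (("trp_toy", "toy"), ("ecoli_trp", "full")):
    outdir = RESULTS / tag
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(preset=preset, seed=1, output_dir=str(outdir))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, dataset = stage_simulate(cfg, outdir)
        problem, thermo = stage_tfa(cfg, model, dataset, outdir)
        E = stage_elasticity(cfg, model, dataset, thermo, outdir)
    table = pd.read_csv(outdir / "elasticities.tsv", sep="\t")
    counts = table["provenance"].value_counts().to_dict()
    print(f"[{preset}] {len(table)} nonzero elasticities ({counts}); "
          f"-> {outdir / 'elasticities.tsv'}")
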
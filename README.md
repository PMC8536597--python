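# thermomca

Thermodynamics-based flux variability analysis (TFA) and metabolic control
analysis (MCA) for L-tryptophan production in *Escherichia coli*, at the
scale of a reduced central-carbon + aromatic-amino-acid network (50
enzymatic reactions, 57 metabolites, a 45-metabolite measured panel). Built
for systems-biology practitioners who want to go from perturbation-
experiment tables (extracellular rates, intracellular metabolome) to
thermodynamically consistent flux ranges, elasticities and flux control
coefficients with quantified uncertainty.

## What it computes

**TFA.** A mixed-integer linear program couples steady-state flux balance,
transformed Gibbs reaction energies and direction binaries,

    N v = 0,    ΔrG′_j = ΔrG′°_j + RT Σ_i n_ij ln x_i,    sign(v_j)·ΔrG′_j ≤ 0,

maximises growth subject to measured extracellular rates and intracellular
concentrations, solves per-variable feasible ranges over all solutions
reaching 99.9% of the optimum, and samples the residual solution space with
an artificially centered hit-and-run sampler (10,000 points).

**Elasticities.** Reactions whose feasible ΔrG′ range reaches above
−10 kJ/mol are near equilibrium and get thermokinetic elasticities

    ε_X^v = −n RT / (A − A#),   A = −ΔrG′,  A# = 0,

directly from the Gibbs-energy ranges; far-from-equilibrium reactions are
regressed with the lin-log model

    (v/v⁰)(e⁰/e) − 1 = Σ_i ε_i ln(X_i/X_i⁰)

over the perturbation steady states, using literature effectors
(anthranilate inhibiting indole-3-glycerol-phosphate synthase).

**MCA.** Flux control coefficients follow from the steady-state
linearisation with the link matrix L0 = [X0]⁻¹ N (N_R)⁺ [X0^ind]:

    C_v = I + E·K,    K = −L0 (N_R [v0] E L0)⁻¹ N_R [v0],

with the summation and connectivity theorems as built-in diagnostics, and
Monte Carlo propagation of the thermodynamically feasible flux, Gibbs-energy
and concentration ranges (jointly feasible samples, 10,000 cycles).

**Synthetic data.** Because the study's raw fermentation data are not
published, a first-class generator reproduces the experimental design: 4
substrate regimes (glycerol; glucose; glycerol+shikimate; glucose+shikimate)
× 3 feeding levels + the reference production state = 13 steady states of a
lin-log kinetic cell model, with multiplicative measurement noise and known
ground-truth control coefficients (brute-force 1% enzyme perturbation) that
serve as the pipeline's oracle.

## Worked example

```python
from thermomca.pipeline import PipelineConfig, run_full
import pandas as pd

cfg = PipelineConfig(seed=1, n_cycles=10_000, output_dir="results/demo")
run_full(cfg)
fcc = pd.read_csv("results/demo/fcc_mean.tsv", sep="\t", index_col=0)
print(fcc.abs().stack().sort_values(ascending=False).head(5))
```

prints the strongest mean control interactions of the default configuration:

```
enzyme
ans      ppp           0.808498
ser_syn  ser_drain     0.805147
ans      ans           0.804032
         trp_export    0.804032
         igps_trps     0.804032
```

Anthranilate synthase — the committed step of the L-trp branch — carries the
strongest control over L-tryptophan export (≈ +0.80: a 1% increase in its
activity raises the production flux by ≈ 0.80%) and, through the PRPP
connection, a comparable positive control over the pentose-phosphate flux;
the serine-branch supply controls the serine drain at a similar magnitude.
All mean enzyme control coefficients lie within the unit interval, the
summation theorem holds to ~10⁻¹⁴ on the point computation, and the same
artifact directory contains the dataset tables (`rates.tsv`,
`metabolome.tsv`), the TFA ranges with near/far-from-equilibrium
classification (`ranges.tsv`), the provenance-tagged elasticities
(`elasticities.tsv`) and the FCC summaries (`fcc_{mean,sd,se,q05,q95}.tsv`).

The same pipeline runs from a shell:

```sh
thermomca run --seed 1 --out results/demo
thermomca report results/demo
```

and the `analysis/` scripts walk the full study (simulate → TFA →
elasticities → MCA → report) on both the default toy configuration and the
full 50-reaction network, writing their tables under `results/`.

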
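# Default pipeline configuration: the coarse-grained L-trp production toy
# under the 4-regime x 3-level + reference perturbation design.
# Every numeric default the analysis depends on is surfaced here.
preset: trp_toy
regimes: [glycerol, glucose, glycerol+shikimate, glucose+shikimate]
levels_per_regime: 3
supply_multipliers: [0.77, 1.15, 1.65]
noise_cv: 0.1          # multiplicative log-normal measurement noise
seed: 1                # measurement-noise / Monte Carlo seed
model_seed: 1          # fixes the synthetic cell line's true elasticities
gamma: 0.999           # optimality fraction of the variability analysis
bigM: 1000.0           # kJ/mol big-M constant of the direction coupling
epsilon_flux: 1.0e-6   # minimum |flux| of an active reaction, mmol/gCDW/h
rate_rel_width: 0.05   # relative widening of measured rates into bounds
conc_rel_width: 0.20   # relative widening of measured concentrations
near_threshold: 10.0   # |deltarG'| near/far-from-equilibrium split, kJ/mol
n_cycles: 10000        # Monte Carlo cycles of the FCC uncertainty analysis
output_dir: results/pipeline
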
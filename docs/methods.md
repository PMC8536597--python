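# Methods

## Scope and model

`thermomca` implements thermodynamics-based flux variability analysis (TFA)
and metabolic control analysis (MCA) for L-tryptophan production in
*E. coli* growing on glycerol, at the scale of a reduced central-carbon +
aromatic-amino-acid network. The packaged default network
(`thermomca/data/ecoli_trp_reduced.json`) has exactly **50 enzymatic
reactions and 57 metabolites**, covering glycolysis and glycerol metabolism,
the TCA cycle, the pentose-phosphate pathway (PPP), L-serine biosynthesis,
chorismate biosynthesis, the L-phe/L-tyr branch and the L-trp branch, plus
exchange/transport pseudo-reactions (feeds, product exports, respiration, an
ATP-maintenance drain) that are not counted among the 50. 45 pathway
intermediates are flagged as the measured metabolome panel; cofactor pools
and freely exchanged small species are unmeasured.

A few standard lumpings keep the network at its pinned size and are noted in
the model file per reaction: 6-phosphogluconolactonase is folded into the
G6P dehydrogenase step, PRAI into IGPS, CoA and AMP carriers are omitted,
nitrogen enters as free NH4+, the respiratory chain is one lumped
NADH-to-ATP reaction (P/O = 2), and phosphate is absorbed into the
transformed reaction energies.

Thermodynamic annotations are synthetic but internally consistent: for each
reaction a target |ΔrG′| at the curated reference concentrations was chosen
to match the qualitative thermodynamic profile of *E. coli* central
metabolism (the glycolytic/TCA/PPP interconversions within a few kJ/mol of
equilibrium; kinases, decarboxylations and the aromatic pathway strongly
downhill; glycerol-3-phosphate dehydrogenase around −14 kJ/mol), the sign
was set to oppose the reference flux direction, and ΔrG′° was backed out
through ΔrG′ = ΔrG′° + RT·Σ n_ij ln x_i (x in mol/L; T = 310.15 K,
R = 8.314462618×10⁻³ kJ/mol/K; energies are transformed values at
intracellular pH 7.5, ionic strength 0.15 M). Unmeasured cofactor pools
carry literature-informed physiological concentration bounds (e.g. ATP 1–10
mM, NADH 0.02–0.4 mM); without them the feasible ΔrG′ ranges of
cofactor-coupled reactions span tens of kJ/mol and kinases misclassify as
near-equilibrium. All other unmeasured species default to [10⁻⁴, 50] mM.

## Synthetic perturbation data

The generator emulates the study design: a reference fed-batch production
state plus four parallel perturbation regimes (glycerol; glucose;
glycerol+shikimate; glucose+shikimate), each at three feeding levels —
**13 metabolic steady states**. Supply magnitudes follow the printed rates
(glycerol 2.0–4.3, glucose ~0.7–1.5, shikimate ~0.26 mmol/gCDW/h; level
multipliers 0.77/1.15/1.65 around the reference uptake of 2.6).

Cells follow lin-log kinetics around the reference state,
v_j = e_j·v_j*·(1 + Σ_i ε*_ij ln(X_i/X_i*)), with feed-limited supplies as
fixed-rate steps. True elasticities follow a thermokinetic decomposition:

* near equilibrium (|ΔrG′| < 10 kJ/mol): fully thermodynamic,
  ε = n_ij·RT/ΔrG′ for every participant;
* far from equilibrium: kinetic substrate elasticities drawn once from
  U(0.4, 1.0), effector elasticities from U(0.3, 0.6) with the literature
  sign (anthranilate feed-forward-inhibits IGPS), and products retaining
  only the thermodynamic part n_ij·RT/ΔrG′ (kinetic product saturation).
  The product-saturation choice is also what makes the rate laws
  identifiable from the 13-state design, whose perturbation space has rank
  three.

The default configuration fixes the synthetic cell line (`model_seed = 1`):
the elasticity draw defines the biological system under study, while the run
seed varies only measurement noise and Monte Carlo draws. Measurement noise
is multiplicative log-normal (mean-preserving) with CV 0.1 on rates and
concentrations — the study reports no error model, and 10% is a typical
combined LC-MS/rate uncertainty.

Steady states are solved exactly for the log-concentration deviations (the
lin-log balances are linear in them); conserved cofactor totals are then
enforced by a damped Newton (Powell hybrid) iteration in the null space of
the balances. Pool totals are conserved for enzyme perturbations around a
state — the flux-control-coefficient definition, matching the link-matrix
treatment — but not across regimes: the four analysis reactors are
independent cultures, and pinning the reference culture's totals provably
leaves large regime shifts without a steady state. Lin-log extrapolation
across regimes can produce large concentration excursions for weakly coupled
metabolites; this is a known artifact of the rate-law family, not of the
solver.

Ground-truth flux control coefficients come from brute-force enzyme
perturbation: central finite differences at 1% relative enzyme change, the
definition scale of the FCC.

## TFA

The MILP couples N·v = 0, ΔrG′_j = ΔrG′°_j + RT·Σ n_ij ln x_i, and
direction binaries with big-M linking (big-M = 1000 kJ/mol, minimum active
flux 10⁻⁶ mmol/gCDW/h), so every active annotated reaction runs downhill
(sign(v_j)·ΔrG′_j ≤ 0). Reactions without an annotation (the lumped
respiratory chain, biomass, exchanges) are flux-only. Solved with HiGHS
through `scipy.optimize.milp`.

Measured rates are the exchanges, the growth/energy drain, and pure
consumption drains (by-product formation and growth-composition demands,
pinned by growth rate and biomass composition). Because structurally coupled
rates are measured independently, the raw values are first reconciled: the
smallest relative L1 correction restoring flux balance within the reaction
bounds (standard fermentation data reconciliation). Reconciled rates are
widened ±5% into bounds; measured concentrations ±20% (≈2 standard
deviations of the assay noise).

Growth is maximised; variability then solves each variable's minimum and
maximum subject to objective ≥ γ·optimum with γ = 0.999 (routes fulfilling
99.9% of the optimum). Reactions are classified **near** equilibrium when
their feasible ΔrG′ range reaches above −10 kJ/mol and **far** when the
whole range lies at or below it (closed comparison at the boundary).

The residual solution space is explored with an artificially centered
hit-and-run sampler after fixing the optimal direction pattern: the
equalities decouple into a flux block (null space of N) and a thermodynamic
block (each log-concentration drags its reaction energies along), each
coordinate is rescaled by its feasible extent, and directions run through
the moving centre of the visited points — the treatment elongated flux
polytopes need. Warm-up is 100 steps per dimension with thinning 10,
deterministic per seed; the default 10,000 samples match the study's
sampling depth. The optimality cut applies to the variability ranges but not
to reference-state sampling, which explores the whole measured-constrained
space.

## Elasticities

Near-equilibrium rows use the thermokinetic formula ε = −n_ij·RT/(A_j −
A_j#) with A_j = −ΔrG′_j and A_j# = 0 (equivalently n_ij·RT/ΔrG′_j),
evaluated at the midpoint of the feasible ΔrG′ range for point estimates;
the formula is orientation-invariant, so net-reverse reactions need no
special casing.

Far-from-equilibrium rows are estimated from the perturbation data with the
lin-log regression (v_j/v_j⁰)(e_j⁰/e_j) − 1 = Σ_i ε_i ln(X_i/X_i⁰), solved
per reaction over its measured net-direction substrates and effectors. Three
safeguards address the small, noisy, near-collinear design:

* the known thermodynamic contributions of participants outside the
  regression (products, unmeasured cofactors) are filled in as n_ij·RT/ΔrG′
  and, where measured, subtracted from the response first;
* coefficients are bounded by their admissible region — substrate
  elasticities at least their thermodynamic part, products at most theirs,
  inhibitors non-positive — via bounded least squares;
* an empirical-Bayes ridge (prior ε ~ N(0,1), observation variance estimated
  from the first-pass residual) shrinks weakly identified directions. The
  penalty vanishes on noise-free data, so exact recovery is preserved.

Every entry carries a provenance tag (`thermokinetic`/`linlog`/`zero`).
Elasticities toward unmeasured cofactors beyond their thermodynamic floor
are not identifiable from the metabolome panel; this is the main known bias
on the full network.

## Control analysis

With the boundary species (CO2, O2, NH4+, extracellular substrates) clamped,
the stoichiometric matrix is reduced to a full-row-rank N_R over the
independent metabolites (Gaussian elimination in input order; the adenylate,
NAD(H) and NADP(H) pools are the conserved moieties of the default network),
and the concentration-scaled link matrix is L0 = [X0]⁻¹·N·(N_R)⁺·[X0^ind]
with (N_R)⁺ the Moore–Penrose pseudoinverse. The concentration-response
kernel is K = −L0·(N_R[v0]E L0)⁻¹·N_R[v0] and the flux-FCC matrix is

    C_v = I + E·K.

The identity term completes the canonical lin-log flux-control expression;
the product E·K alone is the concentration-response part, retained as
`C_response`, and does not satisfy the summation theorem on its own. Both
the summation theorem (per-flux enzyme FCCs summing to 1 whenever N_R·v0 =
0) and the connectivity theorem (C·(E·L0) = 0) are reported as diagnostics;
measured reference fluxes are reconciled to exact flux balance before the
point computation. Inner matrices with condition number above 10⁸ are
treated as singular (well-posed problems sit at 10³–10⁵).

Uncertainty propagation draws jointly feasible (v0, ΔrG′, ln x) points from
the TFA solution polytope — so flux balance and the second law hold in every
cycle — rebuilds the near-equilibrium rows thermokinetically from the
sampled ΔrG′, re-fits the far rows on a bootstrap resample of the
perturbation states (bagging the regression, whose instability under noise
otherwise dominates), and recomputes C; 10,000 cycles by default. Summaries
are entrywise means, standard deviations, central 90% intervals, and
batch-means standard errors of the mean (the cycles are a thinned Markov
chain, so residual autocorrelation must enter the uncertainty). Singular
cycles are dropped and counted; more than 50% dropped is an error.

FCC tables report enzyme-catalysed reactions as rows: feed-limited supply
steps are boundary parameters whose sensitivities are response coefficients,
not control coefficients. Columns cover all model fluxes; control on a
near-zero flux (e.g. the small futile pairing in the full network) is
legitimately large in magnitude.

## Problem sizes and defaults

The default pipeline configuration (all surfaced in
`thermomca/data/default_config.yaml`) runs the coarse-grained 15-reaction /
10-metabolite L-trp toy with 10,000 Monte Carlo cycles; the full 50-reaction
network is analysed in `analysis/` with 2,000 cycles, the problem size
chosen for this analysis. The toy's true enzyme FCC magnitudes stay within
the unit interval, consistent with the regime the study reports.

## What the synthetic data do and do not show

The generator reproduces the study's design (state counts, supply
magnitudes, measured panel, noise scale, thermodynamic profile) but not real
fermentation data: rate laws are exactly lin-log (so estimator consistency
checks are favourable by construction), noise is independent across
measurements, proteome constancy is exact (e ≡ 1 across levels), and the
regulatory map contains a single literature effector. Passing tests
therefore demonstrate correctness of the computations and internal
consistency of the estimators at realistic noise, not predictive accuracy on
wet-lab measurements. Estimation limits that do carry over to real data —
errors-in-variables attenuation at CV 0.1 (median elasticity error ≈ 0.23 on
a two-parameter reaction over 200 replicates), unidentifiable cofactor
elasticities, control inflation on poorly determined drain fluxes — are
quantified in the test suite.
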
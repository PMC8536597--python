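"""End-to-end pipeline: simulate -> TFA -> elasticities -> Monte Carlo MCA.

Mirrors the study workflow: a perturbation experiment yields extracellular
rates and an intracellular metabolome around a reference production state;
thermodynamics-based variability analysis bounds the feasible fluxes, Gibbs
reaction energies and concentrations of the reference state; elasticities
are assembled (thermokinetic near equilibrium, lin-log regression far from
it); flux control coefficients follow from the linearisation, with
uncertainty propagated by Monte Carlo over the TFA ranges.

All artifacts are plain TSV/JSON and byte-reproducible for a fixed config.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import mca, tfa
from .elasticity import (
    EffectorMap,
    ElasticityMatrix,
    assemble_elasticity_matrix,
    write_elasticities,
)
from .errors import SingularSystemError, ValidationError
from .mca import SteadyState
from .model_core import MetabolicNetwork, decompose, stoichiometric_matrix
from .synthetic_data import (
    FULL_BOUNDARY,
    PerturbationDesign,
    build_default_kinetic_model,
    generate_perturbation_dataset,
    write_dataset,
)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, surfaced in one place."""

    preset: str = "trp_toy"
    regimes: list[str] = field(default_factory=lambda: [
        "glycerol", "glucose", "glycerol+shikimate", "glucose+shikimate",
    ])
    levels_per_regime: int = 3
    supply_multipliers: tuple[float, ...] = (0.77, 1.15, 1.65)
    noise_cv: float = 0.1
    seed: int = 1
    model_seed: int = 1   # fixes the synthetic cell line; `seed` varies the
    #                       measurement noise and Monte Carlo draws only
    gamma: float = 0.999
    bigM: float = 1000.0
    epsilon_flux: float = 1e-6
    rate_rel_width: float = 0.05
    conc_rel_width: float = 0.20
    near_threshold: float = 10.0
    n_cycles: int = 10_000
    mc_seed: int | None = None   # Monte Carlo seed; defaults to `seed`
    effectors_path: str | None = None
    output_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.supply_multipliers = tuple(cfg.supply_multipliers)
        return cfg

    def design(self) -> PerturbationDesign:
        return PerturbationDesign(
            regimes=list(self.regimes),
            levels_per_regime=self.levels_per_regime,
            supply_multipliers=tuple(self.supply_multipliers),
        )


def default_effectors(net: MetabolicNetwork,
                      path: str | None = None) -> EffectorMap:
    """Load the effector map and restrict it to reactions of this network."""
    if path is None:
        ref = resources.files("thermomca.data").joinpath("effectors.yaml")
        with resources.as_file(ref) as p:
            emap = EffectorMap.from_yaml(p)
    else:
        emap = EffectorMap.from_yaml(path)
    emap.effectors = {
        rid: effs for rid, effs in emap.effectors.items()
        if rid in net._rxn_index
    }
    emap.validate_against(net)
    return emap


def measured_rate_reactions(net: MetabolicNetwork) -> list[str]:
    """Reactions observable as rates: exchanges (feeds, product exports,
    respiration), the growth/energy drain, and pure consumption drains
    (by-product formation and growth-composition demands, pinned by the
    measured growth rate and biomass composition). The maintenance
    pseudo-reaction is not measurable."""
    out = []
    for r in net.reactions:
        if r.id == "atpm":
            continue
        if (r.pathway_tag in ("exchange", "biomass")
                or all(n < 0 for n in r.stoich.values())):
            out.append(r.id)
    return out


def internal_metabolites(net: MetabolicNetwork) -> list[str]:
    """Metabolites balanced in the control analysis (clamped boundary species
    excluded)."""
    return [m.id for m in net.metabolites if m.id not in FULL_BOUNDARY]


def project_steady(N_int: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Orthogonal projection of measured fluxes onto the steady-state null
    space (smallest correction with N v = 0)."""
    correction = np.linalg.pinv(N_int) @ (N_int @ v)
    return v - correction


def reconcile_rates(net: MetabolicNetwork, v_meas: np.ndarray) -> np.ndarray:
    """Data reconciliation of measured rates: the smallest relative L1
    correction that restores flux balance within the reaction bounds
    (measurement noise is multiplicative, so deviations are weighted by the
    measured magnitudes). Deterministic (HiGHS)."""
    from scipy.optimize import linprog

    N = stoichiometric_matrix(net)
    n = len(net.reactions)
    w = 1.0 / np.maximum(np.abs(v_meas), 1e-6)
    # variables: v (n), t (n) with t >= w |v - v_meas|
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([N, np.zeros_like(N)])
    b_eq = np.zeros(N.shape[0])
    A_ub = np.block([
        [np.diag(w), -np.eye(n)],
        [-np.diag(w), -np.eye(n)],
    ])
    b_ub = np.concatenate([w * v_meas, -w * v_meas])
    bounds = [(r.flux_lb, r.flux_ub) for r in net.reactions]
    bounds += [(0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:
        raise ValidationError(f"rate reconciliation failed: {res.message}")
    return res.x[:n]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path):
    model = build_default_kinetic_model(config.preset, seed=config.model_seed)
    dataset = generate_perturbation_dataset(
        model, config.design(), noise_cv=config.noise_cv, seed=config.seed,
    )
    write_dataset(dataset, outdir)
    return model, dataset


def stage_tfa(config: PipelineConfig, model, dataset, outdir: Path
              ) -> tuple[tfa.TFAProblem, tfa.ThermoSolution]:
    net = model.network
    ref = dataset.reference
    # data reconciliation: raw noisy rates are mutually inconsistent with
    # the balances (structurally coupled rates are measured independently),
    # so the smallest relative correction restoring flux balance is applied
    # before deriving bounds
    v_rec = reconcile_rates(net, ref.v0)
    rates = {
        rid: float(v_rec[net.rxn_idx(rid)])
        for rid in measured_rate_reactions(net)
    }
    conc = {
        m.id: ref.conc(m.id) for m in net.metabolites if m.measured
    }
    problem = tfa.build_tfa_problem(
        net,
        measured_rates=tfa.widen_point_measurements(rates, config.rate_rel_width),
        measured_conc=tfa.widen_point_measurements(conc, config.conc_rel_width),
        gamma=config.gamma,
        bigM=config.bigM,
        epsilon_flux=config.epsilon_flux,
    )
    thermo = tfa.variability(problem)
    with open(outdir / "thermo_solution.json", "w") as fh:
        json.dump(thermo.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    rows = []
    classification = tfa.classify_equilibrium(thermo.drg_ranges,
                                              config.near_threshold)
    for rid in net.reaction_ids:
        row = {"reaction": rid,
               "flux_min": thermo.flux_ranges[rid][0],
               "flux_max": thermo.flux_ranges[rid][1],
               "direction": thermo.directions[rid]}
        if rid in thermo.drg_ranges:
            row["drg_min"], row["drg_max"] = thermo.drg_ranges[rid]
            row["equilibrium_class"] = classification[rid]
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "ranges.tsv", sep="\t", index=False,
                              float_format=_FLOAT_FMT)
    return problem, thermo


def stage_elasticity(config: PipelineConfig, model, dataset,
                     thermo: tfa.ThermoSolution, outdir: Path) -> ElasticityMatrix:
    net = model.network
    effectors = default_effectors(net, config.effectors_path)
    E = assemble_elasticity_matrix(
        net, thermo.drg_ranges, dataset.states, dataset.reference,
        effectors=effectors, threshold=config.near_threshold,
        skip_reactions=set(model.supply_rates),
    )
    write_elasticities(E, outdir / "elasticities.tsv")
    return E


def _enzyme_rows(net: MetabolicNetwork, model) -> list[str]:
    """Reactions reported as enzymes in FCC tables: everything except the
    feed-limited supply steps (boundary parameters, not enzymes)."""
    return [r.id for r in net.reactions if r.id not in model.supply_rates]


class _FastEBuilder:
    """Per-cycle elasticity rebuild.

    Near-equilibrium rows follow the thermokinetic formula at the cycle's
    sampled deltarG' (their uncertainty is thermodynamic). Far rows are
    re-fitted per cycle on a bootstrap resample of the perturbation states
    (their uncertainty is measurement-driven); averaging the control
    coefficients over cycles then bags the regression, which tames the
    instability of near-collinear noisy designs. The regression stays
    anchored to the measured reference state throughout.
    """

    def __init__(self, config, net, model, dataset, thermo, effectors,
                 internal, E_point, rng):
        from .constants import R as _R
        from .elasticity import default_regressors, regressor_sign_bounds

        self.RT = _R * net.temperature
        self.rng = rng
        self.int_pos = {m: k for k, m in enumerate(internal)}
        int_idx = [net.met_idx(m) for m in internal]
        self.E_base = E_point.values[:, int_idx].copy()
        classification = tfa.classify_equilibrium(
            thermo.drg_ranges, config.near_threshold)
        skip = set(model.supply_rates)
        ref = dataset.reference
        states = dataset.perturbed
        self.n_states = len(states)
        self.near_rows = []   # (j, rid, [(col, n_ij)], midpoint)
        self.far_rows = []    # (j, cols, G, y, lo, hi)
        for j, rxn in enumerate(net.reactions):
            if rxn.id in skip:
                continue
            if classification.get(rxn.id) == "near":
                entries = [
                    (self.int_pos[mid], n_ij)
                    for mid, n_ij in rxn.stoich.items() if mid in self.int_pos
                ]
                lo, hi = thermo.drg_ranges[rxn.id]
                self.near_rows.append((j, rxn.id, entries, 0.5 * (lo + hi)))
                continue
            v0 = ref.v0[j]
            if v0 == 0:
                continue
            regr = default_regressors(net, rxn.id, effectors, True,
                                      v_ref_sign=np.sign(v0))
            regr = [m for m in regr if m in self.int_pos]
            if not regr:
                continue
            cols = np.array([self.int_pos[m] for m in regr])
            G = np.array([
                [np.log(s.X0[s.metabolite_ids.index(m)]
                        / ref.X0[ref.metabolite_ids.index(m)]) for m in regr]
                for s in states
            ])
            y = np.array([
                (s.v0[j] / v0) * (ref.e0[j] / s.e0[j]) - 1.0 for s in states
            ])
            lo_mid0, hi_mid0 = thermo.drg_ranges.get(rxn.id, (0.0, 0.0))
            drg_mid0 = 0.5 * (lo_mid0 + hi_mid0)
            sb = regressor_sign_bounds(net, rxn.id, effectors, regr,
                                       np.sign(v0),
                                       drg=drg_mid0 if drg_mid0 else None)
            lo = np.array([sb.get(m, (-np.inf, np.inf))[0] for m in regr])
            hi = np.array([sb.get(m, (-np.inf, np.inf))[1] for m in regr])
            # thermodynamic sensitivities of uncovered participants: entries
            # scale as n_ij RT / deltarG'(cycle); measured ones also adjust
            # the regression response
            prod_cols, prod_n = [], []
            pm_cols, pm_lnX = [], []
            if rxn.id in thermo.drg_ranges:
                for mid, n_ij in rxn.stoich.items():
                    if mid in regr or mid not in self.int_pos:
                        continue
                    prod_cols.append(self.int_pos[mid])
                    prod_n.append(n_ij)
                    if net.metabolite(mid).measured:
                        pm_cols.append(len(prod_n) - 1)
                        pm_lnX.append([
                            np.log(s.X0[s.metabolite_ids.index(mid)]
                                   / ref.X0[ref.metabolite_ids.index(mid)])
                            for s in states
                        ])
            lo_mid, hi_mid = thermo.drg_ranges.get(rxn.id, (0.0, 0.0))
            self.far_rows.append((
                j, rxn.id, cols, G, y, lo, hi,
                np.array(prod_cols, dtype=int), np.array(prod_n),
                np.array(pm_cols, dtype=int),
                np.array(pm_lnX).T if pm_lnX else np.zeros((len(states), 0)),
                0.5 * (lo_mid + hi_mid),
            ))

    def build(self, X_draw: np.ndarray, drg_draw: dict[str, float]) -> np.ndarray:
        from .elasticity import _ridged_bounded_lstsq

        E = self.E_base.copy()
        boot = self.rng.integers(0, self.n_states, self.n_states)
        for (j, rid, cols, G, y, lo, hi, prod_cols, prod_n, pm_cols,
             pm_lnX, drg_mid) in self.far_rows:
            y_adj = y
            prod_coef = None
            if len(prod_cols):
                drg = drg_draw.get(rid, drg_mid)
                prod_coef = prod_n * self.RT / drg
                if len(pm_cols):
                    y_adj = y - pm_lnX @ prod_coef[pm_cols]
            Gb, yb = G[boot], y_adj[boot]
            span = np.abs(Gb).max(axis=0)
            keep = span > 1e-12
            if not keep.any():
                continue
            coef = _ridged_bounded_lstsq(Gb[:, keep], yb, lo[keep], hi[keep])
            E[j, :] = 0.0
            E[j, cols[keep]] = coef
            if prod_coef is not None:
                E[j, prod_cols] = prod_coef
        for j, rid, entries, mid in self.near_rows:
            drg = drg_draw.get(rid, mid)
            if drg == 0:
                raise ValidationError(f"{rid}: sampled deltarG' exactly zero")
            for col, n_ij in entries:
                E[j, col] = n_ij * self.RT / drg
        return E


def stage_mca(config: PipelineConfig, model, dataset,
              problem: tfa.TFAProblem, thermo: tfa.ThermoSolution,
              E: ElasticityMatrix, outdir: Path) -> mca.FCCResult:
    net = model.network
    effectors = default_effectors(net, config.effectors_path)
    internal = internal_metabolites(net)
    int_idx = [net.met_idx(m) for m in internal]
    N_int = stoichiometric_matrix(net)[int_idx]
    dec = decompose(N_int)
    ref = dataset.reference
    v0 = project_steady(N_int, ref.v0)
    X0 = ref.X0[int_idx]

    E_int = E.values[:, int_idx]
    try:
        point = mca.flux_control_coefficients(
            E_int, N_int, v0, X0, decomposition=dec,
            reaction_ids=net.reaction_ids,
        )
        point_diag = point.diagnostics
    except SingularSystemError as exc:
        # the point estimate can sit at a singular combination of estimated
        # elasticities; the Monte Carlo cycles below carry the result
        warnings.warn(f"point FCC computation singular: {exc}")
        point = None
        point_diag = {"singular": str(exc)}

    # Monte Carlo over jointly feasible TFA solutions: each cycle is one
    # hit-and-run sample (v0, deltarG', ln x) of the solution polytope, so
    # flux balance and the second law hold in every cycle.
    mc_seed = config.seed if config.mc_seed is None else config.mc_seed
    samples = tfa.sample_solutions(problem, n=config.n_cycles, seed=mc_seed)
    boot_rng = np.random.default_rng((mc_seed + 10007) % 2**31)
    builder = _FastEBuilder(config, net, model, dataset, thermo, effectors,
                            internal, E, boot_rng)
    lnc_cols = {m: k for k, m in enumerate(samples.lnc_columns)}
    drg_cols = {r: k for k, r in enumerate(samples.drg_columns)}
    C_samples = []
    dropped = 0
    for c in range(config.n_cycles):
        v_draw = samples.v[c]
        X_draw = X0.copy()
        for m, k in lnc_cols.items():
            if m in builder.int_pos:
                X_draw[builder.int_pos[m]] = np.exp(samples.lnc[c, k]) * 1e3
        drg_draw = {r: samples.drg[c, k] for r, k in drg_cols.items()}
        try:
            E_draw = builder.build(X_draw, drg_draw)
            res = mca.flux_control_coefficients(
                E_draw, N_int, v_draw, X_draw, decomposition=dec,
            )
        except Exception:
            dropped += 1
            continue
        C_samples.append(res.C)
    if dropped > 0.5 * config.n_cycles:
        raise ValidationError(
            f"model too ill-conditioned: {dropped}/{config.n_cycles} cycles dropped"
        )
    stack = np.stack(C_samples)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    # batch-means standard error of the mean: the cycles are a (thinned)
    # Markov chain, so residual autocorrelation must enter the uncertainty
    n_batches = min(50, len(stack))
    bs = len(stack) // n_batches
    batches = stack[: n_batches * bs].reshape(n_batches, bs, *stack.shape[1:])
    se_mean = batches.mean(axis=1).std(axis=0, ddof=1) / np.sqrt(n_batches)
    result = mca.FCCResult(
        C=mean,
        L0=point.L0 if point is not None else np.eye(len(dec.independent_idx)),
        reaction_ids=net.reaction_ids,
        summary={"mean": mean, "sd": sd, "se": se_mean,
                 "q05": np.quantile(stack, 0.05, axis=0),
                 "q95": np.quantile(stack, 0.95, axis=0)},
        diagnostics={"se_mean": se_mean},
        n_cycles=config.n_cycles, n_dropped=dropped,
    )

    enzymes = _enzyme_rows(net, model)
    enz_idx = [net.rxn_idx(r) for r in enzymes]
    fluxes = net.reaction_ids

    def save(mat: np.ndarray, name: str) -> None:
        pd.DataFrame(mat[enz_idx], index=enzymes, columns=fluxes).to_csv(
            outdir / name, sep="\t", float_format=_FLOAT_FMT,
            index_label="enzyme",
        )

    save(result.summary["mean"], "fcc_mean.tsv")
    save(result.summary["sd"], "fcc_sd.tsv")
    save(result.summary["se"], "fcc_se.tsv")
    save(result.summary["q05"], "fcc_q05.tsv")
    save(result.summary["q95"], "fcc_q95.tsv")
    diagnostics = {
        "point": point_diag,
        "n_cycles": result.n_cycles,
        "n_dropped": result.n_dropped,
        "max_abs_mean_fcc_enzymes": float(
            np.abs(result.summary["mean"][enz_idx]).max()
        ),
        "true_fcc_available": dataset.true_fcc is not None,
    }
    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=1, sort_keys=True)
        fh.write("\n")
    result.diagnostics.update(diagnostics)
    return result


def run_full(config: PipelineConfig) -> Path:
    """Run every stage and write the artifact set to config.output_dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"thermomca pipeline run (seed {config.seed}, preset {config.preset})",
        f"python {platform.python_version()}, numpy {np.__version__}",
        f"config: {config}",
    ]
    stage = "simulate"
    try:
        model, dataset = stage_simulate(config, outdir)
        log_lines.append(f"simulate: {len(dataset.states)} steady states")
        stage = "tfa"
        problem, thermo = stage_tfa(config, model, dataset, outdir)
        log_lines.append(f"tfa: optimum {thermo.optimum:.6g}")
        stage = "elasticity"
        E = stage_elasticity(config, model, dataset, thermo, outdir)
        log_lines.append(
            f"elasticity: {int(np.count_nonzero(E.values))} nonzero entries"
        )
        stage = "mca"
        result = stage_mca(config, model, dataset, problem, thermo, E, outdir)
        log_lines.append(
            f"mca: {result.n_cycles} cycles, {result.n_dropped} dropped"
        )
    except Exception as exc:
        log_lines.append(f"FAILED at stage {stage}: {exc}")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


def report(artifact_dir) -> dict[str, Path]:
    """Summary tables from a finished (or partial) pipeline run.

    Writes a per-condition flux table, a Gibbs-energy range table with the
    near/far classification, and (when the MCA stage ran) an FCC table.
    """
    artifact_dir = Path(artifact_dir)
    out = {}
    rates = artifact_dir / "rates.tsv"
    if not rates.exists():
        raise FileNotFoundError(f"missing artifact: {rates}")
    flux_table = artifact_dir / "flux_table.tsv"
    pd.read_csv(rates, sep="\t", index_col=0).to_csv(
        flux_table, sep="\t", float_format=_FLOAT_FMT)
    out["flux_table"] = flux_table

    ranges = artifact_dir / "ranges.tsv"
    if not ranges.exists():
        raise FileNotFoundError(f"missing artifact: {ranges}")
    gibbs = pd.read_csv(ranges, sep="\t")
    gibbs = gibbs[gibbs["drg_min"].notna()] if "drg_min" in gibbs else gibbs
    gibbs_table = artifact_dir / "gibbs_table.tsv"
    gibbs.to_csv(gibbs_table, sep="\t", index=False, float_format=_FLOAT_FMT)
    out["gibbs_table"] = gibbs_table

    fcc = artifact_dir / "fcc_mean.tsv"
    if fcc.exists():
        fcc_table = artifact_dir / "fcc_table.tsv"
        pd.read_csv(fcc, sep="\t", index_col=0).to_csv(
            fcc_table, sep="\t", float_format=_FLOAT_FMT)
        out["fcc_table"] = fcc_table
    else:
        print("notice: MCA stage artifacts missing; FCC summary skipped")
    return out
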
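"""Configuration-driven orchestration of the full analysis.

A single plain-text (YAML) configuration drives the stage chain
simulate -> qc -> varcomp -> structure -> ld -> gwas -> predict; every stage
writes TSV outputs plus a log entry with its parameters and seeds, and a
machine-readable summary collects the headline numbers.  The report
arithmetic comparing intra- and cross-environment predictive abilities
lives here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geno_qc, gs_engine, gwas_scan, ld_decay, pheno_varcomp, \
    pop_structure, simpop

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "varcomp", "structure", "ld", "gwas", "predict")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its inputs."""


@dataclass
class RunConfig:
    outdir: str = "lupinqg_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulate: dict = field(default_factory=dict)
    marker_missing_rate: float = 0.1
    marker_rate_concentration: float | None = 6.0
    sample_missing_rate: float = 0.02
    thresholds: tuple[float, ...] = (0.15, 0.20, 0.30)
    maf_min: float = 0.05
    impute_trees: int = 100
    impute_max_iter: int = 10
    k_max: int = 20
    kmeans_starts: int = 50
    ld_window_bp: int = 100_000
    gwas_alpha: float = 0.01
    gs_models: tuple[str, ...] = gs_engine.MODELS
    gs_folds: int = 10
    gs_repeats: int = 10
    gs_iterations: int = 10_000
    gs_burn_in: int = 1_000
    gs_traits: tuple[str, ...] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__annotations__}
        unknown = set(raw) - set(known)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "thresholds", "gs_models", "gs_traits"):
            if key in known and known[key] is not None:
                known[key] = tuple(known[key])
        return cls(**known)


def relative_decrease(intra_values, cross_value: float) -> int:
    """Percent decrease of cross-environment vs mean intra-environment
    predictive ability, rounded to the nearest integer percent:
    100 * (mean(intra) - cross) / mean(intra)."""
    intra = np.asarray(list(intra_values), dtype=float)
    if intra.size == 0:
        raise ValueError("intra list must be non-empty")
    m = intra.mean()
    if m == 0:
        raise ValueError("relative decrease undefined: mean intra ability is 0")
    return int(round(100.0 * (m - cross_value) / m))


def _write(df: pd.DataFrame, out: Path, name: str) -> None:
    df.to_csv(out / name, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the summary dictionary
    (also written to ``summary.yaml`` in the output directory)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    logger.info("run seed %d, stages %s", config.seed, config.stages)
    summary: dict = {"seed": config.seed}
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, state, summary, out)
            logger.info("stage %s done", stage)
        except Exception as exc:
            raise PipelineError(
                f"stage {stage!r} failed (inputs from "
                f"{sorted(state.keys())}): {exc}") from exc
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(_plain(summary), fh, sort_keys=False)
    return summary


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, state, summary, out: Path):
    sim = simpop.SimConfig(seed=config.seed, **config.simulate)
    pop = simpop.simulate_population(sim)
    pop = simpop.add_missing_genotypes(
        pop, config.marker_missing_rate, config.sample_missing_rate,
        seed=config.seed + 10,
        marker_rate_concentration=config.marker_rate_concentration)
    arch = simpop.default_architectures()
    if config.gs_traits:
        arch = {k: v for k, v in arch.items() if k in config.gs_traits}
    trial = simpop.simulate_trial(pop, arch, sim)
    simpop.write_vcf(pop, out / "genotypes.vcf")
    simpop.write_genotypes_tsv(pop, out / "genotypes.tsv")
    simpop.write_phenotypes_tsv(trial, out / "phenotypes.tsv")
    simpop.write_config(sim, out / "sim_config.tsv")
    state.update(sim=sim, pop=pop, trial=trial, arch=arch)
    summary["n_lines"] = pop.n_lines
    summary["n_markers"] = pop.n_markers


def _stage_qc(config: RunConfig, state, summary, out: Path):
    gm_raw = geno_qc.genotype_matrix_from_population(state["pop"])
    gm_by_thr = {}
    for thr in config.thresholds:
        gm_f, report = geno_qc.filter_genotypes(
            gm_raw, maf_min=config.maf_min, max_marker_missing=thr)
        gm_i = geno_qc.impute_missing(
            gm_f, n_trees=config.impute_trees,
            max_iter=config.impute_max_iter, seed=config.seed + 20)
        gm_by_thr[thr] = gm_i
        geno_qc.write_genotype_matrix(
            gm_i, out / f"genotypes_filtered_{thr:.2f}.tsv")
        report.to_frame().to_csv(out / f"filter_report_{thr:.2f}.tsv",
                                 sep="\t", index=False)
        summary.setdefault("markers_retained", {})[f"{thr:.2f}"] = \
            gm_i.n_markers
    state["gm_by_thr"] = gm_by_thr


def _stage_varcomp(config: RunConfig, state, summary, out: Path):
    table = state["trial"].records
    traits = sorted(table["trait"].unique())
    envs = sorted(table["env"].unique())
    vc_table = pheno_varcomp.varcomp_table(table, traits, envs)
    _write(vc_table, out, "variance_components.tsv")
    blups = {}
    rg = {}
    for t in traits:
        for e in envs:
            blups[(t, e)] = pheno_varcomp.compute_blups(table, t, e)
        if len(envs) == 2:
            rg[t] = pheno_varcomp.genetic_correlation(table, t, *envs)
    blup_frames = [b.to_frame() for b in blups.values()]
    _write(pd.concat(blup_frames, ignore_index=True), out, "blups.tsv")
    corr = pheno_varcomp.phenotypic_correlations(table, traits, envs[0])
    _write(corr, out, f"phenotypic_correlations_{envs[0]}.tsv")
    state.update(blups=blups, traits=traits, envs=envs)
    summary["genetic_correlations"] = {t: None if np.isnan(v) else round(v, 3)
                                       for t, v in rg.items()}
    summary["H2"] = {f"{r.trait}@{r.env}": round(r.H2, 3)
                     for r in vc_table.itertuples()}


def _stage_structure(config: RunConfig, state, summary, out: Path):
    thr = min(state["gm_by_thr"])
    gm = state["gm_by_thr"][thr]
    res = pop_structure.infer_structure(
        gm, k_max=config.k_max, n_starts=config.kmeans_starts,
        seed=config.seed + 30)
    pop_structure.write_structure(res, gm.samples, str(out / "structure"))
    state["structure"] = res
    state["structure_samples"] = gm.samples
    summary["chosen_K"] = int(res.chosen_k)
    summary["dapc_components_retained"] = \
        int(res.n_retained or 0) if res.chosen_k > 1 else 0


def _stage_ld(config: RunConfig, state, summary, out: Path):
    thr = max(state["gm_by_thr"])
    gm = state["gm_by_thr"][thr].sort_markers()
    res = ld_decay.ld_decay(gm, window_bp=config.ld_window_bp)
    _write(res.summary(), out, "ld_decay.tsv")
    res.pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
    state["ld"] = res
    summary["ld_half_decay_bp"] = (
        None if not res.genome.crossed else round(res.genome.half_decay_bp))
    summary["ld_r2_p90"] = round(res.genome.percentile90, 3)


def _aligned_covariates(state, samples) -> np.ndarray | None:
    res = state.get("structure")
    if res is None or res.chosen_k <= 1:
        return None
    src = pd.DataFrame(res.covariates, index=state["structure_samples"])
    # samples absent from the structure panel get the (zero) center of the
    # discriminant space
    return src.reindex(samples).fillna(0.0).to_numpy(float)


def _stage_gwas(config: RunConfig, state, summary, out: Path):
    thr = max(state["gm_by_thr"])
    gm = state["gm_by_thr"][thr]
    cov = _aligned_covariates(state, gm.samples)
    n_sig = {}
    frames = []
    for (t, e), blup in state["blups"].items():
        res = gwas_scan.marker_scan(blup.values, gm, cov,
                                    alpha=config.gwas_alpha, trait=t,
                                    environment=e)
        tab = res.table.assign(trait=t, env=e)
        frames.append(tab)
        n_sig[f"{t}@{e}"] = int(res.table["significant"].sum())
    _write(pd.concat(frames, ignore_index=True), out, "gwas_results.tsv")
    summary["gwas_significant_markers"] = n_sig
    state["gwas_covariates"] = cov


def _stage_predict(config: RunConfig, state, summary, out: Path):
    blups = state["blups"]
    envs = state["envs"]
    gm_by_thr = state["gm_by_thr"]
    phenos = {}
    for (t, e), b in blups.items():
        s = b.values.copy()          # indexed by line id, aligned per panel
        s.name = f"{t}@{e}"
        phenos[s.name] = s
    cov_by_thr = {thr: _aligned_covariates(state, gm.samples)
                  for thr, gm in gm_by_thr.items()}
    all_lines = state["pop"].line_ids
    cross_labels = pd.Series(
        [str(ln).split("_")[0] for ln in all_lines], index=all_lines)
    cross_pairs = None
    if len(envs) == 2:
        rg = summary.get("genetic_correlations", {})
        cross_pairs = {t: (f"{t}@{envs[0]}", f"{t}@{envs[1]}")
                       for t, v in rg.items()
                       if v is not None and v > 0.5}
    grid = gs_engine.run_grid(
        phenos, gm_by_thr, covariates_by_threshold=cov_by_thr,
        cross_labels=cross_labels, models=config.gs_models,
        cross_env_pairs=cross_pairs, folds=config.gs_folds,
        repeats=config.gs_repeats, iterations=config.gs_iterations,
        burn_in=config.gs_burn_in, seed=config.seed + 40)
    grid_out = grid.copy()
    grid_out["abilities"] = grid_out["abilities"].apply(
        lambda xs: ",".join(f"{x:.3f}" for x in xs))
    _write(grid_out, out, "prediction_grid.tsv")
    best = gs_engine.best_per_trait(grid)
    _write(best, out, "best_configurations.tsv")
    means = gs_engine.model_threshold_means(grid)
    means.to_csv(out / "model_threshold_means.tsv", sep="\t")
    report = {}
    if cross_pairs:
        for t, (k1, k2) in cross_pairs.items():
            intra = best[(best["scenario"] == "intra")
                         & (best["trait"].isin([k1, k2]))]["mean_ability"]
            cross = best[(best["scenario"] == "cross-env")
                         & (best["trait"] == t)]["mean_ability"]
            if len(intra) == 2 and len(cross) == 1:
                report[t] = relative_decrease(intra, float(cross.iloc[0]))
    summary["best_configurations"] = {
        f"{r.trait}[{r.scenario}]": round(r.mean_ability, 3)
        for r in best.itertuples()}
    summary["cross_env_relative_decrease_pct"] = report
    state["grid"] = grid


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "varcomp": _stage_varcomp,
    "structure": _stage_structure,
    "ld": _stage_ld,
    "gwas": _stage_gwas,
    "predict": _stage_predict,
}
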
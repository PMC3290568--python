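"""End-to-end orchestration of the analysis stages from one config.

Stages run in dependency order — synthetic-input generation, summary
statistics, coalescent null test, LD, iHS scan, allele age,
environmental correlation, dN/dS — each writing its outputs as files in
the run directory so any stage can be re-run or inspected in isolation.
The run report records per-stage outputs, dropped-site counts, seeds
and wall-clock times.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import age as age_mod
from . import dnds as dnds_mod
from . import envcorr as env_mod
from . import ihs as ihs_mod
from . import ld as ld_mod
from . import stats as stats_mod
from . import synth as synth_mod
from .coalescent import (
    MODEL_PRESETS,
    SimParams,
    null_distribution,
    neutrality_test,
    percentile,
)
from .types import HaplotypeMatrix, RegionSpec

log = logging.getLogger(__name__)

ALL_STAGES = ("synth", "stats", "nulltest", "ld", "ihs", "age", "envcorr", "dnds")

__version__ = "0.1.0"


@dataclass
class AnalysisConfig:
    """Validated run configuration; see ``demo_config`` for a template."""

    out_dir: str
    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # simulation / synthetic inputs
    n: int = 40
    L: int = 100_000
    theta_per_bp: float = 8e-4
    rho_per_bp: float = 4e-4
    conv_ratio_f: float = 2.0
    tract_mean: float = 500.0
    null_model: str = "constant"
    null_reps: int = 500
    # regions (hotspot boundary splits the locus)
    regions: list[dict] = field(default_factory=list)
    # sweep scenario for ihs/age stages
    sweep_frequency: float = 0.6
    sweep_age_generations: float = 400.0
    sweep_morgans_per_bp: float = 1e-7
    max_cluster_gap: int = 20_000
    # calibration constants
    generation_time_years: float = age_mod.DEFAULT_GENERATION_TIME
    split_time_years: float = age_mod.DEFAULT_SPLIT_TIME_YEARS
    mu_per_marker: float = age_mod.DEFAULT_MU_PER_MARKER
    # environmental correlation scenario
    env_populations: int = 50
    env_countries: int = 21
    env_effect_tau: float = 0.4
    env_noise_sd: float = 0.05
    # codon selection scenario
    codons: int = 300
    tree_scale: float = 0.05
    omega_true: float = 0.2

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def validate_config(cfg: AnalysisConfig) -> list[str]:
    """Collect (not raise) configuration errors."""
    errors = []
    for name in ("theta_per_bp", "rho_per_bp", "generation_time_years",
                 "split_time_years", "mu_per_marker", "tree_scale"):
        if getattr(cfg, name) <= 0:
            errors.append(f"{name} must be positive")
    if cfg.n < 4:
        errors.append("n must be >= 4")
    if cfg.null_model not in MODEL_PRESETS:
        errors.append(f"unknown null model {cfg.null_model!r}")
    unknown = set(cfg.stages) - set(ALL_STAGES)
    if unknown:
        errors.append(f"unknown stages: {sorted(unknown)}")
    for r in cfg.regions:
        if not {"label", "start", "end"} <= set(r):
            errors.append(f"region missing keys: {r}")
    return errors


@dataclass
class RunReport:
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def run_pipeline(cfg: AnalysisConfig) -> RunReport:
    """Execute the configured stages; halt with a partial report on failure."""
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed, version=__version__)
    rng = np.random.default_rng(cfg.seed)
    params = SimParams(
        n=cfg.n, L=cfg.L, theta_per_bp=cfg.theta_per_bp,
        rho_per_bp=cfg.rho_per_bp, conv_ratio_f=cfg.conv_ratio_f,
        tract_mean=cfg.tract_mean, reps=max(cfg.null_reps, 100), seed=cfg.seed,
    )
    model = MODEL_PRESETS[cfg.null_model]
    state: dict = {}

    def stage(name):
        def deco(fn):
            if name in cfg.stages:
                t0 = time.time()
                try:
                    outputs = fn()
                except Exception as exc:  # halt, keep partial report
                    report.failed_stage = name
                    report.stages[name] = {"error": str(exc)}
                    report.save(out / "run_report.json")
                    raise
                report.stages[name] = {
                    "outputs": outputs, "seconds": round(time.time() - t0, 2)
                }
            return fn
        return deco

    @stage("synth")
    def _synth():
        h = synth_mod.generate_neutral(params, model, rng)
        sw, truth = synth_mod.inject_sweep(
            h,
            synth_mod.SweepScenario(
                cfg.sweep_frequency, cfg.sweep_age_generations,
                morgans_per_bp=cfg.sweep_morgans_per_bp,
            ),
            rng,
        )
        state["haplotypes"] = sw
        state["truth"] = truth
        from .io import write_phased_haplotypes

        write_phased_haplotypes(sw, out / "haplotypes.phased.txt")
        (out / "sweep_truth.json").write_text(json.dumps(truth, indent=2))
        return ["haplotypes.phased.txt", "sweep_truth.json"]

    @stage("stats")
    def _stats():
        h = state["haplotypes"]
        regions = [
            RegionSpec(r["label"], r["start"], r["end"],
                       r.get("L_surveyed", r["end"] - r["start"]))
            for r in cfg.regions
        ] or [RegionSpec("full", 1, cfg.L + 1, cfg.L)]
        rows = []
        for r in regions:
            s = stats_mod.summarize_region(h, r)
            row = {"region": r.label, **s.as_row()}
            rows.append(row)
        df = pd.DataFrame(rows)
        df.to_csv(out / "summary_stats.tsv", sep="\t", index=False)
        state["summary"] = stats_mod.summarize(h, cfg.L)
        return ["summary_stats.tsv"]

    @stage("nulltest")
    def _nulltest():
        obs = state.get("summary") or stats_mod.summarize(state["haplotypes"], cfg.L)
        results = {}
        for statistic, value in (
            ("pi_per_bp", obs.pi_per_bp), ("tajima_d", obs.tajima_d),
        ):
            nd = null_distribution(params, model, statistic)
            p, flag = neutrality_test(value, nd, statistic)
            results[statistic] = {
                "observed": value,
                "p975": percentile(nd, 97.5),
                "p_value": p,
                "significant": flag,
                "reps_used": len(nd.values),
            }
        (out / "null_test.json").write_text(json.dumps(results, indent=2))
        return ["null_test.json"]

    @stage("ld")
    def _ld():
        df = ld_mod.ld_matrix(state["haplotypes"])
        df.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
        groups = ld_mod.complete_ld_groups(df)
        (out / "complete_ld_groups.json").write_text(
            json.dumps([sorted(g) for g in groups], indent=2)
        )
        return ["ld_pairs.tsv", "complete_ld_groups.json"]

    @stage("ihs")
    def _ihs():
        h = state["haplotypes"]
        res = ihs_mod.standardize_ihs(ihs_mod.scan_ihs(h))
        df = ihs_mod.results_table(res)
        df.to_csv(out / "ihs.tsv", sep="\t", index=False)
        clusters = ihs_mod.cluster_significant(res, cfg.max_cluster_gap)
        bed = out / "ihs_clusters.bed"
        with open(bed, "w") as fh:
            for c in clusters:
                fh.write(f"region\t{c[0].position - 1}\t{c[-1].position}\t"
                         f"n={len(c)}\n")
        state["ihs"] = res
        return ["ihs.tsv", "ihs_clusters.bed"]

    @stage("age")
    def _age():
        h = state["haplotypes"]
        truth = state["truth"]
        non_carriers = [
            i for i in range(h.n_hap) if i not in set(truth["carriers"])
        ]
        cases = HaplotypeMatrix(
            h.haplotypes[truth["carriers"]], h.positions
        )
        controls = HaplotypeMatrix(h.haplotypes[non_carriers], h.positions)
        est = age_mod.dhs_tau(
            cases, truth["core_site"], controls=controls,
            morgans_per_bp=cfg.sweep_morgans_per_bp,
            mu_per_marker=cfg.mu_per_marker,
            generation_time=cfg.generation_time_years,
            n_bootstrap=200, rng=rng,
        )
        payload = {
            "tau": est.tau, "generations": est.generations,
            "years": est.years, "n_cases": est.n_cases,
            "censored": est.censored, "ci_generations": est.ci_generations,
            "true_age_generations": truth["age_generations"],
        }
        (out / "allele_age.json").write_text(json.dumps(payload, indent=2))
        return ["allele_age.json"]

    @stage("envcorr")
    def _envcorr():
        ft, pm, truth = synth_mod.generate_env_table(
            synth_mod.EnvEffectScenario(
                cfg.env_populations, cfg.env_countries,
                cfg.env_effect_tau, cfg.env_noise_sd,
            ),
            rng,
        )
        richness = env_mod.pathogen_richness(pm)
        res = env_mod.correlate_frequencies(ft, richness)
        res.to_csv(out / "env_correlation.tsv", sep="\t", index=False)
        ft.to_csv(out / "population_frequencies.tsv", sep="\t", index=False)
        pm.to_csv(out / "pathogen_matrix.tsv", sep="\t", index=False)
        return ["env_correlation.tsv", "population_frequencies.tsv",
                "pathogen_matrix.tsv"]

    @stage("dnds")
    def _dnds():
        aln, truth = synth_mod.generate_codon_alignment(
            cfg.codons, cfg.tree_scale, cfg.omega_true, rng
        )
        rows = []
        for i in range(len(aln.taxa)):
            for j in range(i + 1, len(aln.taxa)):
                r = dnds_mod.pairwise_dnds(aln.sequences[i], aln.sequences[j])
                rows.append({
                    "pair": f"{aln.taxa[i]}-{aln.taxa[j]}",
                    "dN": r.dN, "dS": r.dS, "omega": r.omega,
                    "class": dnds_mod.classify_omega(r.omega),
                })
        pd.DataFrame(rows).to_csv(out / "dnds.tsv", sep="\t", index=False)
        changes = dnds_mod.lineage_changes(aln, aln.taxa[0], list(aln.taxa[1:]))
        pd.DataFrame([asdict(c) for c in changes]).to_csv(
            out / "lineage_changes.tsv", sep="\t", index=False
        )
        return ["dnds.tsv", "lineage_changes.tsv"]

    report.save(out / "run_report.json")
    return report
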
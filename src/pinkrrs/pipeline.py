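"""End-to-end orchestration: simulate -> assign -> RRS -> GLM -> power.

A run executes stages in order with per-stage seed substreams derived from
one master seed, writes every table as CSV into an output directory, and
finishes with a machine-readable JSON manifest (config echo, checksums,
per-stage status). Reruns with an identical config and seed are
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import glm as glm_mod
from . import parentage, rrs
from .io import file_checksum, get_logger, load_config, read_genotype_table, \
    read_panel, read_sample_table, write_genotype_table, write_panel, \
    write_sample_table
from .records import Config
from .simulate import (CovariateSpec, ReproConfig, apply_carcass_sampling,
                       make_panel, simulate_genotypes, simulate_reproduction,
                       simulate_spawners)

__all__ = ["RunReport", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunReport:
    out_dir: Path
    config: dict
    seeds: dict
    stages: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "config": self.config,
            "seeds": self.seeds,
            "stages": self.stages,
            "tables": {k: str(v) for k, v in self.tables.items()},
            "checksums": {k: file_checksum(v) for k, v in self.tables.items()},
        }


def _save(report: RunReport, name: str, df: pd.DataFrame) -> None:
    path = report.out_dir / f"{name}.csv"
    df.to_csv(path, index=False)
    report.tables[name] = path


def run_pipeline(
    cfg: Optional[Config] = None,
    out_dir: str = "pinkrrs_run",
    seed: Optional[int] = None,
    n_parents: int = 600,
    phos: float = 0.5,
    repro: Optional[ReproConfig] = None,
    sample_table: Optional[str] = None,
    genotype_table: Optional[str] = None,
    panel_table: Optional[str] = None,
    run_power: bool = False,
) -> RunReport:
    """Run the full pipeline, synthetic by default.

    In synthetic mode a spawner cohort, true pedigree and genotypes are
    generated, offspring are carcass-sampled at the configured fraction,
    and the true pedigree CSV is kept alongside for validation. With
    ``sample_table``/``genotype_table``/``panel_table`` the assignment and
    statistics stages run on user data instead. Partial failure leaves the
    completed artifacts plus a status manifest.
    """
    cfg = cfg or Config()
    if seed is None:
        seed = cfg.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = get_logger("pinkrrs.pipeline")
    seeds = {name: int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
             for i, name in enumerate(
                 ["panel", "spawners", "reproduction", "genotypes",
                  "sampling", "stats", "power"])}
    report = RunReport(out_dir=out, config=cfg.to_dict(), seeds=seeds)
    log.info("run seed=%s out=%s", seed, out)

    truth = None
    try:
        if sample_table is None:
            panel = make_panel(seed=seeds["panel"])
            parents = simulate_spawners(
                n_parents, phos, seed=seeds["spawners"],
                intertidal_boundary_m=cfg.intertidal_boundary_m,
                covariate_spec=CovariateSpec(stream_length_m=cfg.stream_length_m),
            )
            truth, offspring_cohort = simulate_reproduction(
                parents, repro or ReproConfig(), seed=seeds["reproduction"],
            )
            sampled_offspring = apply_carcass_sampling(
                offspring_cohort, cfg.offspring_sampling_fraction,
                seed=seeds["sampling"],
            )
            genotypes = simulate_genotypes(
                truth, parents["sample_id"].tolist(),
                sampled_offspring["sample_id"].tolist(), panel,
                eps=cfg.genotyping_error_rate, miss=cfg.missing_rate,
                seed=seeds["genotypes"],
            )
            _save(report, "parents", parents)
            _save(report, "offspring", sampled_offspring)
            _save(report, "true_pedigree", truth.links)
            write_panel(panel, out / "panel.csv")
            report.tables["panel"] = out / "panel.csv"
            write_genotype_table(genotypes, out / "genotypes.csv")
            report.tables["genotypes"] = out / "genotypes.csv"
        else:
            panel = read_panel(panel_table)
            samples = read_sample_table(sample_table)
            genotypes = read_genotype_table(genotype_table, panel)
            years = sorted(samples["year"].unique())
            parents = samples[samples["year"] == years[0]].reset_index(drop=True)
            sampled_offspring = samples[samples["year"] == years[0] + 2].reset_index(drop=True)
        report.stages["simulate"] = "ok"
    except Exception as e:
        report.stages["simulate"] = f"error: {e}"
        _write_manifest(report)
        raise StageError("simulate", str(e)) from e

    try:
        phos_table = rrs.compute_phos(parents, strata=["stream", "year"])
        _save(report, "phos", phos_table)
        cand_geno = genotypes.subset(
            [s for s in parents["sample_id"] if s in genotypes])
        off_geno = genotypes.subset(
            [s for s in sampled_offspring["sample_id"] if s in genotypes])
        assignments = parentage.assign_parentage(off_geno, parents, cand_geno, cfg)
        _save(report, "assignments", assignments)
        summary = assignments["kind"].value_counts().to_dict()
        report.stages["assign"] = {"ok": True, **{k: int(v) for k, v in summary.items()}}
    except Exception as e:
        report.stages["assign"] = f"error: {e}"
        _write_manifest(report)
        raise StageError("assign", str(e)) from e

    try:
        rs_table = rrs.tabulate_rs(assignments, parents)
        _save(report, "rs_table", rs_table)
        rrs_by_sex = rrs.unweighted_rrs(rs_table, by_sex=True,
                                        n_perm=cfg.n_permutations, seed=seeds["stats"])
        rrs_all = rrs.unweighted_rrs(rs_table, by_sex=False,
                                     n_perm=cfg.n_permutations, seed=seeds["stats"])
        _save(report, "rrs", pd.concat([rrs_by_sex, rrs_all], ignore_index=True))
        contrasts = rrs.covariate_contrasts(parents)
        _save(report, "contrasts", contrasts)
        if (assignments["kind"] == "triad").any():
            crosses, cross_p = rrs.cross_type_rs(
                assignments, parents, n_perm=cfg.n_permutations,
                seed=seeds["stats"])
            _save(report, "cross_types", crosses)
            _save(report, "cross_type_pvalues", cross_p)
        report.stages["rrs"] = "ok"
    except Exception as e:
        report.stages["rrs"] = f"error: {e}"
        _write_manifest(report)
        raise StageError("rrs", str(e)) from e

    try:
        for sex in ("F", "M"):
            data = rs_table[rs_table["sex"] == sex]
            try:
                models = glm_mod.enumerate_models(include_sex=False)
                ranking, best = glm_mod.select_model(
                    models, data,
                    min_offspring_per_origin=cfg.glm_min_offspring_per_origin)
            except glm_mod.EligibilityError as e:
                report.stages[f"glm_{sex}"] = f"refused: {e}"
                continue
            # re-fit the selected model with profile-likelihood CIs
            best = glm_mod.fit_nb_glm(data, best.terms, ci_method="profile")
            _save(report, f"glm_ranking_{sex}", ranking)
            coef = best.incident_ratios.copy()
            coef.insert(0, "term", coef.index)
            if best.terms:
                hp = glm_mod.hierarchical_partitioning(data, best.terms)
                coef = coef.merge(
                    hp.rename(columns={"variable": "term"})[["term", "pct_ie"]],
                    on="term", how="left")
            _save(report, f"glm_coefficients_{sex}", coef)
        report.stages["glm"] = "ok"
    except Exception as e:
        report.stages["glm"] = f"error: {e}"
        _write_manifest(report)
        raise StageError("glm", str(e)) from e

    if run_power:
        from .power import power_grid
        grid = power_grid(
            m_values=[0.5, 1, 2, 4], k_values=[1.0], p_values=[0.25, 1.0],
            n_h=437, n_n=214, n_reps=200, seed=seeds["power"])
        _save(report, "power_grid", grid.cells)
        report.stages["power"] = "ok"

    _write_manifest(report)
    log.info("run complete: %s", {k: v for k, v in report.stages.items()})
    return report


def _write_manifest(report: RunReport) -> None:
    (report.out_dir / "manifest.json").write_text(
        json.dumps(report.manifest(), indent=2, default=str)
    )
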
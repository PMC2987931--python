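"""End-to-end pipeline wiring: simulate -> msnp-mi -> call-diff ->
classify -> validate -> express, with config hashing, per-stage logging
and a machine-readable summary.

Every output file is stamped with the tool version and seed; the summary
carries a hash of the semantic configuration so identical runs are
byte-identical and config changes are detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .classify import loocv
from .diffmeth import call_differential, gene_level_summary, remove_sex_probes, supervised_cluster
from .expression import dose_response_trend, group_expression_test, relative_expression_table
from .msnp import run_msnp
from .simulate import SimulatedCohort, generate_cohort, table1_default_config
from .types import ValidationError, criteria_preset
from .validation import (
    age_adjusted_group_test,
    cohort_stability_summary,
    pyroseq_sample_means,
    stability_over_time,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "msnp-mi", "call-diff", "classify", "validate", "express")


@dataclass
class RunConfig:
    """Pipeline run description (parsed from YAML by the CLI)."""

    seed: int
    out_dir: str
    stages: tuple = STAGES
    criteria: str = "pbl"
    ridge_lambda: float = 1e-8
    selection: str = "fixed_panel"
    mi_mode: str = "ratio"
    intermediate_band: tuple = (0.25, 0.75)
    cohort_overrides: dict = field(default_factory=dict)

    def semantic_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # output location is not semantic
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


class _StageLog:
    """Line-delimited structured run log."""

    def __init__(self, path: Path):
        self.path = path
        self.records = []

    def add(self, stage: str, **counts) -> None:
        rec = {"stage": stage, **counts}
        self.records.append(rec)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=_jsonable) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and return the summary dict.

    A requested stage whose upstream output is absent raises a
    :class:`ValidationError` naming the stage.
    """
    bad = [s for s in config.stages if s not in STAGES]
    if bad:
        raise ValidationError(f"unknown stages: {bad}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_path.unlink(missing_ok=True)
    log = _StageLog(log_path)
    seed = config.seed

    summary: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": config.config_hash(),
        "stages": list(config.stages),
        "n_calls": 0,
    }

    cohort: SimulatedCohort | None = None
    if "simulate" in config.stages:
        cconfig = table1_default_config(seed=seed, **config.cohort_overrides)
        cohort = generate_cohort(cconfig)
        io.write_sample_sheet(cohort.sheet, out / "sample_sheet.tsv", seed=seed)
        io.write_beta_matrix(cohort.beta, out / "beta.tsv", seed=seed)
        io.write_annotation(cohort.annotation, out / "annotation.tsv", seed=seed)
        if cohort.msnp is not None:
            io.write_long_table(cohort.msnp, out / "msnp_intensities.tsv", seed=seed)
        if cohort.pyroseq is not None:
            io.write_long_table(cohort.pyroseq, out / "pyroseq.tsv", seed=seed)
        if cohort.ct is not None:
            io.write_long_table(cohort.ct, out / "qpcr_ct.tsv", seed=seed)
        if cohort.dose is not None:
            io.write_long_table(cohort.dose, out / "aza_dose_response.tsv", seed=seed)
        log.add("simulate", n_samples=len(cohort.sheet.table),
                n_loci=len(cohort.beta.probes), n_clipped=cohort.n_clipped)
        summary["n_samples"] = len(cohort.sheet.table)
        summary["n_loci"] = len(cohort.beta.probes)

    def _need(path: Path, stage: str) -> Path:
        if not path.exists():
            raise ValidationError(f"stage {stage!r} needs missing upstream output {path.name}")
        return path

    if "msnp-mi" in config.stages:
        msnp_tab = cohort.msnp if cohort is not None else \
            io.read_long_table(_need(out / "msnp_intensities.tsv", "msnp-mi"))
        res = run_msnp(msnp_tab, mode=config.mi_mode)
        io.write_beta_matrix(res.beta, out / "msnp_mi_beta.tsv", seed=seed)
        log.add("msnp-mi", n_probes_in=int(msnp_tab["probe_id"].nunique()),
                n_class2=int(res.class2["class2_pass"].sum()),
                n_mi_clipped=res.mi.attrs.get("n_clipped", 0))
        summary["n_class2"] = int(res.class2["class2_pass"].sum())

    calls = None
    if "call-diff" in config.stages:
        if cohort is not None:
            beta, sheet, annotation = cohort.beta, cohort.sheet, cohort.annotation
        else:
            beta = io.read_beta_matrix(_need(out / "beta.tsv", "call-diff"))
            sheet = io.read_sample_sheet(_need(out / "sample_sheet.tsv", "call-diff"))
            annotation = io.read_annotation(_need(out / "annotation.tsv", "call-diff"))
        criteria = criteria_preset(config.criteria)
        unique = sheet.unique_cases()
        beta_u = beta.subset_samples(unique.table["sample_id"].tolist())
        if criteria.exclude_sex_chroms:
            beta_u = remove_sex_probes(beta_u, annotation)
        groups = unique.groups_for(beta_u.samples)
        calls = call_differential(beta_u, groups, criteria)
        io.write_results_table(calls, out / "diffmeth_calls.tsv", seed=seed)
        passed = calls[calls["passed"]]
        io.export_bed(passed, annotation, out / "diffmeth_calls.bed", seed=seed)
        if len(passed) >= 2:
            clust = supervised_cluster(beta_u.subset_probes(passed["probe_id"].tolist()))
            (out / "cluster_order.txt").write_text(
                "# samples\n" + "\n".join(clust["sample_order"]) +
                "\n# loci\n" + "\n".join(clust["locus_order"]) + "\n")
        gsum = gene_level_summary(calls, annotation)
        log.add("call-diff", n_loci_in=len(calls), n_passed=int(passed.shape[0]),
                n_genes=gsum["n_genes_passed"])
        summary["n_calls"] = int(passed.shape[0])
        summary["n_genes_called"] = gsum["n_genes_passed"]

    if "classify" in config.stages:
        if cohort is not None:
            beta, sheet = cohort.beta, cohort.sheet
        else:
            beta = io.read_beta_matrix(_need(out / "beta.tsv", "classify"))
            sheet = io.read_sample_sheet(_need(out / "sample_sheet.tsv", "classify"))
        if calls is None:
            calls_path = out / "diffmeth_calls.tsv"
            if calls_path.exists():
                calls = io.read_long_table(calls_path)
        if calls is None or not calls["passed"].any():
            raise ValidationError("stage 'classify' needs a non-empty panel from 'call-diff'")
        panel = calls.loc[calls["passed"], "probe_id"].tolist()
        unique = sheet.unique_cases()
        features = beta.subset_probes(panel).subset_samples(
            unique.table["sample_id"].tolist()).values.T
        labels = unique.groups_for(list(features.index))
        report = loocv(features, labels.to_numpy(), ridge_lambda=config.ridge_lambda,
                       feature_selection="fixed_panel", band=config.intermediate_band)
        report.predictions.to_csv(out / "classifier_predictions.tsv", sep="\t", index=False)
        log.add("classify", n_folds=report.n_folds,
                sensitivity=report.sensitivity, specificity=report.specificity)
        summary["sensitivity"] = report.sensitivity
        summary["specificity"] = report.specificity
        summary["n_panel"] = len(panel)

    if "validate" in config.stages:
        if cohort is not None and cohort.pyroseq is not None:
            pyro, sheet = cohort.pyroseq, cohort.sheet
        else:
            pyro = io.read_long_table(_need(out / "pyroseq.tsv", "validate"))
            sheet = io.read_sample_sheet(_need(out / "sample_sheet.tsv", "validate"))
        means = pyroseq_sample_means(pyro)
        meta = sheet.table.set_index("sample_id")
        means = means.join(meta[["group", "age", "individual_id", "timepoint_index",
                                 "mosaic_fraction"]], on="sample_id")
        rows = []
        for gene, sub in means.groupby("gene", sort=False):
            u = sub[sub["timepoint_index"] == 0]
            res = age_adjusted_group_test(u["region_mean"], u["age"], u["group"])
            rows.append({"gene": gene, **res})
        val = pd.DataFrame(rows)
        io.write_results_table(val, out / "validation_age_adjusted.tsv", seed=seed)
        stab = stability_over_time(means.rename(columns={"region_mean": "region_mean"}))
        stab_summary = cohort_stability_summary(stab)
        summary["validation_max_p"] = float(val["p_methylation"].max())
        med = stab_summary["median_range"]
        summary["stability_median_range"] = None if np.isnan(med) else med
        log.add("validate", n_genes=len(val), **stab_summary)

    if "express" in config.stages:
        if cohort is not None and cohort.ct is not None:
            ct_df, dose_df, sheet = cohort.ct, cohort.dose, cohort.sheet
        else:
            ct_df = io.read_long_table(_need(out / "qpcr_ct.tsv", "express"))
            dose_df = io.read_long_table(_need(out / "aza_dose_response.tsv", "express"))
            sheet = io.read_sample_sheet(_need(out / "sample_sheet.tsv", "express"))
        rel = relative_expression_table(ct_df)
        grp = sheet.table.set_index("sample_id")["group"]
        rows = []
        for gene, sub in rel.groupby("gene", sort=False):
            res = group_expression_test(sub["relative_expression"],
                                        grp.loc[sub["sample_id"]].to_numpy())
            rows.append({"gene": gene, **res})
        expr = pd.DataFrame(rows)
        io.write_results_table(expr, out / "expression_group_tests.tsv", seed=seed)
        trend_rows = []
        if dose_df is not None and len(dose_df):
            for (gene, cond), sub in dose_df.groupby(["gene", "condition"], sort=False):
                res = dose_response_trend(sub["dose"], sub["expression"])
                trend_rows.append({"gene": gene, "condition": cond, **res})
        trends = pd.DataFrame(trend_rows)
        io.write_results_table(trends, out / "aza_dose_trends.tsv", seed=seed)
        log.add("express", n_genes=len(expr), n_dose_series=len(trends))
        summary["n_expression_genes"] = len(expr)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return summary
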
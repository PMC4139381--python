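"""End-to-end orchestration: simulate -> preprocess -> classify ->
compare -> enrich -> permute, with a JSON run manifest.

Every stage writes flat TSV/JSON outputs (diffable in tests); the
manifest records the config snapshot, input hashes, the master seed and
per-stage output paths, so an identical manifest reproduces identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from . import __version__
from .datatypes import AnalysisThresholds, SurvivalCohort, ValidationError
from .expression_io import median_scale_normalize, write_expression_table, write_clinical_table
from .pattern_classification import build_pattern_catalog, classify_genes, ptn_counts
from .signature_permutation import compare_lists, make_random_baseline, permutation_run
from .synthetic_data import (
    SyntheticConfig,
    generate_qpcr_table,
    generate_staged_expression,
    generate_tumor_cohorts,
)
from .tumor_comparison import adc_related_genes, monotone_trend_stat, ptn_enrichment

logger = logging.getLogger(__name__)

_CONFIG_KEYS = {"seed", "outdir", "synthetic", "thresholds", "candidate_list_size_cap"}
_THRESH_KEYS = {f.name for f in dataclasses.fields(AnalysisThresholds)}
_SYN_KEYS = {f.name for f in dataclasses.fields(SyntheticConfig)}


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    unknown = set(cfg.get("thresholds", {})) - _THRESH_KEYS
    if unknown:
        raise ValidationError(f"unknown threshold keys: {sorted(unknown)}")
    unknown = set(cfg.get("synthetic", {})) - _SYN_KEYS
    if unknown:
        raise ValidationError(f"unknown synthetic keys: {sorted(unknown)}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build(cfg: dict, seed: int | None):
    syn = dict(cfg.get("synthetic", {}))
    if seed is not None:
        syn["master_seed"] = seed
    if "samples_per_stage" in syn:
        syn["samples_per_stage"] = tuple(syn["samples_per_stage"])
    if "patients_per_cohort" in syn and not isinstance(syn["patients_per_cohort"], int):
        syn["patients_per_cohort"] = tuple(syn["patients_per_cohort"])
    th = dict(cfg.get("thresholds", {}))
    if "n_values" in th:
        th["n_values"] = tuple(th["n_values"])
    return SyntheticConfig(**syn), AnalysisThresholds(**th)


def subgroup_filter(cohort: SurvivalCohort, stage_selector: str) -> SurvivalCohort:
    """Restrict a cohort to patients with a matching TNM stage."""
    if "tnm_stage" not in cohort.clinical.data.columns:
        raise ValidationError(f"cohort {cohort.cohort_label!r} lacks tnm_stage")
    keep = cohort.clinical.data["tnm_stage"] == stage_selector
    if not keep.any():
        raise ValidationError(f"no patients with stage {stage_selector!r}")
    logger.info("subgroup %s: %d of %d patients kept",
                stage_selector, int(keep.sum()), len(keep))
    clin = type(cohort.clinical)(cohort.clinical.data.loc[keep])
    return SurvivalCohort(f"{cohort.cohort_label}_stage{stage_selector}", clin,
                          cohort.expression.subset_samples(clin.sample_ids))


def run_pipeline(config_path, *, outdir=None, seed: int | None = None) -> dict:
    """Execute the full synthetic pipeline and return the run manifest."""
    cfg = load_config(config_path)
    outdir = Path(outdir or cfg.get("outdir", "devptn_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else int(cfg.get("seed", 0))
    syncfg, thresholds = _build(cfg, seed)

    manifest: dict = {
        "version": __version__,
        "master_seed": seed,
        "config": cfg,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    # simulate + preprocess
    matrix, design, truth = generate_staged_expression(syncfg)
    matrix = median_scale_normalize(matrix)
    cohorts, truth = generate_tumor_cohorts(syncfg, truth)
    dev_path = outdir / "developmental_expression.tsv"
    write_expression_table(matrix, dev_path)
    truth.to_json(outdir / "truth.json")
    for cohort in cohorts:
        write_expression_table(cohort.expression, outdir / f"{cohort.cohort_label}_expression.tsv")
        write_clinical_table(cohort.clinical, outdir / f"{cohort.cohort_label}_clinical.tsv")
    manifest["stages"]["simulate"] = {"developmental": str(dev_path),
                                      "truth": str(outdir / "truth.json"),
                                      "cohorts": [c.cohort_label for c in cohorts]}

    # classify
    catalog = build_pattern_catalog(design.n_transitions)
    assignment = classify_genes(matrix, design, thresholds, catalog=catalog)
    assignment.to_csv(outdir / "pattern_assignment.tsv", sep="\t")
    counts = ptn_counts(assignment, catalog)
    counts.rename("gene_count").to_csv(outdir / "ptn_counts.tsv", sep="\t")
    (outdir / "pattern_catalog.json").write_text(
        json.dumps({c: i for c, i in catalog.code_to_index.items()}, indent=1))
    manifest["stages"]["classify"] = {"assignment": str(outdir / "pattern_assignment.tsv"),
                                      "counts": counts.to_dict()}

    # compare: tumor cohort 0 vs MatureL samples of the developmental matrix
    mature = matrix.subset_samples(design.samples_for(design.ordered_stages[-1]))
    tumor = cohorts[0].expression
    shared = sorted(set(mature.gene_ids) & set(tumor.gene_ids))
    sets = adc_related_genes(tumor.subset_genes(shared), mature.subset_genes(shared), thresholds)
    sets.table.to_csv(outdir / "adc_related_genes.tsv", sep="\t")
    enrich = ptn_enrichment(sets, assignment.loc[assignment.index.isin(shared)])
    enrich.to_csv(outdir / "ptn_enrichment.tsv", sep="\t", index=False)
    trend = None
    try:
        rho, p = monotone_trend_stat(enrich)
        trend = {"spearman_rho": rho, "p": p}
    except ValidationError:
        pass
    manifest["stages"]["compare"] = {"n_up": len(sets.up_genes), "n_down": len(sets.down_genes),
                                     "trend": trend}

    # qPCR demonstration table
    qpcr = generate_qpcr_table(syncfg, matrix)
    qpcr.to_csv(outdir / "qpcr_dct.tsv", sep="\t")

    # permute: planted candidate list vs a size-matched random baseline
    candidates = truth.prognostic_genes
    baseline = make_random_baseline(matrix.gene_ids, size=max(len(candidates), 200), seed=seed)
    planted = permutation_run(candidates, cohorts, thresholds, seed, list_label="planted")
    random_list = permutation_run(baseline, cohorts, thresholds, seed, list_label="random")
    planted.per_n.to_csv(outdir / "permutation_planted.tsv", sep="\t")
    random_list.per_n.to_csv(outdir / "permutation_random.tsv", sep="\t")
    comparison = compare_lists(planted, random_list)
    comparison.to_csv(outdir / "permutation_comparison.tsv", sep="\t")
    manifest["stages"]["permute"] = {
        "planted": planted.per_n["fraction_robust"].to_dict(),
        "random": random_list.per_n["fraction_robust"].to_dict(),
    }

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["input_hashes"] = {p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
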
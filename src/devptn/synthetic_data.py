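"""Synthetic data with known ground truth for the whole pipeline.

Three generators mirror the study design at desk scale:

* a staged developmental expression matrix (four ordered stages, sample
  sizes 10/10/9/15 by default) in which each gene follows the idealized
  template of a planted tri-state pattern code plus Gaussian noise;
* independent tumor cohorts whose survival follows a proportional-
  hazards model driven by a latent per-patient score loaded onto a
  planted prognostic gene set, with uniform right censoring calibrated
  to a target censoring fraction and per-cohort batch offsets;
* a probe-level matrix with a known max-mean probe per gene, and a
  qPCR delta-Ct table that inverts back to expression.

Everything is deterministic given the master seed.  The generator
validates mechanisms (recovery, calibration, signal detection), not
lung biology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    CANONICAL_STAGES,
    ClinicalTable,
    ExpressionMatrix,
    StageDesign,
    SurvivalCohort,
    ValidationError,
)
from .pattern_classification import template_profile


@dataclass
class SyntheticConfig:
    """Knobs for all generators; defaults are the desk-scale study shape."""

    n_genes: int = 1000
    samples_per_stage: tuple[int, int, int, int] = (10, 10, 9, 15)
    #: planted code -> proportion of genes; remainder (if < 1) is flat "nnn"
    pattern_mixture: dict = field(default_factory=lambda: {"uuu": 0.1, "ddd": 0.1, "nnn": 0.8})
    step_effect: float = 2.0   # per-transition mean shift, log2 units
    noise_sd: float = 0.5      # residual sd, log2 units
    baseline_mean: float = 8.0
    n_cohorts: int = 3
    patients_per_cohort: tuple[int, ...] | int = 100
    planted_prognostic_genes: int = 50
    prognostic_loading: float = 1.0    # expression units per unit latent score
    hazard_coefficient: float = 1.0    # log hazard ratio per unit latent score
    baseline_hazard: float = 0.02      # events per month
    censoring_rate: float = 0.30       # target fraction censored
    gene_dropout: float = 0.05         # fraction of genes masked per cohort
    master_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.pattern_mixture.values())
        if total > 1 + 1e-9:
            raise ValidationError("pattern mixture proportions exceed 1")
        for code in self.pattern_mixture:
            template_profile(code)  # raises on invalid codes
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ValidationError("censoring_rate must lie in [0, 1)")

    def cohort_sizes(self) -> tuple[int, ...]:
        if isinstance(self.patients_per_cohort, int):
            return (self.patients_per_cohort,) * self.n_cohorts
        return tuple(self.patients_per_cohort)


#: Stage/cohort sizes mirroring the study: developmental samples
#: 10/10/9/15 and five ADC cohorts of 69, 125, 117, 62 and 282 patients.
STUDY_SHAPE = dict(
    samples_per_stage=(10, 10, 9, 15),
    n_cohorts=5,
    patients_per_cohort=(69, 125, 117, 62, 282),
)


@dataclass
class SyntheticTruth:
    """Ground truth written beside every generated dataset."""

    planted_codes: dict = field(default_factory=dict)        # gene -> code
    prognostic_genes: list = field(default_factory=list)
    latent_scores: dict = field(default_factory=dict)        # cohort -> {patient: score}

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(
            {"planted_codes": self.planted_codes,
             "prognostic_genes": self.prognostic_genes,
             "latent_scores": self.latent_scores}, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["planted_codes"], d["prognostic_genes"], d["latent_scores"])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_staged_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, StageDesign, SyntheticTruth]:
    """Four-stage developmental matrix with planted pattern codes.

    A gene with planted code c has stage means
    baseline + step_effect * template_profile(c), plus i.i.d. Gaussian
    noise; genes not covered by the mixture are flat ("nnn").
    """
    rng = np.random.default_rng(config.master_seed)
    genes = _gene_ids(config.n_genes)
    n_stages = len(config.samples_per_stage)

    codes = []
    for code, prop in config.pattern_mixture.items():
        codes += [code] * int(round(prop * config.n_genes))
    codes += ["n" * (n_stages - 1)] * (config.n_genes - len(codes))
    codes = codes[: config.n_genes]

    baselines = rng.normal(config.baseline_mean, 1.0, size=config.n_genes)
    templates = np.stack([template_profile(c, n_stages) for c in codes])
    stage_means = baselines[:, None] + config.step_effect * templates  # genes x stages

    cols, stage_of = [], {}
    blocks = []
    for s, (stage, n_s) in enumerate(zip(CANONICAL_STAGES[:n_stages], config.samples_per_stage)):
        ids = [f"{stage}_{j:02d}" for j in range(n_s)]
        cols += ids
        stage_of.update({i: stage for i in ids})
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_s))
        blocks.append(stage_means[:, [s]] + noise)
    matrix = ExpressionMatrix(pd.DataFrame(np.hstack(blocks), index=genes, columns=cols))
    design = StageDesign(CANONICAL_STAGES[:n_stages], stage_of)
    truth = SyntheticTruth(planted_codes=dict(zip(genes, codes)))
    return matrix, design, truth


def _calibrate_uniform_censoring(times: np.ndarray, target: float, rng) -> np.ndarray:
    """Uniform(0, c) censoring times with c chosen by bisection so the
    expected censored fraction matches the target."""
    if target <= 0:
        return np.full_like(times, np.inf)

    def frac(c):  # E[censored] = mean_i P(C < T_i) = mean min(T_i / c, 1)
        return float(np.minimum(times / c, 1.0).mean())

    lo, hi = 1e-6, float(times.max()) * 1e3
    if frac(hi) > target:
        warnings.warn("censoring target unattainable; using closest achievable")
        c = hi
    else:
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if frac(mid) > target:
                lo = mid
            else:
                hi = mid
        c = 0.5 * (lo + hi)
    return rng.uniform(0.0, c, size=times.shape)


def generate_tumor_cohorts(
    config: SyntheticConfig,
    truth: SyntheticTruth | None = None,
) -> tuple[list[SurvivalCohort], SyntheticTruth]:
    """Independent tumor cohorts with survival driven by a planted set.

    Per patient a latent score s ~ N(0,1); planted prognostic genes get
    expression loading * s + noise, the rest pure noise around their
    baselines.  Survival is exponential with hazard
    baseline_hazard * exp(beta * s); censoring is independent uniform,
    calibrated to the target rate.  Each cohort gets an additive batch
    offset and an independent random mask of dropped genes.
    """
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 7010]))
    genes = _gene_ids(config.n_genes)
    if config.planted_prognostic_genes > config.n_genes:
        raise ValidationError("more prognostic genes than genes")
    prognostic = list(rng.choice(genes, size=config.planted_prognostic_genes, replace=False))
    truth.prognostic_genes = sorted(prognostic)
    prog_mask = np.isin(genes, prognostic)
    baselines = rng.normal(config.baseline_mean, 1.0, size=config.n_genes)

    cohorts = []
    for c_idx, n_pat in enumerate(config.cohort_sizes()):
        crng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 7020, c_idx]))
        label = f"cohort_{c_idx}"
        patients = [f"{label}_P{j:03d}" for j in range(n_pat)]
        s = crng.normal(0.0, 1.0, size=n_pat)
        expr = baselines[:, None] + crng.normal(0.0, config.noise_sd,
                                                size=(config.n_genes, n_pat))
        expr[prog_mask] += config.prognostic_loading * s[None, :]
        expr += crng.normal(0.0, 0.5)  # cohort-wide batch offset

        hazard = config.baseline_hazard * np.exp(config.hazard_coefficient * s)
        t_event = crng.exponential(1.0 / hazard)
        t_cens = _calibrate_uniform_censoring(t_event, config.censoring_rate, crng)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)

        keep = np.ones(config.n_genes, dtype=bool)
        if config.gene_dropout > 0:
            drop = crng.random(config.n_genes) < config.gene_dropout
            keep = ~drop
        df = pd.DataFrame(expr[keep], index=np.array(genes)[keep], columns=patients)
        clin = ClinicalTable(pd.DataFrame(
            {"time": time, "event": event,
             "tnm_stage": crng.choice(["I", "II", "III"], size=n_pat, p=[0.5, 0.3, 0.2])},
            index=pd.Index(patients, name="id")))
        cohorts.append(SurvivalCohort(label, clin, ExpressionMatrix(df)))
        truth.latent_scores[label] = dict(zip(patients, map(float, s)))
    return cohorts, truth


def generate_probe_map(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.Series, pd.Series]:
    """Probe-level matrix where each gene owns 1-4 probes and exactly one
    probe per gene is the known maximum-mean probe.

    Returns (probe matrix, probe->gene map, gene->best-probe truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 7030]))
    matrix, _, _ = generate_staged_expression(config)
    rows, mapping, best = [], {}, {}
    index = []
    for gene in matrix.gene_ids:
        n_probes = int(rng.integers(1, 5))
        base = matrix.data.loc[gene].to_numpy()
        offsets = rng.uniform(-2.0, -0.5, size=n_probes)
        winner = int(rng.integers(n_probes))
        offsets[winner] = 0.0  # the max-mean probe sits on the gene profile
        for j in range(n_probes):
            pid = f"{gene}_pr{j}"
            mapping[pid] = gene
            index.append(pid)
            rows.append(base + offsets[j])
            if j == winner:
                best[gene] = pid
    probe_matrix = ExpressionMatrix(pd.DataFrame(rows, index=index, columns=matrix.sample_ids))
    return probe_matrix, pd.Series(mapping), pd.Series(best)


def generate_qpcr_table(
    config: SyntheticConfig,
    expression: ExpressionMatrix,
    target_genes=None,
    *,
    reference_noise_sd: float = 0.1,
) -> pd.DataFrame:
    """qPCR delta-Ct table for a gene subset (12 targets plus one
    reference gene by default): delta-Ct = -(expression) + reference
    noise, so negation recovers expression up to that noise."""
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 7040]))
    if target_genes is None:
        target_genes = expression.gene_ids[:12]
    missing = [g for g in target_genes if g not in expression.data.index]
    if missing:
        raise ValidationError(f"qPCR targets outside the gene universe: {missing}")
    sub = expression.data.loc[list(target_genes)]
    ref_noise = rng.normal(0.0, reference_noise_sd, size=(len(target_genes), sub.shape[1]))
    dct = -sub + ref_noise
    dct.loc["REF"] = rng.normal(0.0, reference_noise_sd, size=sub.shape[1])
    return dct
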
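"""Shared domain containers for the developmental-pattern pipeline.

The pipeline moves log2 expression matrices (genes x samples) through
pattern classification, tumor-vs-mature comparison and survival-based
signature permutation.  The containers here are thin, validated wrappers
around pandas objects; heavy computation lives in the operation modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical ordered developmental stages: whole embryo, early lung,
#: middle (pseudoglandular/canalicular) lung, mature adult lung.
CANONICAL_STAGES = ("WholeE", "EarlyL", "MiddleL", "MatureL")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of log2 expression values.

    ``data`` has unique gene ids as the index and unique sample ids as
    columns; every value must be finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene/probe ids: {dups[:10]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:10]}")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression values: {exc}") from exc
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            r, c = bad[0]
            raise ValidationError(
                f"non-finite value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
                f" ({len(bad)} offending cells)"
            )
        self.data = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])


@dataclass
class StageDesign:
    """Assignment of samples to an ordered set of developmental stages."""

    ordered_stages: tuple[str, ...] = CANONICAL_STAGES
    sample_to_stage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ordered_stages = tuple(self.ordered_stages)
        if len(set(self.ordered_stages)) != len(self.ordered_stages):
            raise ValidationError("stage labels must be unique")
        unknown = {s for s in self.sample_to_stage.values()} - set(self.ordered_stages)
        if unknown:
            raise ValidationError(f"samples mapped to undeclared stages: {sorted(unknown)}")

    def samples_for(self, stage: str) -> list[str]:
        return [s for s, st in self.sample_to_stage.items() if st == stage]

    @property
    def n_transitions(self) -> int:
        return len(self.ordered_stages) - 1

    def validate_against(self, matrix: ExpressionMatrix, min_per_stage: int = 2) -> None:
        cols = set(matrix.sample_ids)
        missing = [s for s in self.sample_to_stage if s not in cols]
        if missing:
            raise ValidationError(f"design samples absent from matrix: {missing[:10]}")
        for stage in self.ordered_stages:
            n = len(self.samples_for(stage))
            if n < min_per_stage:
                raise ValidationError(
                    f"stage {stage!r} has {n} samples; at least {min_per_stage} required"
                )


@dataclass
class ClinicalTable:
    """Per-patient follow-up: survival time (months), event (1=death/0=censored),
    and optional categorical covariates such as TNM stage."""

    data: pd.DataFrame  # index: sample_id; columns: time, event [, tnm_stage, ...]

    def __post_init__(self) -> None:
        df = self.data
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValidationError(f"clinical table missing required column {col!r}")
        if df.index.has_duplicates:
            raise ValidationError("duplicate patient ids in clinical table")
        if (df["time"].to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative survival time")
        ev = set(pd.unique(df["event"]))
        if not ev <= {0, 1}:
            raise ValidationError(f"event indicator outside {{0,1}}: {sorted(ev - {0, 1})}")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)


@dataclass
class SurvivalCohort:
    """A labeled patient cohort: clinical follow-up plus the cohort's
    expression matrix restricted to those patients."""

    cohort_label: str
    clinical: ClinicalTable
    expression: ExpressionMatrix

    def __post_init__(self) -> None:
        cols = set(self.expression.sample_ids)
        missing = [s for s in self.clinical.sample_ids if s not in cols]
        if missing:
            raise ValidationError(
                f"cohort {self.cohort_label!r}: patients without expression column: {missing[:10]}"
            )
        # keep expression columns aligned to the clinical patients, in order
        self.expression = self.expression.subset_samples(self.clinical.sample_ids)

    @property
    def n_patients(self) -> int:
        return len(self.clinical.sample_ids)


@dataclass(frozen=True)
class AnalysisThresholds:
    """All significance thresholds and permutation settings in one place.

    Defaults follow the study design: per-transition calls require both
    raw p < 0.05 and BH FDR q < 0.01; tumor-vs-mature calls use a
    Bonferroni-adjusted p < 0.01; stratified survival uses log-rank
    alpha 0.05; gene-set enrichment alpha 1e-4; the permutation engine
    draws 10,000 signatures per size n in {3, 6, ..., 21} and splits
    patients with k-means, k = 2.
    """

    alpha_transition: float = 0.05
    q_transition: float = 0.01
    bonferroni_alpha: float = 0.01
    logrank_alpha: float = 0.05
    enrichment_alpha: float = 1e-4
    reps: int = 10_000
    n_values: tuple[int, ...] = (3, 6, 9, 12, 15, 18, 21)
    k: int = 2

    def __post_init__(self) -> None:
        for name in ("alpha_transition", "q_transition", "bonferroni_alpha",
                     "logrank_alpha", "enrichment_alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must lie in (0, 1], got {v}")
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")
        if any((not isinstance(n, (int, np.integer))) or n < 1 for n in self.n_values):
            raise ValidationError("n_values must be positive integers")
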
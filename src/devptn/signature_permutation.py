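"""The prognostic-signature permutation engine.

For each signature size n, a candidate gene list (e.g. the steadily
decreasing pattern PTN1, or a fixed random baseline list of 200 genes)
is sampled without replacement ``reps`` times.  Every sampled n-gene
signature stratifies each patient cohort into two groups by k-means
(k = 2) on the signature submatrix and is scored by the log-rank test;
a signature is a *robust effective signature* only if log-rank p falls
below alpha in every cohort simultaneously.  The per-n fraction of
robust signatures is the engine's output, compared between candidate
lists with a two-proportion z-test.

Per-trial RNG streams derive from (master seed, n, trial index) so the
result is independent of execution order and worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .datatypes import AnalysisThresholds, SurvivalCohort, ValidationError
from .survival_analysis import kmeans_stratify, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class SignatureTrial:
    """One sampled n-gene signature and its per-cohort log-rank outcome."""

    genes: tuple
    cohort_p: dict  # cohort label -> log-rank p (nan if the trial was invalid there)
    robust: bool
    flagged: bool = False  # invalid stratification or no genes in some cohort


@dataclass
class PermutationSummary:
    """Per-n robust-signature counts for one candidate list."""

    list_label: str
    master_seed: int
    reps: int
    per_n: pd.DataFrame = field(repr=False)  # index n: robust_count, fraction_robust

    def fraction(self, n: int) -> float:
        return float(self.per_n.loc[n, "fraction_robust"])


def make_random_baseline(universe, size: int = 200, seed: int = 0) -> list:
    """A fixed list of ``size`` genes sampled once, without replacement,
    from the full gene universe (the 'Random200' baseline for the
    default size)."""
    universe = list(universe)
    if len(universe) < size:
        raise ValidationError(f"universe of {len(universe)} smaller than requested {size}")
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(universe, size=size, replace=False).tolist())


def sample_signature(candidate_list, n: int, rng: np.random.Generator) -> tuple:
    """n distinct genes drawn uniformly without replacement."""
    candidate_list = list(candidate_list)
    if n > len(candidate_list):
        raise ValidationError(f"signature size {n} exceeds candidate list of {len(candidate_list)}")
    return tuple(rng.choice(candidate_list, size=n, replace=False).tolist())


def evaluate_signature(
    genes,
    cohorts: list[SurvivalCohort],
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    seed: int = 0,
    *,
    strict: bool = False,
) -> SignatureTrial:
    """Stratify every cohort on the signature and log-rank test each.

    Genes absent from a cohort's platform are dropped per cohort; the
    trial is flagged invalid (and non-robust) if a cohort retains no
    genes, or if any stratification is degenerate.  ``strict`` aborts
    on missing genes instead of dropping them.
    """
    genes = list(genes)
    cohort_p: dict = {}
    flagged = False
    for i, cohort in enumerate(cohorts):
        present = [g for g in genes if g in cohort.expression.data.index]
        if len(present) < len(genes):
            if strict:
                raise ValidationError(
                    f"cohort {cohort.cohort_label!r} lacks signature genes "
                    f"{sorted(set(genes) - set(present))}")
            logger.debug("cohort %s: dropped %d missing signature genes",
                         cohort.cohort_label, len(genes) - len(present))
        if not present:
            cohort_p[cohort.cohort_label] = float("nan")
            flagged = True
            continue
        sub = cohort.expression.subset_genes(present)
        strat = kmeans_stratify(sub, seed=seed + i, k=thresholds.k)
        if not strat.valid:
            cohort_p[cohort.cohort_label] = float("nan")
            flagged = True
            continue
        _, p = logrank_test(cohort.clinical.times, cohort.clinical.events,
                            strat.labels.loc[cohort.clinical.sample_ids].to_numpy())
        cohort_p[cohort.cohort_label] = p
    robust = (not flagged) and all(p < thresholds.logrank_alpha for p in cohort_p.values())
    return SignatureTrial(tuple(genes), cohort_p, robust, flagged)


def _trial_seed(master_seed: int, n: int, trial: int) -> int:
    """Deterministic sub-stream seed below 2**31."""
    ss = np.random.SeedSequence([master_seed, n, trial])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def permutation_run(
    candidate_list,
    cohorts: list[SurvivalCohort],
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    master_seed: int = 0,
    *,
    list_label: str = "candidate",
    keep_trials: bool = False,
) -> PermutationSummary:
    """Run the full permutation over every n in ``thresholds.n_values``.

    Each trial draws its own RNG stream from (master_seed, n, trial
    index): the same master seed reproduces the summary bit-identically
    regardless of execution order.  A signature sampled twice by chance
    still counts as an independent trial.
    """
    candidate_list = sorted(candidate_list)
    if len(candidate_list) < max(thresholds.n_values):
        raise ValidationError(
            f"candidate list of {len(candidate_list)} smaller than max n "
            f"{max(thresholds.n_values)}")
    rows = []
    trials: list[SignatureTrial] = []
    for n in thresholds.n_values:
        robust_count = 0
        for trial in range(thresholds.reps):
            seed = _trial_seed(master_seed, n, trial)
            rng = np.random.default_rng(seed)
            genes = sample_signature(candidate_list, n, rng)
            result = evaluate_signature(genes, cohorts, thresholds, seed=seed)
            robust_count += result.robust
            if keep_trials:
                trials.append(result)
        rows.append({"n": n, "reps": thresholds.reps, "robust_count": robust_count,
                     "fraction_robust": robust_count / thresholds.reps})
        logger.info("list %s, n=%d: %d/%d robust", list_label, n, robust_count, thresholds.reps)
    per_n = pd.DataFrame(rows).set_index("n")
    summary = PermutationSummary(list_label, master_seed, thresholds.reps, per_n)
    if keep_trials:
        summary.trials = trials  # type: ignore[attr-defined]
    return summary


def compare_lists(summary_a: PermutationSummary, summary_b: PermutationSummary) -> pd.DataFrame:
    """Per-n difference in robust fractions with a two-proportion z-test.

    The z-test is added plumbing beyond the raw fractions and is labeled
    as such in the output column names.
    """
    a, b = summary_a.per_n, summary_b.per_n
    if list(a.index) != list(b.index) or (a["reps"].to_numpy() != b["reps"].to_numpy()).any():
        raise ValidationError("summaries have mismatched n grids or reps")
    rows = []
    for n in a.index:
        ca, cb = int(a.loc[n, "robust_count"]), int(b.loc[n, "robust_count"])
        reps = int(a.loc[n, "reps"])
        if ca == cb:
            p = 1.0
        else:
            _, p = proportions_ztest([ca, cb], [reps, reps])
        rows.append({
            "n": n,
            f"fraction_{summary_a.list_label}": ca / reps,
            f"fraction_{summary_b.list_label}": cb / reps,
            "difference": (ca - cb) / reps,
            "two_proportion_p_added_plumbing": float(p),
        })
    return pd.DataFrame(rows).set_index("n")
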
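"""Kaplan-Meier estimation, log-rank testing and unsupervised
two-group patient stratification.

Patients are split on a signature's expression either by k-means
(k = 2, ten seeded k-means++ restarts) or by average-linkage
hierarchical clustering on 1 - Pearson correlation distance, cut into
two groups.  The group with the larger mean (z-scored) signature
expression is labeled "high".  The log-rank statistic uses the standard
hypergeometric variance with aggregated increments at tied times; its
null distribution is chi-square with 1 df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import pdist

from .datatypes import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at the event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


@dataclass
class GroupLabels:
    """A two-group patient stratification with high/low orientation."""

    labels: pd.Series  # patient -> "high" | "low"
    valid: bool
    orientation_score: dict = field(default_factory=dict)  # group -> mean signature expr

    def mask(self, group: str) -> np.ndarray:
        return (self.labels == group).to_numpy()


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censoring at an event time follows the standard convention: the
    censored subject is still at risk for the event at that time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty survival input")
    if times.shape != events.shape:
        raise ValidationError("times and events differ in length")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    ev_times = np.unique(times[events == 1])
    if ev_times.size == 0:
        return KMCurve(ev_times, np.ones(0), np.zeros(0, int), np.zeros(0, int))
    surv = kmf.survival_function_at_times(ev_times).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in ev_times])
    d = np.array([((times == t) & (events == 1)).sum() for t in ev_times])
    return KMCurve(ev_times, surv, at_risk, d)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p).

    ``groups`` is any two-level labeling.  With no variance in the
    observed-minus-expected increments (e.g. identical survival in both
    groups) the statistic is 0 and p = 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"log-rank needs exactly two non-empty groups, got {len(levels)}")
    g = groups == levels[0]

    ev_times = np.unique(times[events == 1])
    if ev_times.size == 0:
        return 0.0, 1.0
    t_sorted = np.sort(times)
    n_at_risk = len(times) - np.searchsorted(t_sorted, ev_times, side="left")
    t1_sorted = np.sort(times[g])
    n1_at_risk = len(t1_sorted) - np.searchsorted(t1_sorted, ev_times, side="left")
    is_event = events == 1
    d = np.array([((times == t) & is_event).sum() for t in ev_times])
    d1 = np.array([((times == t) & is_event & g).sum() for t in ev_times])

    frac1 = n1_at_risk / n_at_risk
    expected1 = d * frac1
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * frac1 * (1 - frac1) * (n_at_risk - d) / np.maximum(n_at_risk - 1, 1)
    o_minus_e = (d1 - expected1).sum()
    v = var.sum()
    if v <= 0:
        return 0.0, 1.0
    statistic = o_minus_e**2 / v
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def _zscore_rows(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (mat - mu) / sd


def _orient(labels01: np.ndarray, patients, score_mat: np.ndarray) -> GroupLabels:
    """Name the cluster with larger mean signature expression 'high'."""
    sig = score_mat.mean(axis=0)  # per-patient mean signature expression
    means = {c: sig[labels01 == c].mean() for c in (0, 1)}
    high = max(means, key=means.get)
    named = np.where(labels01 == high, "high", "low")
    labels = pd.Series(named, index=list(patients))
    return GroupLabels(
        labels=labels,
        valid=True,
        orientation_score={"high": float(means[high]), "low": float(means[1 - high])},
    )


def kmeans_stratify(expression: ExpressionMatrix, seed: int, *, k: int = 2,
                    n_restarts: int = 10, zscore: bool = True) -> GroupLabels:
    """k-means (k = 2) stratification of patients on a signature submatrix.

    Genes are z-scored across patients, then patients are clustered on
    their gene vectors with ``n_restarts`` k-means++ restarts from a
    seeded RNG stream; the lowest-inertia solution wins.  Degenerate
    inputs (all patients identical, or an empty cluster) yield an
    invalid stratification rather than an arbitrary split.
    """
    mat = expression.values
    n_genes, n_patients = mat.shape
    if n_genes < 1:
        raise ValidationError("signature submatrix has no genes")
    if n_patients < k:
        raise ValidationError(f"need at least {k} patients, got {n_patients}")
    scored = _zscore_rows(mat) if zscore else mat
    X = scored.T  # patients x genes
    if np.allclose(X, X[0]):
        logger.info("degenerate stratification: all patient profiles identical")
        return GroupLabels(pd.Series("low", index=expression.sample_ids), valid=False)
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_restarts):
        centroids, labels = kmeans2(X, k, minit="++", seed=rng)
        inertia = float(((X - centroids[labels]) ** 2).sum())
        if len(np.unique(labels)) == k and inertia < best_inertia:
            best_inertia, best_labels = inertia, labels
    if best_labels is None:
        return GroupLabels(pd.Series("low", index=expression.sample_ids), valid=False)
    return _orient(best_labels, expression.sample_ids, scored)


def hclust_stratify(expression: ExpressionMatrix, *, zscore: bool = True) -> GroupLabels:
    """Hierarchical two-group stratification.

    Average-linkage clustering of patients on 1 - Pearson correlation
    distance between their signature profiles, cut into two groups.
    Patients with zero-variance profiles (correlation undefined) are
    assigned afterwards to the nearer group centroid.
    """
    mat = expression.values
    if mat.shape[1] < 2:
        raise ValidationError("need at least 2 patients")
    scored = _zscore_rows(mat) if zscore else mat
    X = scored.T
    var = X.var(axis=1)
    ok = var > 0
    if ok.sum() < 2:
        logger.info("degenerate stratification: fewer than 2 variable patient profiles")
        return GroupLabels(pd.Series("low", index=expression.sample_ids), valid=False)
    dist = pdist(X[ok], metric="correlation")
    tree = linkage(dist, method="average")
    cut = fcluster(tree, t=2, criterion="maxclust") - 1
    labels01 = np.zeros(X.shape[0], dtype=int)
    labels01[ok] = cut
    if (~ok).any():
        logger.info("assigning %d zero-variance patients by nearest centroid", int((~ok).sum()))
        cents = np.stack([X[ok][cut == c].mean(axis=0) for c in (0, 1)])
        for i in np.where(~ok)[0]:
            labels01[i] = np.argmin(((cents - X[i]) ** 2).sum(axis=1))
    if len(np.unique(labels01)) < 2:
        return GroupLabels(pd.Series("low", index=expression.sample_ids), valid=False)
    return _orient(labels01, expression.sample_ids, scored)
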
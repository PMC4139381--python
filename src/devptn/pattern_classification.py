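"""Tri-state developmental pattern classification.

Across four ordered developmental stages there are three adjacent-stage
transitions.  Each transition is called per gene as ``u`` (expression
higher in the earlier stage), ``d`` (higher in the later stage) or ``n``
(no significant change) from a two-sided unpaired t-test, declared
significant only when both raw p < alpha and BH FDR q < q_threshold
hold.  The three calls concatenate to a code over {u, d, n}, giving
3**3 = 27 patterns (PTNs).  ``uuu`` — steadily decreasing through
development — is PTN1; the flat code ``nnn`` is PTN14; the remaining
codes are ranked by the Pearson correlation of their idealized stage
template with the PTN1 template, which places the steadily increasing
``ddd`` last, at PTN27.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import AnalysisThresholds, ExpressionMatrix, StageDesign, ValidationError

logger = logging.getLogger(__name__)

ALPHABET = ("u", "n", "d")  # tie-break order: u < n < d


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def template_profile(code: str, n_stages: int | None = None) -> np.ndarray:
    """Idealized stage profile implied by a pattern code.

    A cumulative walk from 0: ``u`` steps -1 (expression falls at that
    transition), ``d`` steps +1, ``n`` steps 0.  ``uuu`` is therefore
    monotone decreasing, matching PTN1.
    """
    bad = set(code) - set("udn")
    if bad:
        raise ValidationError(f"invalid pattern-code characters: {sorted(bad)}")
    if n_stages is not None and len(code) != n_stages - 1:
        raise ValidationError(f"code {code!r} incompatible with {n_stages} stages")
    steps = {"u": -1.0, "d": 1.0, "n": 0.0}
    return np.concatenate([[0.0], np.cumsum([steps[c] for c in code])])


@dataclass(frozen=True)
class PatternCatalog:
    """The fixed bijection between the 27 tri-state codes and PTN 1..27."""

    code_to_index: dict
    index_to_code: dict
    correlations: dict  # code -> Pearson r with the PTN1 template (nan for "nnn")

    def __len__(self) -> int:
        return len(self.code_to_index)

    def index_of(self, code: str) -> int:
        return self.code_to_index[code]

    def code_of(self, index: int) -> str:
        return self.index_to_code[index]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ptn_index": i, "code": c, "corr_with_ptn1": self.correlations[c]}
            for i, c in sorted(self.index_to_code.items())
        ]
        return pd.DataFrame(rows).set_index("ptn_index")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / den) if den > 0 else float("nan")


def build_pattern_catalog(n_transitions: int = 3) -> PatternCatalog:
    """Enumerate all tri-state codes and assign PTN indices.

    ``u`` * n_transitions is pinned to index 1 and the constant code to
    the middle slot (14 for three transitions); the rest are sorted by
    descending Pearson correlation of their template with the PTN1
    template, ties broken lexicographically with u < n < d.
    """
    codes = ["".join(c) for c in product("udn", repeat=n_transitions)]
    anchor_top = "u" * n_transitions
    anchor_flat = "n" * n_transitions
    ref = template_profile(anchor_top)
    corr = {c: _pearson(template_profile(c), ref) for c in codes}

    rank = {ch: i for i, ch in enumerate(ALPHABET)}
    rest = sorted(
        (c for c in codes if c not in (anchor_top, anchor_flat)),
        key=lambda c: (-corr[c], [rank[ch] for ch in c]),
    )
    mid = (len(codes) + 1) // 2  # 14 for 27 codes
    code_to_index = {anchor_top: 1, anchor_flat: mid}
    slots = [i for i in range(2, len(codes) + 1) if i != mid]
    for slot, code in zip(slots, rest):
        code_to_index[code] = slot
    index_to_code = {i: c for c, i in code_to_index.items()}
    return PatternCatalog(code_to_index, index_to_code, corr)


def _student_t_rows(x: np.ndarray, y: np.ndarray, *, welch: bool = False):
    """Row-wise two-sided unpaired t-test; returns (p, mean_x - mean_y).

    Rows where both groups have zero variance are given p = 1 when the
    means agree and p = 0 when they differ (an exact separation).
    """
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = vx / nx + vy / ny
            df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        else:
            sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
            se2 = sp2 * (1 / nx + 1 / ny)
            df = np.full_like(se2, nx + ny - 2, dtype=float)
        t = diff / np.sqrt(se2)
        p = 2 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    if degenerate.any():
        n_deg = int(degenerate.sum())
        logger.info("%d genes with zero variance in both groups", n_deg)
        p = np.where(degenerate & (diff == 0), 1.0, p)
        p = np.where(degenerate & (diff != 0), 0.0, p)
    return p, diff


def call_transitions(
    matrix: ExpressionMatrix,
    design: StageDesign,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    *,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene, per-adjacent-stage-pair direction calls.

    Returns a long table with one row per (gene, transition): direction
    in {u, d, n}, raw p and BH q (FDR computed across genes within each
    transition).  Direction is ``u`` when the call is significant (raw
    p < alpha and q < q_threshold) and the earlier stage mean is higher.
    """
    design.validate_against(matrix, min_per_stage=2)
    frames = []
    for t in range(design.n_transitions):
        earlier = design.ordered_stages[t]
        later = design.ordered_stages[t + 1]
        x = matrix.data[design.samples_for(earlier)].to_numpy()
        y = matrix.data[design.samples_for(later)].to_numpy()
        p, diff = _student_t_rows(x, y, welch=welch)
        q = fdr_adjust(np.clip(p, 0.0, 1.0))
        sig = (p < thresholds.alpha_transition) & (q < thresholds.q_transition)
        direction = np.where(sig & (diff > 0), "u", np.where(sig & (diff < 0), "d", "n"))
        frames.append(pd.DataFrame({
            "gene": matrix.gene_ids,
            "transition": t + 1,
            "earlier": earlier,
            "later": later,
            "direction": direction,
            "p": p,
            "q": q,
        }))
    return pd.concat(frames, ignore_index=True)


def assign_pattern_codes(calls: pd.DataFrame) -> pd.Series:
    """Concatenate per-transition directions, in stage order, into the
    per-gene pattern code (gene -> code)."""
    counts = calls.groupby("gene")["transition"].nunique()
    n_trans = calls["transition"].max()
    incomplete = counts[counts < n_trans]
    if len(incomplete):
        raise ValidationError(f"genes missing transition calls: {list(incomplete.index[:10])}")
    wide = calls.pivot(index="gene", columns="transition", values="direction")
    codes = wide[sorted(wide.columns)].agg("".join, axis=1)
    codes.name = "code"
    return codes


def classify_genes(
    matrix: ExpressionMatrix,
    design: StageDesign,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    *,
    welch: bool = False,
    catalog: PatternCatalog | None = None,
) -> pd.DataFrame:
    """Full classification: transition calls -> codes -> PTN indices.

    Returns a per-gene table with the code, the PTN index and the three
    raw p's and q's (columns p1..p3, q1..q3).
    """
    catalog = catalog or build_pattern_catalog(design.n_transitions)
    calls = call_transitions(matrix, design, thresholds, welch=welch)
    codes = assign_pattern_codes(calls)
    out = codes.to_frame()
    out["ptn_index"] = [catalog.index_of(c) for c in codes]
    for t in sorted(calls["transition"].unique()):
        sub = calls[calls["transition"] == t].set_index("gene")
        out[f"p{t}"] = sub["p"]
        out[f"q{t}"] = sub["q"]
    counts = out["ptn_index"].value_counts().sort_index()
    logger.info("per-PTN gene counts: %s", counts.to_dict())
    return out.loc[matrix.gene_ids]


def ptn_counts(assignment: pd.DataFrame, catalog: PatternCatalog | None = None) -> pd.Series:
    """Genes per PTN over all 27 slots (zeros included)."""
    catalog = catalog or build_pattern_catalog()
    counts = assignment["ptn_index"].value_counts()
    return counts.reindex(sorted(catalog.index_to_code), fill_value=0)
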
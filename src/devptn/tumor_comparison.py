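"""Tumor-versus-mature-lung comparison and pattern enrichment.

Adenocarcinoma (ADC)-related genes are those differentially expressed
between tumor and mature lung under a two-sided unpaired t-test with
Bonferroni correction over the gene universe.  Their distribution over
the 26 variable patterns (vPTNs) is tested for over-representation with
one-sided hypergeometric tests, and the expected monotone drift —
tumor-upregulated genes concentrating in low-numbered (development-
decreasing) patterns — is summarized by a Spearman rank trend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnalysisThresholds, ExpressionMatrix, ValidationError
from .pattern_classification import _student_t_rows, fdr_adjust

logger = logging.getLogger(__name__)


@dataclass
class DifferentialGeneSets:
    """ADC-related genes split by direction, with per-gene p-values."""

    up_genes: set
    down_genes: set
    table: pd.DataFrame = field(repr=False)  # gene, p_raw, p_bonferroni, direction

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValidationError("up and down gene sets overlap")


def adc_related_genes(
    tumor: ExpressionMatrix,
    mature: ExpressionMatrix,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
) -> DifferentialGeneSets:
    """Differential genes between tumor and mature lung.

    Two-sided unpaired Student's t-test per gene, Bonferroni adjustment
    over the shared gene universe; significant genes split by the sign
    of (tumor mean - mature mean).
    """
    if set(tumor.gene_ids) != set(mature.gene_ids):
        raise ValidationError("tumor and mature matrices cover different gene universes")
    genes = tumor.gene_ids
    x = tumor.values
    y = mature.data.loc[genes].to_numpy()
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValidationError("need at least 2 samples per group")
    p, diff = _student_t_rows(x, y)
    p_bonf = np.minimum(p * len(genes), 1.0)
    sig = p_bonf < thresholds.bonferroni_alpha
    direction = np.where(~sig, "ns", np.where(diff > 0, "up", "down"))
    table = pd.DataFrame(
        {"p_raw": p, "p_bonferroni": p_bonf, "direction": direction},
        index=pd.Index(genes, name="gene"),
    )
    up = set(table.index[table["direction"] == "up"])
    down = set(table.index[table["direction"] == "down"])
    logger.info("ADC-related genes: %d up, %d down of %d", len(up), len(down), len(genes))
    return DifferentialGeneSets(up, down, table)


def _hypergeom_upper(overlap: int, universe: int, set_size: int, group_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, group_size)."""
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, group_size))


def ptn_enrichment(sets: DifferentialGeneSets, assignment: pd.DataFrame) -> pd.DataFrame:
    """Over-representation of up/down ADC-related genes in each vPTN.

    One-sided hypergeometric upper-tail p per (vPTN, direction) against
    the universe of all assigned genes, BH-adjusted across the 52 tests.
    The flat pattern (the middle PTN index) is excluded as in the vPTN
    definition, but stays in the background universe.
    """
    universe = set(assignment.index)
    # vPTNs are all 27 slots except the flat anchor at index 14
    all_indices = sorted(set(range(1, 28)) - {14})
    rows = []
    for direction, gene_set in (("up", sets.up_genes & universe), ("down", sets.down_genes & universe)):
        for idx in all_indices:
            members = set(assignment.index[assignment["ptn_index"] == idx])
            overlap = len(gene_set & members)
            p = 1.0 if not members else _hypergeom_upper(
                overlap, len(universe), len(gene_set), len(members))
            rows.append({
                "ptn_index": idx, "direction": direction, "overlap": overlap,
                "set_size": len(gene_set), "ptn_size": len(members),
                "background_size": len(universe), "p": p,
            })
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out


def monotone_trend_stat(results: pd.DataFrame) -> tuple[float, float]:
    """Spearman trend between PTN index and the per-vPTN proportion of
    tumor-upregulated genes.  Returns (rho, two-sided p); a constant
    proportion profile yields (0, 1) by convention."""
    up = results[(results["direction"] == "up") & (results["ptn_size"] > 0)]
    if len(up) < 3:
        raise ValidationError("need at least 3 non-empty vPTNs for a trend")
    prop = up["overlap"] / up["ptn_size"]
    if prop.nunique() == 1:
        return 0.0, 1.0
    rho, p = stats.spearmanr(up["ptn_index"], prop)
    return float(rho), float(p)


def geneset_enrichment(
    ptn_genes: dict,
    external_sets: dict,
    universe: set,
    alpha: float = AnalysisThresholds().enrichment_alpha,
) -> pd.DataFrame:
    """Hypergeometric gene-set enrichment of each vPTN against named
    external sets (stem-cell modules, proliferation sets, ...).

    External sets are intersected with the universe first.  Returns a
    long table with p, -log10 p and a significance flag at ``alpha``.
    """
    if not universe:
        raise ValidationError("empty gene universe")
    rows = []
    for set_label, ext in external_sets.items():
        ext = set(ext) & universe
        for idx, members in sorted(ptn_genes.items()):
            members = set(members) & universe
            overlap = len(ext & members)
            p = _hypergeom_upper(overlap, len(universe), len(ext), len(members))
            rows.append({
                "ptn_index": idx, "set_label": set_label, "overlap": overlap,
                "set_size": len(ext), "ptn_size": len(members), "p": p,
                "neg_log10_p": float(-np.log10(p)) if p > 0 else np.inf,
                "significant": p < alpha,
            })
    return pd.DataFrame(rows)


def contingency_association(group_labels: pd.Series, clinical_category: pd.Series,
                            *, yates: bool = False) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square association between a high/low stratification
    and a clinical category (e.g. TNM stage).

    Zero marginal rows/columns are dropped with a warning.  Returns
    (statistic, p, contingency table).
    """
    common = group_labels.index.intersection(clinical_category.index)
    if len(common) == 0:
        raise ValidationError("no shared patients between labels and category")
    table = pd.crosstab(group_labels.loc[common], clinical_category.loc[common])
    empty_rows = table.index[table.sum(axis=1) == 0]
    empty_cols = table.columns[table.sum(axis=0) == 0]
    if len(empty_rows) or len(empty_cols):
        warnings.warn(f"dropping zero-marginal rows {list(empty_rows)} / columns {list(empty_cols)}")
        table = table.drop(index=empty_rows, columns=empty_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("need at least a 2x2 table after dropping zero marginals")
    stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=yates)
    return float(stat), float(p), table
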
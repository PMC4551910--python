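"""Regulatory categorisation of genes from three-strain contrast statistics.

Genes are sorted into four categories by a fixed decision ladder over the
three M statistics (WT vs ΔRI, ΔRI vs none, WT vs none):

1. ``RI_dependent`` — more reads with wild-type σ54 than with either the
   ΔRI bypass form or no σ54 (M_WT_vs_dRI ≥ t_major and M_WT_vs_none ≥
   t_major): a canonical promoter activated in a Region I-dependent manner.
2. ``bypass`` — more reads with the ΔRI form than with no σ54
   (M_dRI_vs_none ≥ t_bypass): low-level activator-independent
   transcription, hence the lower threshold.
3. ``sigma54_repressed`` — more reads when σ54 is absent than with either
   σ54 form (−M_WT_vs_none ≥ t_major and −M_dRI_vs_none ≥ t_major).
4. ``unchanged`` otherwise.

The ladder is evaluated in that order so each gene receives exactly one
category.  When a per-gene ANOVA q-value is available, categories 1–3
additionally require q ≤ alpha; in single-replicate designs the q gate is
skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import ExpressionTable

CATEGORIES = ("RI_dependent", "bypass", "sigma54_repressed", "unchanged")

DEFAULT_T_MAJOR = 2.0   # four-fold, the MA-plot shaded-region boundary
DEFAULT_T_BYPASS = 1.0  # two-fold: bypass transcription is low-level
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GeneCall:
    gene_id: str
    category: str
    m_wt_dri: float
    m_dri_none: float
    m_wt_none: float
    q: float | None
    t_major: float
    t_bypass: float


def classify_gene(
    m_wt_dri: float,
    m_dri_none: float,
    m_wt_none: float,
    q: float | None = None,
    t_major: float = DEFAULT_T_MAJOR,
    t_bypass: float = DEFAULT_T_BYPASS,
    alpha: float = DEFAULT_ALPHA,
    gene_id: str = "",
) -> GeneCall:
    """Apply the decision ladder to one gene's contrast statistics."""
    if t_major <= 0 or t_bypass <= 0:
        raise ValueError("thresholds must be positive")
    values = (m_wt_dri, m_dri_none, m_wt_none)
    if not all(math.isfinite(v) for v in values):
        raise ValueError(f"non-finite M values {values}")
    significant = q is None or q <= alpha
    if significant and m_wt_dri >= t_major and m_wt_none >= t_major:
        category = "RI_dependent"
    elif significant and m_dri_none >= t_bypass:
        category = "bypass"
    elif significant and -m_wt_none >= t_major and -m_dri_none >= t_major:
        category = "sigma54_repressed"
    else:
        category = "unchanged"
    return GeneCall(gene_id, category, m_wt_dri, m_dri_none, m_wt_none,
                    q, t_major, t_bypass)


def call_genome(
    expr: ExpressionTable,
    t_major: float = DEFAULT_T_MAJOR,
    t_bypass: float = DEFAULT_T_BYPASS,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, pd.Series]:
    """Categorise every gene in an expression table.

    Returns a per-gene call table (gene_id index; category, the three M
    values, q, thresholds) and a summary of counts per category (all four
    categories present, summing to the number of genes).  The q ≤ alpha
    gate applies only when the table's ANOVA is available.
    """
    if t_major <= 0 or t_bypass <= 0:
        raise ValueError("thresholds must be positive")
    required = ["M_WT_vs_dRI", "M_dRI_vs_none", "M_WT_vs_none"]
    missing = [c for c in required if c not in expr.summary.columns]
    if missing:
        raise ValueError(f"expression table lacks contrast columns {missing}")
    s = expr.summary
    m_wd = s["M_WT_vs_dRI"].to_numpy(dtype=float)
    m_dn = s["M_dRI_vs_none"].to_numpy(dtype=float)
    m_wn = s["M_WT_vs_none"].to_numpy(dtype=float)
    if len(s) and not np.isfinite(np.concatenate([m_wd, m_dn, m_wn])).all():
        raise ValueError("non-finite M values in expression table")
    if expr.anova_available:
        q = s["q"].to_numpy(dtype=float)
        significant = q <= alpha
    else:
        q = np.full(len(s), np.nan)
        significant = np.ones(len(s), dtype=bool)
    category = np.select(
        [
            significant & (m_wd >= t_major) & (m_wn >= t_major),
            significant & (m_dn >= t_bypass),
            significant & (-m_wn >= t_major) & (-m_dn >= t_major),
        ],
        ["RI_dependent", "bypass", "sigma54_repressed"],
        default="unchanged",
    )
    calls = pd.DataFrame(
        {
            "category": category,
            "M_WT_vs_dRI": m_wd,
            "M_dRI_vs_none": m_dn,
            "M_WT_vs_none": m_wn,
            "q": q,
            "t_major": t_major,
            "t_bypass": t_bypass,
        },
        index=s.index,
    )
    summary = calls["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    summary.name = "n_genes"
    return calls, summary
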
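"""RPKM, MA contrast statistics and the three-strain one-way ANOVA.

RPKM = count × 10⁹ / (gene length in bp × library size).  For a pair of
strains, M = log₂(RPKM₁ + ε) − log₂(RPKM₂ + ε) and
A = ½[log₂(RPKM₁ + ε) + log₂(RPKM₂ + ε)]; a pseudocount ε (default 0.5
RPKM) is added inside the logarithms only, so reported RPKM values are
unshifted while M and A stay finite for silent genes.  |M| ≤ 2 delimits
genes at most four-fold differently expressed between two strains.

Differences across all three strains are tested per gene by a classical
equal-variance one-way ANOVA on log₂(RPKM + ε) over replicates, with
Benjamini–Hochberg FDR control across genes.  With a single replicate per
strain the ANOVA is flagged not computable rather than fabricated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import STRAINS, CountMatrix

#: Strain contrasts, in the order (numerator, denominator) of the M ratio.
CONTRASTS = {
    "WT_vs_none": ("WT", "none"),
    "WT_vs_dRI": ("WT", "dRI"),
    "dRI_vs_none": ("dRI", "none"),
}

DEFAULT_PSEUDOCOUNT = 0.5


def rpkm(count: float, gene_length_bp: int, library_size: int) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if count < 0:
        raise ValueError("counts must be non-negative")
    return count * 1e9 / (gene_length_bp * library_size)


def ma_stats(
    rpkm1: float, rpkm2: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> tuple[float, float]:
    """(M, A) for a pair of RPKM values; ε is added inside the logs only."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if rpkm1 < 0 or rpkm2 < 0:
        raise ValueError("RPKM values must be non-negative")
    l1 = np.log2(rpkm1 + pseudocount)
    l2 = np.log2(rpkm2 + pseudocount)
    return float(l1 - l2), float(0.5 * (l1 + l2))


@dataclass
class AnovaResult:
    f: float
    p: float
    computable: bool = True


# Sums of squared deviations below this relative floor are treated as zero
# (identical replicate values do not reproduce exactly in float arithmetic).
_SS_FLOOR = 1e-12


def _group_ss(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, float]:
    """(SS_between, SS_within, scale) along the last axis of each group."""
    all_values = np.concatenate(groups, axis=-1)
    grand = all_values.mean(axis=-1, keepdims=True)
    n_total = all_values.shape[-1]
    ss_between = sum(
        g.shape[-1] * (g.mean(axis=-1, keepdims=True) - grand) ** 2 for g in groups
    )[..., 0]
    ss_within = sum(
        ((g - g.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1) for g in groups
    )
    scale = float(np.mean(np.abs(all_values))) ** 2 + 1.0
    return np.asarray(ss_between), np.asarray(ss_within), scale * n_total


def anova_one_way(groups: list) -> AnovaResult:
    """Classical one-way ANOVA across replicate groups (one gene).

    Degenerate inputs are resolved explicitly: all-identical values give
    F = 0, p = 1; zero within-group variance with distinct means gives
    F = inf, p = 0; a single replicate per group is flagged not computable.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.ndim != 1 for a in arrays):
        raise ValueError("groups must be one-dimensional")
    if any(len(a) < 2 for a in arrays):
        return AnovaResult(np.nan, np.nan, computable=False)
    ss_b, ss_w, floor_scale = _group_ss(arrays)
    tol = _SS_FLOOR * floor_scale
    if ss_w <= tol:
        if ss_b <= tol:
            return AnovaResult(0.0, 1.0)
        return AnovaResult(np.inf, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    return AnovaResult(float(f), float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ExpressionTable:
    """Per-gene expression statistics for the three-strain design.

    ``rpkm`` holds replicate-level RPKM (genes × strain_replicate columns);
    ``summary`` holds per-gene ``rpkm_mean_<strain>``, ``M_<contrast>`` and
    ``A_<contrast>`` for the three contrasts, and ``F``/``p``/``q`` when the
    ANOVA is computable.
    """

    rpkm: pd.DataFrame
    summary: pd.DataFrame
    pseudocount: float
    n_replicates: int
    anova_available: bool
    strains: tuple[str, ...] = STRAINS

    def m(self, contrast: str) -> pd.Series:
        return self.summary[f"M_{contrast}"]

    def a(self, contrast: str) -> pd.Series:
        return self.summary[f"A_{contrast}"]

    def to_tsv(self, path) -> None:
        merged = self.rpkm.add_prefix("rpkm_").join(self.summary)
        merged.insert(0, "pseudocount", self.pseudocount)
        merged.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t").set_index("gene_id")
        pseudocount = float(df["pseudocount"].iloc[0]) if len(df) else DEFAULT_PSEUDOCOUNT
        rpkm_cols = [c for c in df.columns if c.startswith("rpkm_") and not c.startswith("rpkm_mean_")]
        rpkm_df = df[rpkm_cols].rename(columns=lambda c: c[len("rpkm_"):])
        summary = df.drop(columns=rpkm_cols + ["pseudocount"])
        reps = {int(c.rsplit("_", 1)[1]) for c in rpkm_df.columns} or {0}
        return cls(
            rpkm=rpkm_df,
            summary=summary,
            pseudocount=pseudocount,
            n_replicates=max(reps),
            anova_available="q" in summary.columns and summary["q"].notna().any(),
        )


def build_expression_table(
    counts: CountMatrix,
    gene_lengths: pd.Series | dict,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ExpressionTable:
    """Compute RPKM, the three MA contrasts and the per-gene ANOVA."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    lengths = pd.Series(gene_lengths, dtype=float).reindex(counts.counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = counts.library_sizes
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    rpkm_df = counts.counts * 1e9 / np.outer(lengths, lib)
    rpkm_df.columns = counts.counts.columns

    summary = pd.DataFrame(index=counts.counts.index)
    log_means = {}
    for strain in counts.strains:
        mean = rpkm_df[counts.columns_for(strain)].mean(axis=1)
        summary[f"rpkm_mean_{strain}"] = mean
        log_means[strain] = np.log2(mean + pseudocount)
    for name, (s1, s2) in CONTRASTS.items():
        summary[f"M_{name}"] = log_means[s1] - log_means[s2]
        summary[f"A_{name}"] = 0.5 * (log_means[s1] + log_means[s2])

    anova_available = counts.n_replicates >= 2
    if anova_available and len(summary):
        log_rpkm = np.log2(rpkm_df + pseudocount)
        groups = [
            log_rpkm[counts.columns_for(strain)].to_numpy()
            for strain in counts.strains
        ]
        ss_b, ss_w, floor_scale = _group_ss(groups)
        tol = _SS_FLOOR * floor_scale
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*groups, axis=1)
        f = np.asarray(f, dtype=float)
        p = np.asarray(p, dtype=float)
        both_zero = (ss_w <= tol) & (ss_b <= tol)
        within_zero = (ss_w <= tol) & ~both_zero
        f[both_zero], p[both_zero] = 0.0, 1.0
        f[within_zero], p[within_zero] = np.inf, 0.0
        summary["F"] = f
        summary["p"] = p
        summary["q"] = bh_adjust(p)
    else:
        summary["F"] = np.nan
        summary["p"] = np.nan
        summary["q"] = np.nan
        anova_available = False

    return ExpressionTable(
        rpkm=rpkm_df,
        summary=summary,
        pseudocount=pseudocount,
        n_replicates=counts.n_replicates,
        anova_available=anova_available,
    )
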
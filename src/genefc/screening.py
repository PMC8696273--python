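"""Individual-level screening of connectivity-related genes.

For each subject and each gene ``a``, the Pearson correlation between the
subject's connectivity vector ``FC_s`` and the gene's co-expression product
vector ``E_ia * E_ja`` is computed across all connections.  A gene is
significant in a subject at the Bonferroni-corrected level ``alpha / N``
(two-sided); genes significant in more than a prevalence fraction of
subjects (strictly more than 80% by default) form the connectivity-related
gene pool used by all later stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import connection_pairs
from .coupling import ConnectivitySet, ExpressionMatrix


def bonferroni_threshold(alpha: float, n_genes: int) -> float:
    """Per-test p-value threshold alpha / n_genes."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


def _pearson_columns(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of vector y against each column of X, plus two-sided p.

    Zero-variance columns yield r = nan, p = 1 (flagged by the caller).
    """
    n = y.size
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sy = np.sqrt((yc**2).sum())
    sx = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ Xc) / (sy * sx)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), 1.0, np.where(np.isclose(np.abs(r), 1.0), 0.0, p))
    return r, p


def per_gene_correlation(expr: ExpressionMatrix, fc_subject: np.ndarray) -> pd.DataFrame:
    """Per-gene (r, p) table for one subject.

    Degenerate genes (zero-variance co-expression product across
    connections) are recorded with ``degenerate=True`` and treated as
    non-significant rather than raising.
    """
    fc_subject = np.asarray(fc_subject, dtype=float)
    iu, ju = connection_pairs(expr.n_regions)
    if fc_subject.shape != iu.shape:
        raise ValueError("connectivity vector length inconsistent with expression")
    products = expr.values[iu] * expr.values[ju]  # connection x gene
    r, p = _pearson_columns(fc_subject, products)
    degenerate = np.isnan(r)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with constant co-expression product; "
            "recorded as non-significant",
            stacklevel=2,
        )
    return pd.DataFrame(
        {"gene": expr.gene_ids, "r": r, "p": p, "degenerate": degenerate}
    )


def prevalence_filter(significance: np.ndarray, threshold: float = 0.8) -> np.ndarray:
    """Boolean gene mask: significant in strictly more than ``threshold`` of
    subjects.

    ``significance`` is a subject x gene boolean table.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    significance = np.asarray(significance, dtype=bool)
    if significance.ndim != 2 or significance.shape[0] == 0:
        raise ValueError("need a non-empty subject x gene table")
    prevalence = significance.mean(axis=0)
    return prevalence > threshold


@dataclass
class ScreeningResult:
    """Output of the individual-level screen."""

    correlations: np.ndarray        # subject x gene r
    pvalues: np.ndarray             # subject x gene p
    significance: np.ndarray        # subject x gene bool at Bonferroni level
    prevalence: np.ndarray          # per-gene fraction of subjects significant
    pool_mask: np.ndarray           # per-gene bool
    gene_ids: list
    alpha: float
    p_threshold: float
    prevalence_threshold: float

    @property
    def pool(self) -> list:
        return [g for g, keep in zip(self.gene_ids, self.pool_mask) if keep]

    def prevalence_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "prevalence": self.prevalence,
                "selected": self.pool_mask,
            }
        )


def screen(
    expr: ExpressionMatrix,
    conn: ConnectivitySet,
    alpha: float = 0.05,
    prevalence_threshold: float = 0.8,
) -> ScreeningResult:
    """Full individual-level screen over all subjects.

    Pearson r is invariant to the per-subject linear normalization of
    connectivity, so normalized or raw connectivity gives identical screens.
    """
    if expr.n_regions != conn.n_regions:
        raise ValueError("expression and connectivity region counts differ")
    p_thr = bonferroni_threshold(alpha, expr.n_genes)
    iu, ju = connection_pairs(expr.n_regions)
    products = expr.values[iu] * expr.values[ju]
    n_sub = conn.n_subjects
    rmat = np.empty((n_sub, expr.n_genes))
    pmat = np.empty((n_sub, expr.n_genes))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(n_sub):
            rmat[s], pmat[s] = _pearson_columns(conn.values[s], products)
    significance = pmat < p_thr
    prevalence = significance.mean(axis=0)
    pool_mask = prevalence > prevalence_threshold
    return ScreeningResult(
        correlations=rmat,
        pvalues=pmat,
        significance=significance,
        prevalence=prevalence,
        pool_mask=pool_mask,
        gene_ids=list(expr.gene_ids),
        alpha=alpha,
        p_threshold=p_thr,
        prevalence_threshold=prevalence_threshold,
    )
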
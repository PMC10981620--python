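"""Pearson/Spearman correlation and per-miRNA ranked gene lists.

The screen's first stage: correlate one miRNA's expression against every
gene in the transcriptome and order genes by the signed coefficient.
Coefficients come from the standard product-moment formula; two-sided
p-values use the t transformation t = r * sqrt((n-2) / (1-r^2)).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .containers import ExpressionMatrix, RankedGeneList

logger = logging.getLogger(__name__)


class ConstantVectorError(ValueError):
    """Correlation is undefined for a zero-variance vector."""


def _validate_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("correlation requires at least 3 observations")
    if np.ptp(x) == 0:
        raise ConstantVectorError("x is constant; correlation undefined")
    if np.ptp(y) == 0:
        raise ConstantVectorError("y is constant; correlation undefined")
    return x, y


def pearson(x, y):
    """Pearson correlation with two-sided t-based p-value.

    Returns ``(r, p)``. Raises :class:`ConstantVectorError` for a
    constant input rather than silently returning NaN.
    """
    x, y = _validate_pair(x, y)
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y):
    """Spearman rank correlation (average ranks for ties), t-based p-value."""
    x, y = _validate_pair(x, y)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _align_samples(mirnas: ExpressionMatrix, genes: ExpressionMatrix):
    """Shared sample IDs of the two matrices, in the miRNA matrix's order."""
    gene_samples = set(genes.sample_ids)
    shared = [s for s in mirnas.sample_ids if s in gene_samples]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared sample(s) between matrices; need >= 3"
        )
    return shared

def rank_genes_for_mirna(
    mirna_id: str, mirnas: ExpressionMatrix, genes: ExpressionMatrix
) -> RankedGeneList:
    """Transcriptome-wide ranked gene list for one miRNA.

    Samples are aligned by ID intersection. Genes with constant
    expression over the shared samples are excluded (counted in
    ``n_dropped_constant``). Ordering is by correlation descending, ties
    broken by gene_id lexicographically.
    """
    shared = _align_samples(mirnas, genes)
    x = mirnas.data.loc[mirna_id, shared].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ConstantVectorError(f"miRNA {mirna_id!r} is constant over shared samples")
    G = genes.data[shared].to_numpy(dtype=float)
    r = _pearson_rows_vs_vector(G, x)
    keep = ~np.isnan(r)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d constant gene(s) before ranking", mirna_id, n_dropped
        )
    gene_ids = np.asarray(genes.feature_ids, dtype=object)[keep]
    r = r[keep]
    order = np.lexsort((gene_ids, -r))
    return RankedGeneList(
        mirna_id=mirna_id,
        gene_ids=list(gene_ids[order]),
        scores=r[order],
        n_dropped_constant=n_dropped,
    )


def rank_all_mirnas(mirnas: ExpressionMatrix, genes: ExpressionMatrix) -> dict:
    """Ranked gene lists for every miRNA in the matrix, keyed by miRNA ID.

    Vectorised over miRNAs (one pass over the gene matrix); equivalent to
    calling :func:`rank_genes_for_mirna` per miRNA.
    """
    shared = _align_samples(mirnas, genes)
    M = mirnas.data[shared].to_numpy(dtype=float)
    G = genes.data[shared].to_numpy(dtype=float)
    gene_ids = np.asarray(genes.feature_ids, dtype=object)

    Gc = G - G.mean(axis=1, keepdims=True)
    gnorm = np.linalg.norm(Gc, axis=1)
    constant_genes = gnorm == 0
    Mc = M - M.mean(axis=1, keepdims=True)
    mnorm = np.linalg.norm(Mc, axis=1)

    out = {}
    R = Gc @ Mc.T  # genes x mirnas cross-products
    for j, mirna_id in enumerate(mirnas.feature_ids):
        if mnorm[j] == 0:
            raise ConstantVectorError(
                f"miRNA {mirna_id!r} is constant over shared samples"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = R[:, j] / (gnorm * mnorm[j])
        r = np.clip(r, -1.0, 1.0)
        keep = ~constant_genes
        ids = gene_ids[keep]
        rj = r[keep]
        order = np.lexsort((ids, -rj))
        out[mirna_id] = RankedGeneList(
            mirna_id=mirna_id,
            gene_ids=list(ids[order]),
            scores=rj[order],
            n_dropped_constant=int(constant_genes.sum()),
        )
    return out


def _pearson_rows_vs_vector(G: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson r of each row of G against x; NaN for constant rows."""
    Gc = G - G.mean(axis=1, keepdims=True)
    xc = x - x.mean()
    gnorm = np.linalg.norm(Gc, axis=1)
    xnorm = np.linalg.norm(xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Gc @ xc) / (gnorm * xnorm)
    r[gnorm == 0] = np.nan
    return np.clip(r, -1.0, 1.0)
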
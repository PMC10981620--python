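"""Single-sample GSEA: per-sample, per-signature enrichment scores.

For one sample, genes are ordered by expression descending (ties broken
by gene_id) and assigned rank values N..1. The signature score is

    score = sum_i [ P_in(i) - P_out(i) ]

over positions i of the ordered list, where P_in is the cumulative sum
of rank^alpha over in-set genes normalised to 1 and P_out the cumulative
fraction of out-of-set genes. The score depends on expression only
through each sample's ranks — the defining invariance of ssGSEA — so any
per-sample monotone transform of the expression vector leaves it
unchanged. The default exponent alpha = 0.25 is the canonical choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet, GeneSetCollection


class DegenerateSignatureError(ValueError):
    """A signature has <2 genes in, or covers all of, the expression vector."""


@dataclass
class SignatureScoreMatrix:
    """Signatures x samples ssGSEA score matrix."""

    scores: pd.DataFrame  # signatures x samples
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.normalized:
            v = self.scores.to_numpy()
            if v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise ValueError("normalized scores outside [0, 1]")

    @property
    def signature_ids(self) -> list:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list:
        return list(self.scores.columns)

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


def _order_positions(expr: np.ndarray, gene_ids) -> np.ndarray:
    """position_of[j] = 0-based rank position of gene j under
    (expression descending, gene_id ascending)."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    order = np.lexsort((gene_ids, -expr))
    position_of = np.empty(len(expr), dtype=np.int64)
    position_of[order] = np.arange(len(expr))
    return position_of


def _score_from_positions(pos_in: np.ndarray, n: int, alpha: float) -> float:
    """ssGSEA score given the in-set genes' rank positions (0-based).

    Uses the closed form of the cumulative sums: a term entering at
    position j contributes to the running difference at every later
    position, so

        sum_i P_in(i)  = sum_j w_j * (n - j) / W,   w_j = (n - j)^alpha
        sum_i P_out(i) = sum_{j not in set} (n - j) / (n - k).
    """
    k = len(pos_in)
    if k < 2:
        raise DegenerateSignatureError("signature has fewer than 2 genes in the vector")
    if k >= n:
        raise DegenerateSignatureError("signature covers the entire expression vector")
    rank_val = n - pos_in.astype(float)  # top gene has rank value n
    w = rank_val**alpha
    sum_in = float((w * rank_val).sum() / w.sum())
    total = n * (n + 1) / 2.0  # sum of (n - j) over all positions
    sum_out = (total - rank_val.sum()) / (n - k)
    return sum_in - sum_out


def ssgsea_sample_score(
    sample_expr, gene_ids, gene_set: GeneSet, alpha: float = 0.25
) -> float:
    """ssGSEA score of one gene set in one sample's expression vector."""
    expr = np.asarray(sample_expr, dtype=float)
    if len(expr) != len(gene_ids):
        raise ValueError("expression vector and gene_ids length mismatch")
    position_of = _order_positions(expr, gene_ids)
    idx = {g: i for i, g in enumerate(gene_ids)}
    members = [idx[g] for g in gene_set.members if g in idx]
    pos_in = np.sort(position_of[members])
    return _score_from_positions(pos_in, len(expr), alpha)


def score_matrix(
    genes: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> SignatureScoreMatrix:
    """ssGSEA scores for every (signature, sample) pair.

    Signatures degenerate in any sample (fewer than 2 member genes
    present, or covering the whole gene universe) are dropped with a
    report attached as ``dropped_signatures``; if all are degenerate an
    error is raised. With ``normalize`` the whole matrix is linearly
    rescaled by its global range into [0, 1], preserving
    between-signature comparability.
    """
    G = genes.values
    gene_ids = genes.feature_ids
    n, n_samples = G.shape
    idx = {g: i for i, g in enumerate(gene_ids)}

    member_rows = []
    kept, dropped = [], []
    for s in collection:
        rows = np.asarray([idx[g] for g in s.members if g in idx], dtype=np.int64)
        if len(rows) < 2:
            dropped.append((s.set_id, f"only {len(rows)} member(s) in matrix"))
        elif len(rows) >= n:
            dropped.append((s.set_id, "covers entire gene universe"))
        else:
            kept.append(s.set_id)
            member_rows.append(rows)
    if not kept:
        raise DegenerateSignatureError("all signatures are degenerate")

    out = np.empty((len(kept), n_samples))
    for j in range(n_samples):
        position_of = _order_positions(G[:, j], gene_ids)
        for i, rows in enumerate(member_rows):
            pos_in = np.sort(position_of[rows])
            out[i, j] = _score_from_positions(pos_in, n, alpha)

    if normalize:
        lo, hi = out.min(), out.max()
        if hi > lo:
            out = (out - lo) / (hi - lo)
        else:
            out = np.zeros_like(out)
    result = SignatureScoreMatrix(
        pd.DataFrame(out, index=kept, columns=genes.sample_ids), normalized=normalize
    )
    result.dropped_signatures = dropped
    return result
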
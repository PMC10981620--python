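"""miRNA vs immune-signature correlation (the heatmap-style analysis).

Each miRNA's expression is Spearman-correlated with every signature's
per-sample ssGSEA score over the shared samples. Spearman is invariant
to the global linear normalisation of the score matrix, so normalised
and raw scores give identical coefficients; the directionality summary
(fraction of positive correlations, mean rho, significant-positive
count) captures whether a miRNA tracks anti-cancer immune programmes
overall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .ssgsea import SignatureScoreMatrix


@dataclass
class SignatureCorrelationMatrix:
    rho: pd.DataFrame  # mirnas x signatures
    p: pd.DataFrame
    n_samples_used: int

    def __post_init__(self) -> None:
        if self.rho.shape != self.p.shape:
            raise ValueError("rho and p matrices differ in shape")
        v = self.rho.to_numpy()
        if np.any(v > 1 + 1e-9) or np.any(v < -1 - 1e-9):
            raise ValueError("rho entries outside [-1, 1]")

    @property
    def mirna_ids(self) -> list:
        return list(self.rho.index)

    @property
    def signature_ids(self) -> list:
        return list(self.rho.columns)


def correlate_mirnas_with_signatures(
    mirnas: ExpressionMatrix, scores: SignatureScoreMatrix
) -> SignatureCorrelationMatrix:
    """Spearman rho and p for every (miRNA, signature) pair.

    Samples are aligned by ID intersection (>= 3 required). Vectorised:
    both matrices are rank-transformed per feature, then correlated as a
    single matrix product; p-values use the t transformation with
    n - 2 degrees of freedom.
    """
    score_samples = set(scores.sample_ids)
    shared = [s for s in mirnas.sample_ids if s in score_samples]
    n = len(shared)
    if n < 3:
        raise ValueError(f"only {n} shared sample(s); need >= 3")

    M = mirnas.data[shared].to_numpy(dtype=float)
    S = scores.scores[shared].to_numpy(dtype=float)
    RM = stats.rankdata(M, axis=1)
    RS = stats.rankdata(S, axis=1)

    def _centre(a):
        ac = a - a.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(ac, axis=1, keepdims=True)
        norm[norm == 0] = np.nan
        return ac / norm

    rho = _centre(RM) @ _centre(RS).T
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(t)] = 0.0  # |rho| == 1
    return SignatureCorrelationMatrix(
        rho=pd.DataFrame(rho, index=mirnas.feature_ids, columns=scores.signature_ids),
        p=pd.DataFrame(p, index=mirnas.feature_ids, columns=scores.signature_ids),
        n_samples_used=n,
    )


def directionality_summary(matrix: SignatureCorrelationMatrix, mirna_id: str) -> dict:
    """Directionality of one miRNA's signature correlations.

    Returns ``fraction_positive``, ``mean_rho`` and
    ``n_significant_positive`` (rho > 0 with p < 0.05) over all
    signatures.
    """
    if mirna_id not in matrix.rho.index:
        raise KeyError(f"unknown miRNA id {mirna_id!r}")
    rho = matrix.rho.loc[mirna_id].to_numpy()
    p = matrix.p.loc[mirna_id].to_numpy()
    return {
        "mirna_id": mirna_id,
        "fraction_positive": float((rho > 0).mean()),
        "mean_rho": float(rho.mean()),
        "n_significant_positive": int(((rho > 0) & (p < 0.05)).sum()),
        "n_signatures": int(len(rho)),
    }
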
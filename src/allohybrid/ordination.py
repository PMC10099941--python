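"""Sample ordination: leading-log-fold-change MDS and PCA.

The MDS distance between two samples is the root-mean-square of the largest
``top`` squared log2 expression differences, the top genes chosen per pair
("leading logFC").  Classical (Torgerson) MDS embeds the distance matrix;
PCA on log-transformed TMM-adjusted TPM serves as the independent check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from allohybrid.normalize import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame        # samples x k
    method: str                      # leading_logFC_MDS | PCA
    explained: np.ndarray            # per-axis share of (positive) eigenmass
    distance_matrix: pd.DataFrame | None = None


def leading_logfc_distance(logcpm: NormalizedMatrix, top: int = 500) -> pd.DataFrame:
    """Pairwise leading-logFC distances.

    d(i, j) = sqrt(mean of the ``top`` largest squared log2 differences
    between samples i and j); genes are re-ranked for every pair.
    """
    if top < 1:
        raise ValueError("top must be >= 1")
    vals = logcpm.values.to_numpy(dtype=float)
    g, n = vals.shape
    if top > g:
        logger.warning("top=%d exceeds %d genes; using all genes", top, g)
        top = g
    d = np.zeros((n, n))
    for i in range(n):
        diff2 = (vals[:, i][:, None] - vals[:, i + 1:]) ** 2
        if diff2.shape[1]:
            part = np.partition(diff2, g - top, axis=0)[g - top:, :]
            d[i, i + 1:] = np.sqrt(part.mean(axis=0))
    d = d + d.T
    cols = logcpm.values.columns
    return pd.DataFrame(d, index=cols, columns=cols)


def classical_mds(dist: pd.DataFrame, k: int = 2) -> OrdinationResult:
    """Torgerson MDS: double-center -D^2/2, eigendecompose, scale by sqrt(eig).

    Axis signs are indeterminate.  If fewer than ``k`` positive eigenvalues
    exist the embedding is truncated with a warning.
    """
    d = dist.to_numpy(dtype=float)
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("invalid distance matrix")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-9 * abs(eigval[0])) if eigval[0] > 0 else eigval > 1e-12
    n_pos = int(pos.sum())
    if n_pos < k:
        logger.warning("only %d positive eigenvalues; truncating from k=%d", n_pos, k)
        k_eff = max(n_pos, 0)
    else:
        k_eff = k
    coords = np.zeros((n, k))
    if k_eff:
        coords[:, :k_eff] = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
    explained = (eigval[:k] / eigval[pos].sum()) if n_pos else np.zeros(k)
    return OrdinationResult(
        pd.DataFrame(coords, index=dist.index,
                     columns=[f"dim{i+1}" for i in range(k)]),
        "leading_logFC_MDS",
        np.asarray(explained),
        distance_matrix=dist,
    )


def mds(logcpm: NormalizedMatrix, top: int = 500, k: int = 2) -> OrdinationResult:
    """Leading-logFC MDS of samples from a log-CPM matrix."""
    return classical_mds(leading_logfc_distance(logcpm, top), k)


def pca_scores(norm: NormalizedMatrix, log_transform: bool = True,
               k: int = 2) -> OrdinationResult:
    """Gene-centered PCA of samples via SVD.

    By default operates on log2(value + 1); intended for TMM-adjusted TPM.
    """
    vals = norm.values.to_numpy(dtype=float)
    if log_transform:
        vals = np.log2(vals + 1.0)
    centered = (vals - vals.mean(axis=1, keepdims=True)).T  # samples x genes
    if np.allclose(centered, 0):
        logger.warning("constant matrix; PCA scores are all zero")
        coords = np.zeros((centered.shape[0], k))
        return OrdinationResult(
            pd.DataFrame(coords, index=norm.values.columns,
                         columns=[f"PC{i+1}" for i in range(k)]),
            "PCA", np.zeros(k))
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(k, len(s))
    scores = u[:, :k] * s[:k]
    explained = (s ** 2) / (s ** 2).sum()
    return OrdinationResult(
        pd.DataFrame(scores, index=norm.values.columns,
                     columns=[f"PC{i+1}" for i in range(k)]),
        "PCA", explained[:k])
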
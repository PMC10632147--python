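"""TF-IDF normalization, LSI and between-cluster analysis (BCA).

LSI is the standard normalization/reduction for single-nucleus ATAC
count matrices: term-frequency/inverse-document-frequency scaling
followed by truncated SVD.  Downstream consumers conventionally drop
component 1 (it tracks sequencing depth) and use components 2..30 or
2..50.

BCA is a supervised reduction for trajectory input: it projects cells
onto the leading eigenvectors of the between-cluster scatter
``S_B = sum_k |C_k| mu_k^T mu_k`` -- note the grand mean is *not*
subtracted, unlike the classical LDA between-class scatter; an optional
``center`` flag restores the conventional behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds


def tfidf(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """log(1 + scale * TF * IDF) normalization of a peak x cell count matrix.

    TF_ij = x_ij / colsum_j, IDF_i = n_cells / rowsum_i.  All-zero peaks
    make IDF undefined and raise; all-zero cells are likewise rejected.
    """
    counts = np.asarray(counts, dtype=float)
    colsum = counts.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError(f"all-zero cell at column {int(np.flatnonzero(colsum == 0)[0])}")
    rowsum = counts.sum(axis=1)
    if (rowsum == 0).any():
        raise ValueError(f"all-zero peak at row {int(np.flatnonzero(rowsum == 0)[0])}")
    tf = counts / colsum[None, :]
    idf = counts.shape[1] / rowsum
    return np.log1p(scale * tf * idf[:, None])


@dataclass
class LSIResult:
    embedding: np.ndarray  # cells x components, scaled by singular values
    singular_values: np.ndarray
    components: np.ndarray  # feature loadings, components x features
    rank_deficient: bool = False


def lsi(tfidf_matrix: np.ndarray, n_components: int = 50) -> LSIResult:
    """Truncated SVD of the TF-IDF matrix (features x cells).

    The cell embedding is ``V * S``.  Signs are fixed deterministically
    (largest-magnitude feature loading positive per component) and
    components are ordered by decreasing singular value.  If the matrix
    has rank below ``n_components`` the attained rank is returned with
    ``rank_deficient=True``.
    """
    X = np.asarray(tfidf_matrix, dtype=float)
    if n_components >= min(X.shape):
        raise ValueError("n_components must be smaller than both matrix dimensions")
    if min(X.shape) <= 300:
        # dense path: exact and robust to rank deficiency on small inputs
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components, :]
    else:
        U, S, Vt = svds(X, k=n_components, v0=np.ones(min(X.shape)))
        order = np.argsort(S)[::-1]
        U, S, Vt = U[:, order], S[order], Vt[order, :]
    tol = max(X.shape) * np.finfo(float).eps * (S[0] if S[0] > 0 else 1.0)
    rank_deficient = bool((S <= tol).any())
    for j in range(len(S)):
        pivot = np.argmax(np.abs(U[:, j]))
        if U[pivot, j] < 0:
            U[:, j] *= -1
            Vt[j, :] *= -1
    return LSIResult(
        embedding=(Vt * S[:, None]).T,
        singular_values=S,
        components=U.T,
        rank_deficient=rank_deficient,
    )


def lsi_trajectory_components(result: LSIResult, upto: int = 50) -> np.ndarray:
    """Components 2..upto of an LSI embedding (component 1 dropped)."""
    return result.embedding[:, 1:upto]


@dataclass
class BCAModel:
    centroids: pd.DataFrame  # cluster x feature means
    scatter: np.ndarray  # p x p between-cluster scatter S_B
    axes: np.ndarray  # p x r orthonormal eigenvectors W
    eigenvalues: np.ndarray  # r values, non-increasing
    cluster_sizes: pd.Series
    two_cluster_warning: bool = False


def bca(X: np.ndarray, clusters, r: int | None = None, center: bool = False):
    """Between-cluster analysis of a cell x feature matrix.

    Maximizes tr(W^T S_B W) over orthonormal W with
    ``S_B = sum_k |C_k| mu_k^T mu_k``; the solution is the top
    ``r = K - 1`` eigenvectors of S_B.  Returns ``(BCAModel, Y)`` with the
    embedding ``Y = X W``.  ``center=True`` subtracts the grand mean from
    X first (classical scatter; off by default for fidelity to the
    uncentred definition).  K = 2 yields a one-dimensional embedding and
    is flagged: downstream 2-D consumers need at least three clusters.
    """
    X = np.asarray(X, dtype=float)
    labels = pd.Series(list(clusters))
    uniq = sorted(labels.unique())
    K = len(uniq)
    if K < 2:
        raise ValueError("BCA requires at least two clusters")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if r is None:
        r = K - 1
    sizes = labels.value_counts().reindex(uniq)
    mus = np.vstack([X[(labels == k).to_numpy()].mean(axis=0) for k in uniq])
    M = mus * np.sqrt(sizes.to_numpy())[:, None]
    S_B = M.T @ M
    evals, evecs = np.linalg.eigh(S_B)
    order = np.argsort(evals)[::-1][:r]
    W = evecs[:, order]
    evals = evals[order]
    for j in range(W.shape[1]):
        pivot = np.argmax(np.abs(W[:, j]))
        if W[pivot, j] < 0:
            W[:, j] *= -1
    model = BCAModel(
        centroids=pd.DataFrame(mus, index=uniq),
        scatter=S_B,
        axes=W,
        eigenvalues=evals,
        cluster_sizes=sizes,
        two_cluster_warning=(K == 2),
    )
    return model, X @ W
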
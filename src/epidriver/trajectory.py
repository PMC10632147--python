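"""Case-level primary-to-metastatic trajectory analysis.

The supervised BCA embedding (see :mod:`epidriver.embedding`) is the
core dimensionality reduction here.  Lineage fitting is a documented
simplification of curve-based trajectory tools: the cluster path is the
minimum-spanning-tree path over cluster centroids starting from the
designated start cluster, and pseudotime is the arc-length coordinate of
each cell's orthogonal projection onto the piecewise-linear centroid
path.  Downstream, TF motif scores are correlated with pseudotime
(Pearson, BH FDR) and metastasis-associated peaks are selected by
cross-validated lasso regression of pseudotime (or a TF score) on the
peak matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from sklearn.linear_model import LassoCV, Lasso
from sklearn.model_selection import KFold

from epidriver.differential import _adjust
from epidriver.embedding import bca, lsi_trajectory_components


@dataclass
class TrajectoryResult:
    embedding: np.ndarray  # cells x 2 (BCA) or cells x d (LSI fallback)
    cluster_path: list  # ordered cluster ids from the start cluster
    pseudotime: np.ndarray  # per-cell arc-length coordinate, >= 0


def assemble_trajectory_input(
    lsi_embedding: np.ndarray,
    conditions,
    case_clusters=None,
    normal_label: str = "normal",
    primary_label: str = "primary",
    met_label: str = "metastatic",
):
    """Choose the reduction and clustering for one case.

    X is LSI components 2..50.  When normal cells are present the
    condition annotation (normal / primary / metastatic, K = 3) is the
    clustering and BCA provides a 2-D embedding; with only two clusters
    BCA would be one-dimensional, so the LSI components themselves are
    used (mode "lsi").  The start cluster is the normal cluster if
    present, else primary.

    Returns (X, clusters, start_cluster, mode).
    """
    conditions = pd.Series(list(conditions))
    present = set(conditions.unique())
    if primary_label not in present:
        raise ValueError("case must contain primary cells")
    if met_label not in present:
        raise ValueError("case must contain metastatic cells")
    from epidriver.embedding import LSIResult

    X = (
        lsi_trajectory_components(lsi_embedding)
        if isinstance(lsi_embedding, LSIResult)
        else np.asarray(lsi_embedding)
    )
    if normal_label in present:
        clusters = conditions
        start = normal_label
    else:
        clusters = pd.Series(list(case_clusters)) if case_clusters is not None else conditions
        start = primary_label if clusters.equals(conditions) else clusters[conditions == primary_label].mode()[0]
    K = clusters.nunique()
    if K < 2:
        raise ValueError("need at least two clusters")
    mode = "bca" if K >= 3 else "lsi"
    return X, clusters, start, mode


def fit_pseudotime(X: np.ndarray, clusters, start_cluster, mode: str = "bca") -> TrajectoryResult:
    """Pseudotime along the MST path of cluster centroids.

    With mode "bca" the embedding is the first two BCA components of X
    given the clustering; with "lsi" X is used as-is.  Cells project
    orthogonally onto the piecewise-linear path through the centroids
    (ordered by a depth-first traversal of the MST from the start
    cluster); pseudotime is the arc length of the projection, so the
    start centroid sits at 0.  Deterministic; rigid rotations of the
    embedding leave pseudotime unchanged.
    """
    clusters = pd.Series(list(clusters))
    if start_cluster not in set(clusters):
        raise ValueError("start cluster not present")
    if mode == "bca":
        model, Y = bca(X, clusters)
        emb = Y[:, : min(2, Y.shape[1])]
    else:
        emb = np.asarray(X, dtype=float)
    uniq = sorted(clusters.unique())
    cent = np.vstack([emb[(clusters == k).to_numpy()].mean(axis=0) for k in uniq])
    D = squareform(pdist(cent))
    if np.any(D[np.triu_indices_from(D, 1)] == 0):
        raise ValueError("degenerate geometry: identical cluster centroids")
    mst = minimum_spanning_tree(D).toarray()
    adj = (mst + mst.T) > 0
    # depth-first traversal from the start cluster defines the path order
    start_idx = uniq.index(start_cluster)
    order, stack, seen = [], [start_idx], set()
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        order.append(node)
        nbrs = sorted(np.flatnonzero(adj[node]), key=lambda j: D[node, j], reverse=True)
        stack.extend(j for j in nbrs if j not in seen)
    path = cent[order]
    seg = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    pts = np.empty(len(emb))
    for i, x in enumerate(emb):
        best_d, best_t = np.inf, 0.0
        for s in range(len(seg)):
            v = seg[s]
            t = np.clip((x - path[s]) @ v / (seg_len[s] ** 2), 0.0, 1.0)
            proj = path[s] + t * v
            d = np.linalg.norm(x - proj)
            if d < best_d:
                best_d = d
                best_t = cum[s] + t * seg_len[s]
        pts[i] = best_t
    return TrajectoryResult(embedding=emb, cluster_path=[uniq[i] for i in order], pseudotime=pts)


def correlate_pseudotime_tf(pseudotime: np.ndarray, motif_scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each TF motif score with pseudotime, BH FDR
    over the full motif panel; constant TFs are excluded (logged in
    ``attrs['excluded']``)."""
    pt = np.asarray(pseudotime, dtype=float)
    excluded = []
    rows = []
    for tf in motif_scores.columns:
        x = motif_scores[tf].to_numpy(float)
        if x.std() == 0 or pt.std() == 0:
            excluded.append(tf)
            continue
        r, p = stats.pearsonr(pt, x)
        rows.append((tf, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["tf", "r", "p"])
    if len(out):
        out["fdr"] = _adjust(out["p"].to_numpy(), "bh")
    out.attrs["excluded"] = excluded
    return out


def lasso_select_peaks(
    response: np.ndarray,
    peak_matrix: np.ndarray,
    peak_ids=None,
    n_folds: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Sparse peak selection by cross-validated lasso.

    ``peak_matrix`` is cells x peaks (p >> n allowed).  Lambda is chosen
    at the 10-fold cross-validation minimum over a descending path (fold
    assignment seeded); selected peaks are those with non-zero
    coefficients at that lambda.
    """
    y = np.asarray(response, dtype=float)
    if y.std() == 0:
        raise ValueError("zero-variance response")
    X = np.asarray(peak_matrix, dtype=float)
    if X.shape[0] < 50:
        raise ValueError("need at least 50 cells")
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=100, tol=tol, max_iter=5000)
    model.fit(X, y)
    coef = model.coef_
    if peak_ids is None:
        peak_ids = np.arange(X.shape[1])
    sel = np.flatnonzero(coef != 0)
    out = pd.DataFrame({"peak_id": np.asarray(peak_ids, dtype=object)[sel], "coef": coef[sel]})
    out.attrs["alpha"] = float(model.alpha_)
    return out


def peak_ora(
    selected_genes,
    pathway_gmt: dict,
    universe_genes,
) -> pd.DataFrame:
    """Hypergeometric over-representation of (peak-derived) genes in each
    pathway, within a stated gene universe; BH across pathways."""
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected_genes) & universe
    rows = []
    for pw, genes in pathway_gmt.items():
        genes = set(genes) & universe
        k = len(selected & genes)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(genes), len(selected)))
        rows.append((pw, k, len(genes), p))
    out = pd.DataFrame(rows, columns=["pathway", "overlap", "pathway_size", "p"])
    if len(out):
        out["fdr"] = _adjust(out["p"].to_numpy(), "bh")
    return out.sort_values("p", kind="stable").reset_index(drop=True)
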
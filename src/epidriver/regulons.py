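"""Regulon stability filtering, AUC activity scoring and enrichment.

A regulon is a transcription factor plus its inferred target-gene set.
Because stochastic GRN inference produces unstable target lists, regulons
are first consolidated across repeated runs (a TF-target pair must appear
in >= 80% of runs; regulons keep >= 20 surviving targets).  Per-cell
activity is then the AUCell statistic: the area under the target-recovery
curve over each cell's expression ranking, normalized by the best
possible curve, evaluated over the top 5% of ranked genes.

``tf_link_enrichment`` implements the sampling z-test for whether a TF's
targets are enriched among genes linked to accessible regions containing
that TF's motif: 500 draws of N random expressed genes give the null
moments (mu, sigma) of the linked-gene count, and the observed count M is
converted to z = (M - mu)/sigma and a one-sided normal p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from epidriver.differential import _adjust, log2_fold_change


def stability_filter(
    run_outputs: list,
    min_frac: float = 0.8,
    min_targets: int = 20,
) -> pd.DataFrame:
    """Consolidate TF -> target sets over repeated inference runs.

    Keeps TF-target pairs present in >= ceil(min_frac * n_runs) runs,
    then drops regulons with fewer than ``min_targets`` surviving targets.
    Returns a (tf, target, occurrence) table.
    """
    if len(run_outputs) < 1:
        raise ValueError("need at least one run")
    n_runs = len(run_outputs)
    need = math.ceil(min_frac * n_runs)
    counts: dict = {}
    for run in run_outputs:
        for tf, targets in run.items():
            for t in targets:
                counts[(tf, t)] = counts.get((tf, t), 0) + 1
    rows = [(tf, t, c) for (tf, t), c in counts.items() if c >= need]
    df = pd.DataFrame(rows, columns=["tf", "target", "occurrence"])
    sizes = df.groupby("tf")["target"].transform("count")
    return (
        df[sizes >= min_targets]
        .sort_values(["tf", "target"], kind="stable")
        .reset_index(drop=True)
    )


def auc_score(
    expression: np.ndarray,
    gene_ids,
    target_set,
    top_frac: float = 0.05,
) -> np.ndarray:
    """Per-cell AUCell activity of one target set.

    Genes are ranked per cell by descending expression (ties broken by
    gene index, so scores are deterministic).  With T = ceil(top_frac *
    n_genes) and recovery curve H(k) = #targets among the top k ranks,
    the score is sum_{k<=T} H(k) / sum_{k<=T} H_max(k), where H_max
    front-loads all targets; scores lie in [0, 1] and are invariant to
    monotone transforms of expression within a cell.
    """
    gene_ids = list(gene_ids)
    idx = [i for i, g in enumerate(gene_ids) if g in set(target_set)]
    if not idx:
        raise ValueError("target set shares no genes with the expression matrix")
    n_genes, n_cells = expression.shape
    T = math.ceil(top_frac * n_genes)
    is_target = np.zeros(n_genes, dtype=bool)
    is_target[idx] = True
    # stable argsort on -expression keeps gene order among ties
    order = np.argsort(-np.asarray(expression, dtype=float), axis=0, kind="stable")
    hits = is_target[order[:T, :]]  # T x cells
    H = np.cumsum(hits, axis=0)
    n_t = len(idx)
    h_max = np.cumsum(np.minimum(np.arange(1, T + 1), n_t))[-1]
    return H.sum(axis=0) / h_max


def score_regulons(
    expression: np.ndarray, gene_ids, regulons: pd.DataFrame, top_frac: float = 0.05
) -> pd.DataFrame:
    """AUC activity matrix (regulon TF x cell) for a stability-filtered
    regulon table."""
    rows = {}
    for tf, sub in regulons.groupby("tf"):
        rows[tf] = auc_score(expression, gene_ids, set(sub["target"]), top_frac)
    return pd.DataFrame(rows).T


def prioritize_specific_regulons(
    auc_matrix: pd.DataFrame,
    cell_groups,
    fdr: float = 0.05,
    min_ratio: float = 1.5,
    n_top: int = 10,
) -> dict:
    """Top group-specific regulons per cell group.

    Per regulon and focal group: two-sided Wilcoxon of AUC scores versus
    all other cells, BH across regulons; selected when FDR < 0.05, the
    focal/other mean ratio exceeds ``min_ratio`` and the focal-group mean
    exceeds the median of per-group means.  The top ``n_top`` by fold
    change are reported per group.
    """
    groups = pd.Series(list(cell_groups), index=auc_matrix.columns)
    uniq = sorted(groups.unique())
    if len(uniq) < 2:
        raise ValueError("need at least two cell groups")
    group_means = pd.DataFrame(
        {g: auc_matrix.loc[:, (groups == g).to_numpy()].mean(axis=1) for g in uniq}
    )
    median_of_means = group_means.median(axis=1)
    out = {}
    for g in uniq:
        focal = auc_matrix.loc[:, (groups == g).to_numpy()].to_numpy(float)
        rest = auc_matrix.loc[:, (groups != g).to_numpy()].to_numpy(float)
        p = stats.mannwhitneyu(focal, rest, axis=1, alternative="two-sided", method="asymptotic").pvalue
        padj = _adjust(np.atleast_1d(p), "bh")
        ratio = group_means[g] / np.maximum(rest.mean(axis=1), 1e-12)
        sel = (
            (padj < fdr)
            & (ratio.to_numpy() > min_ratio)
            & (group_means[g].to_numpy() > median_of_means.to_numpy())
        )
        tab = pd.DataFrame(
            {
                "tf": auc_matrix.index,
                "fold_change": ratio.to_numpy(),
                "fdr": padj,
            }
        )[sel]
        out[g] = tab.sort_values("fold_change", ascending=False, kind="stable").head(n_top).reset_index(drop=True)
    return out


def annotate_cancer_specific(
    auc_matrix: pd.DataFrame,
    tumour_cells,
    cnc_cells,
    fdr: float = 0.05,
    min_diff: float = 0.01,
    min_log2_ratio: float = 0.1,
) -> pd.DataFrame:
    """Label regulons as cancer-cell-specific vs tissue-specific.

    Cancer-cell-specific requires BH FDR < 0.05, a tumour - CNC mean
    difference > 0.01 and log2(mean ratio) > 0.1; regulons high in both
    compartments are tissue-specific.
    """
    tum = auc_matrix.loc[:, list(tumour_cells)].to_numpy(float)
    cnc = auc_matrix.loc[:, list(cnc_cells)].to_numpy(float)
    if tum.shape[1] == 0 or cnc.shape[1] == 0:
        raise ValueError("both cell groups must be non-empty")
    p = stats.mannwhitneyu(tum, cnc, axis=1, alternative="two-sided", method="asymptotic").pvalue
    padj = _adjust(np.atleast_1d(p), "bh")
    diff = tum.mean(axis=1) - cnc.mean(axis=1)
    log2_ratio = log2_fold_change(tum.mean(axis=1), cnc.mean(axis=1))
    cancer_specific = (padj < fdr) & (diff > min_diff) & (log2_ratio > min_log2_ratio)
    return pd.DataFrame(
        {
            "tf": auc_matrix.index,
            "diff": diff,
            "log2_ratio": log2_ratio,
            "fdr": padj,
            "label": np.where(cancer_specific, "cancer-cell-specific", "tissue-specific"),
        }
    )


@dataclass
class EnrichmentResult:
    tf: str
    M: int
    mu: float
    sigma: float
    z: float
    p_one_sided: float
    fold: float
    degenerate: bool = False


def tf_link_enrichment(
    tf: str,
    targets,
    linked_genes,
    expressed_gene_pool,
    n_samplings: int = 500,
    seed: int = 0,
) -> EnrichmentResult:
    """Sampling z-test: are a TF's targets enriched among genes linked to
    motif-containing accessible regions?

    ``linked_genes`` is the set of genes linked to at least one ACR
    containing the TF motif; the pool is the expressed genes of the
    cancer type.  Each of ``n_samplings`` draws takes |targets| genes
    without replacement from the pool and counts linked genes; the
    observed count M is tested against the Gaussian fit (mu, sigma) of
    those counts, one-sided upper tail.
    """
    pool = sorted(set(expressed_gene_pool))
    targets = set(targets)
    linked = set(linked_genes)
    N = len(targets)
    if not targets <= set(pool):
        raise ValueError("expressed gene pool must contain all targets")
    if len(pool) <= N:
        raise ValueError("pool must be larger than the target set")
    rng = np.random.default_rng(seed)
    pool_arr = np.asarray(pool, dtype=object)
    is_linked = np.asarray([g in linked for g in pool], dtype=bool)
    K = np.empty(n_samplings)
    for i in range(n_samplings):
        draw = rng.choice(len(pool_arr), size=N, replace=False)
        K[i] = is_linked[draw].sum()
    mu = float(K.mean())
    sigma = float(K.std(ddof=1))
    M = len(targets & linked)
    if sigma == 0:
        if M > mu:
            return EnrichmentResult(tf, M, mu, sigma, np.inf, np.nextafter(0, 1), M / mu if mu else np.inf, True)
        if M == mu:
            return EnrichmentResult(tf, M, mu, sigma, 0.0, 0.5, M / mu if mu else 0.0, True)
        return EnrichmentResult(tf, M, mu, sigma, -np.inf, 1.0, M / mu if mu else 0.0, True)
    z = (M - mu) / sigma
    return EnrichmentResult(tf, M, mu, sigma, float(z), float(stats.norm.sf(z)), M / mu if mu else np.inf)


def target_pathway_scores(
    target_sets: dict,
    pathway_gmt: dict,
    universe,
) -> pd.DataFrame:
    """Jaccard index and hypergeometric over-representation of each target
    set against each pathway, BH-adjusted across pathways per set.

    The universe is the expressed-gene background; empty target sets are
    rejected.  Disjoint sets score Jaccard 0 and p = 1 (upper-tail
    convention).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    rows = []
    for name, targets in target_sets.items():
        targets = set(targets) & universe
        if not targets:
            raise ValueError(f"target set {name!r} is empty within the universe")
        ps = []
        for pw, genes in pathway_gmt.items():
            genes = set(genes) & universe
            inter = len(targets & genes)
            union = len(targets | genes)
            jacc = inter / union if union else 0.0
            p = float(stats.hypergeom.sf(inter - 1, len(universe), len(genes), len(targets)))
            ps.append((name, pw, inter, jacc, p))
        padj = _adjust(np.array([r[4] for r in ps]), "bh")
        for r, q in zip(ps, padj):
            rows.append(r + (q,))
    return pd.DataFrame(
        rows, columns=["set", "pathway", "overlap", "jaccard", "p", "p_adj"]
    )
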
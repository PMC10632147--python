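"""Correlation-based peak-to-gene (enhancer-to-gene) linking.

Candidate pairs are peaks within 500 kb of a gene TSS in cells with
joint accessibility and expression measurements.  For each pair the
Pearson correlation r is compared with a null of correlations from
background peaks matched to the focal peak by mean accessibility;
``z = (r - mu_null) / sd_null`` and a one-sided normal p-value gate the
link (r > 0.05 and p < 0.05).

Two corrections follow: a *diffuse-correlation* filter that drops links
whose z-scored correlation does not exceed that of the 100-kb window
containing the peak (broad regional accessibility, not a specific
element, drives those), and exclusion of genes frequently amplified in
cancer cells, whose expression shifts are copy-number driven.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _standardize_rows(M: np.ndarray) -> np.ndarray:
    """Rows scaled to zero mean, unit norm; constant rows become zero."""
    M = np.asarray(M, dtype=float)
    M = M - M.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(M, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return M / norm


def _signed_tss_distance(mid, tss, strand):
    d = mid - tss
    return d if strand == "+" else -d


def link_peaks_to_genes(
    atac: np.ndarray,
    rna: np.ndarray,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    max_dist: float = 5e5,
    n_background: int = 200,
    r_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Correlate peak accessibility with gene expression for all candidate
    pairs and score them against an accessibility-matched background.

    The null for a focal peak consists of the ``n_background`` peaks
    nearest to it in mean accessibility (the matching feature; no
    sequence composition exists for synthetic peaks), correlated with the
    same gene.  Genes with zero expression variance are skipped; if fewer
    than ``n_background`` background peaks exist, at least 20 are
    required.

    Returns a link table with signed distance (transcription direction),
    r, z, one-sided p and a ``retained`` flag (the significance gate;
    later filters update it).
    """
    if atac.shape[1] != rna.shape[1]:
        raise ValueError("peak and gene matrices must share cells (multiome contract)")
    n_peaks = atac.shape[0]
    if n_background < 20:
        raise ValueError("n_background must be >= 20")
    n_bg = min(n_background, n_peaks - 1)
    if n_bg < 20:
        raise ValueError("fewer than 20 background peaks available")

    P = _standardize_rows(atac)
    G = _standardize_rows(rna)
    mean_acc = np.asarray(atac, dtype=float).mean(axis=1)
    acc_order = np.argsort(mean_acc, kind="stable")
    rank_of = np.empty(n_peaks, dtype=int)
    rank_of[acc_order] = np.arange(n_peaks)

    # background peaks = window of n_bg nearest neighbours in the
    # accessibility ordering, excluding the focal peak itself
    def background_rows(row):
        rk = rank_of[row]
        lo = max(0, min(rk - n_bg // 2, n_peaks - n_bg - 1))
        window = acc_order[lo : lo + n_bg + 1]
        return window[window != row][:n_bg]

    mids = ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2).astype(np.int64)
    chroms = peaks["chrom"].to_numpy()
    peak_names = peaks["name"].to_numpy()
    gene_sd = np.asarray(rna, dtype=float).std(axis=1)

    R_full = P @ G.T  # r of every (peak, gene) pair, one GEMM
    rows = []
    skipped_genes = []
    for gi, g in genes.reset_index(drop=True).iterrows():
        on_chrom = np.flatnonzero((chroms == g["chrom"]) & (np.abs(mids - g["tss"]) <= max_dist))
        if len(on_chrom) == 0:
            continue
        if gene_sd[gi] == 0:
            skipped_genes.append(g["gene"])
            continue
        r_all = R_full[:, gi]
        for row in on_chrom:
            null_r = r_all[background_rows(row)]
            mu, sd = null_r.mean(), null_r.std(ddof=1)
            r = float(r_all[row])
            z = (r - mu) / sd if sd > 0 else 0.0
            p = float(stats.norm.sf(z))
            rows.append(
                (
                    peak_names[row],
                    g["gene"],
                    int(_signed_tss_distance(mids[row], g["tss"], g["strand"])),
                    r,
                    float(z),
                    p,
                    f"{g['chrom']}:{mids[row] // 100_000}",
                    bool(r > r_threshold and p < p_threshold),
                )
            )
    links = pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "distance", "r", "z", "p", "window_id", "retained"]
    )
    links.attrs["skipped_genes"] = skipped_genes
    return links


def diffuse_window_filter(
    links: pd.DataFrame,
    atac: np.ndarray,
    rna: np.ndarray,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    window_size: int = 100_000,
    max_dist: float = 5e5,
) -> pd.DataFrame:
    """Drop links explainable by broad regional accessibility.

    Chromosomes are tiled with ``window_size`` windows anchored at 0; a
    peak belongs to the window containing its midpoint.  Window
    accessibility (summed counts of member peaks per cell) is correlated
    with genes whose TSS lies within ``max_dist`` of the window.  Link r
    values are z-scored across all links, window-gene r values across all
    window-gene pairs; a link stays retained only if its z exceeds the z
    of (its window, same gene).  Links never gain retention here (subset
    property).
    """
    out = links.copy()
    if not len(out):
        return out
    mids = ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2).astype(np.int64)
    win_of_peak = pd.Series(
        [f"{c}:{m // window_size}" for c, m in zip(peaks["chrom"], mids)],
        index=peaks["name"].to_numpy(),
    )

    # window accessibility profiles
    win_groups = {}
    for row, w in enumerate(win_of_peak):
        win_groups.setdefault(w, []).append(row)
    win_ids = sorted(win_groups)
    A = np.asarray(atac, dtype=float)
    W = np.vstack([A[win_groups[w]].sum(axis=0) for w in win_ids])
    W_std = _standardize_rows(W)
    G_std = _standardize_rows(rna)

    # window-gene pairs: TSS within max_dist of the window interval
    win_chrom = np.array([w.split(":")[0] for w in win_ids])
    win_start = np.array([int(w.split(":")[1]) * window_size for w in win_ids], dtype=np.int64)
    win_end = win_start + window_size
    pair_rows = []
    gene_names = genes["gene"].to_numpy()
    for gi, g in genes.reset_index(drop=True).iterrows():
        on = np.flatnonzero(
            (win_chrom == g["chrom"])
            & (g["tss"] >= win_start - max_dist)
            & (g["tss"] <= win_end + max_dist)
        )
        for wi in on:
            pair_rows.append((win_ids[wi], gene_names[gi], float(W_std[wi] @ G_std[gi])))
    win_pairs = pd.DataFrame(pair_rows, columns=["window_id", "gene_id", "win_r"])

    def zscore(x):
        x = np.asarray(x, dtype=float)
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    out["link_rz"] = zscore(out["r"])
    win_pairs["win_rz"] = zscore(win_pairs["win_r"])
    out["window_id"] = [win_of_peak[p] for p in out["peak_id"]]
    out = out.merge(win_pairs[["window_id", "gene_id", "win_rz"]], on=["window_id", "gene_id"], how="left")
    win_z = out.pop("win_rz").fillna(-np.inf)  # no window pair -> nothing to beat
    out["retained"] = out["retained"] & (out["link_rz"] > win_z)
    return out


def exclude_cnv_genes(
    gene_cnv: pd.DataFrame, frac_threshold: float = 0.25, count_threshold: int = 2000
) -> set:
    """Genes to drop from linking: amplified in more than ``frac_threshold``
    of cancer cells AND in more than ``count_threshold`` cells (strict
    conjunction)."""
    blocked = gene_cnv[
        (gene_cnv["amp_fraction"] > frac_threshold) & (gene_cnv["amp_cells"] > count_threshold)
    ]
    return set(blocked["gene"])


def transition_links(
    links: pd.DataFrame,
    dacr_results: pd.DataFrame,
    deg_results: pd.DataFrame,
    acr_lfc: float = 0.5,
    gene_lfc: float = 0.25,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Links associated with the normal-to-primary transition.

    A link is kept when its peak is significantly more accessible
    (log2fc > 0.5, FDR < 0.05) and its gene significantly upregulated
    (log2fc > 0.25, FDR < 0.05) in primary cancer cells versus the CNC;
    links with missing statistics are dropped and counted in
    ``attrs['missing_stats']``.
    """
    dacr = dacr_results.set_index("feature_id")
    deg = deg_results.set_index("feature_id")
    keep = []
    missing = 0
    for _, ln in links.iterrows():
        if ln["peak_id"] not in dacr.index or ln["gene_id"] not in deg.index:
            missing += 1
            continue
        a = dacr.loc[ln["peak_id"]]
        g = deg.loc[ln["gene_id"]]
        if (
            a["log2fc"] > acr_lfc
            and a["p_adj"] < fdr
            and g["log2fc"] > gene_lfc
            and g["p_adj"] < fdr
        ):
            keep.append(ln)
    out = pd.DataFrame(keep, columns=links.columns).reset_index(drop=True)
    out.attrs["missing_stats"] = missing
    return out


def enhancer_gene_z(links: pd.DataFrame, peak_elements: pd.DataFrame) -> pd.DataFrame:
    """Enhancer x gene z table: mean link z over the member peaks of each
    enhancer (peaks labelled via ``overlap_elements``)."""
    merged = links.merge(peak_elements[["peak", "element"]], left_on="peak_id", right_on="peak")
    if not len(merged):
        return pd.DataFrame(columns=["element", "gene_id", "z"])
    return (
        merged.groupby(["element", "gene_id"], as_index=False)["z"]
        .mean()
        .rename(columns={"element": "enhancer"})
    )
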
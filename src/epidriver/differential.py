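"""Differential accessibility / expression / motif testing.

Three test families, mirroring how the atlas analyses are layered:

* ``wilcoxon_markers`` -- the default marker test (two-sided rank-sum with
  tie-corrected normal approximation) with detection-fraction pre-filters.
* ``lr_dacr_test`` -- differentially accessible region (DACR) calling by a
  logistic-regression likelihood-ratio test with the per-cell fraction of
  fragments in peaks as a latent covariate, absorbing depth effects.
* ``dam_met_tfs`` -- metastasis-associated TFs requiring concordant,
  FDR-significant shifts in both motif scores and regulon activity.

Convention: Bonferroni adjustment for DEG/DACR calls, Benjamini-Hochberg
for regulon / motif / correlation families.  The fold-change pseudocount
(1e-4 on group means) is configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FC_PSEUDOCOUNT = 1e-4


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method in ("bh", "fdr_bh", "BH"):
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment {method!r}")


def log2_fold_change(mean_a, mean_b, pseudocount: float = FC_PSEUDOCOUNT):
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2((np.asarray(mean_a) + pseudocount) / (np.asarray(mean_b) + pseudocount))


def wilcoxon_markers(
    matrix: np.ndarray,
    group_a,
    group_b,
    feature_ids=None,
    min_pct: float = 0.05,
    min_diff_pct: float = 0.0,
    logfc_threshold: float = 0.0,
    only_pos: bool = False,
    adjust: str = "bonferroni",
    pseudocount: float = FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Rank-sum marker test between two cell groups on a feature x cell matrix.

    Features are pre-filtered on detection fractions (fraction of cells
    with value > 0): max(pct_1, pct_2) >= min_pct, |pct_1 - pct_2| >=
    min_diff_pct, and |log2fc| >= logfc_threshold (log2fc >= threshold when
    ``only_pos``).  Adjusted p-values are computed over the tested
    features.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    A = matrix[:, group_a]
    B = matrix[:, group_b]
    pct1 = (A > 0).mean(axis=1)
    pct2 = (B > 0).mean(axis=1)
    lfc = log2_fold_change(A.mean(axis=1), B.mean(axis=1), pseudocount)
    keep = np.maximum(pct1, pct2) >= min_pct
    keep &= np.abs(pct1 - pct2) >= min_diff_pct
    keep &= (lfc >= logfc_threshold) if only_pos else (np.abs(lfc) >= logfc_threshold)
    idx = np.flatnonzero(keep)
    if feature_ids is None:
        feature_ids = np.arange(matrix.shape[0])
    feature_ids = np.asarray(feature_ids, dtype=object)
    if len(idx) == 0:
        return pd.DataFrame(columns=["feature_id", "log2fc", "pct_1", "pct_2", "p", "p_adj"])
    res = stats.mannwhitneyu(
        A[idx], B[idx], axis=1, alternative="two-sided", method="asymptotic"
    )
    p = np.atleast_1d(res.pvalue)
    return pd.DataFrame(
        {
            "feature_id": feature_ids[idx],
            "log2fc": lfc[idx],
            "pct_1": pct1[idx],
            "pct_2": pct2[idx],
            "p": p,
            "p_adj": _adjust(p, adjust),
        }
    )


def _logistic_loglik(y, eta):
    # log-likelihood of a Bernoulli GLM at linear predictor eta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fit_logistic(y: np.ndarray, X: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Newton/IRLS logistic fit; bounded iterations so (quasi-)separated
    features return a converged-deviance estimate with a flag."""
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X * w[:, None]).T @ X + 1e-10 * np.eye(X.shape[1])
        g = X.T @ (y - mu)
        try:
            beta = beta + np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        ll = _logistic_loglik(y, X @ beta)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    return beta, _logistic_loglik(y, X @ beta), converged


def lr_dacr_test(
    access_matrix: np.ndarray,
    groups,
    latent,
    feature_ids=None,
    adjust: str = "bonferroni",
    pseudocount: float = FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Likelihood-ratio DACR test with a latent depth covariate.

    Per feature, compares logit(group) ~ feature + latent against
    logit(group) ~ latent; the p-value comes from chi-square(1) on the
    deviance difference.  Invariant to affine rescaling of the latent
    covariate.
    """
    y = np.asarray(groups, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("groups must be binary 0/1 labels")
    latent = np.asarray(latent, dtype=float)
    if not np.isfinite(latent).all():
        raise ValueError("latent covariate must be finite")
    n = len(y)
    ones = np.ones(n)
    X0 = np.column_stack([ones, latent])
    _, ll0, _ = _fit_logistic(y, X0)
    if feature_ids is None:
        feature_ids = np.arange(access_matrix.shape[0])
    rows = []
    in_a = y == 1
    for i in range(access_matrix.shape[0]):
        f = np.asarray(access_matrix[i], dtype=float)
        X1 = np.column_stack([ones, f, latent])
        _, ll1, converged = _fit_logistic(y, X1)
        stat = max(0.0, 2.0 * (ll1 - ll0))
        p = stats.chi2.sf(stat, df=1)
        rows.append(
            (
                feature_ids[i],
                log2_fold_change(f[in_a].mean(), f[~in_a].mean(), pseudocount),
                float((f[in_a] > 0).mean()),
                float((f[~in_a] > 0).mean()),
                p,
                not converged,
            )
        )
    out = pd.DataFrame(
        rows, columns=["feature_id", "log2fc", "pct_1", "pct_2", "p", "separation_flag"]
    )
    out["p_adj"] = _adjust(out["p"].to_numpy(), adjust)
    return out


def cnv_filter_dacrs(dacrs: pd.DataFrame, gene_cnv: pd.DataFrame, threshold: float = 0.25):
    """Drop DACRs whose direction is explainable by copy number.

    ``gene_cnv`` maps genes to AMP / DEL scores (fraction of cancer cells
    with the nearest gene amplified / deleted).  A DACR with log2fc > 0 is
    removed when AMP > 0.25; log2fc < 0 removed when DEL > 0.25 (strict).
    DACRs whose gene is absent from the table pass with a warning flag.
    """
    amp = gene_cnv.set_index("gene")["amp"] if "gene" in gene_cnv.columns else gene_cnv["amp"]
    dele = gene_cnv.set_index("gene")["del"] if "gene" in gene_cnv.columns else gene_cnv["del"]
    out = dacrs.copy()
    a = out["nearest_gene"].map(amp)
    d = out["nearest_gene"].map(dele)
    out["cnv_unannotated"] = a.isna() | d.isna()
    drop = ((out["log2fc"] > 0) & (a > threshold)) | ((out["log2fc"] < 0) & (d > threshold))
    drop = drop.fillna(False) & ~out["cnv_unannotated"]
    return out[~drop].reset_index(drop=True)


def prioritize_met_dacrs(per_sample_log2fc: pd.DataFrame, n_top: int = 200) -> pd.DataFrame:
    """Rank metastasis DACRs by (fraction of metastatic samples with
    positive fold change, then mean fold change), descending; keep the top
    ``n_top``."""
    if per_sample_log2fc.shape[1] < 1:
        raise ValueError("need at least one metastatic sample")
    frac_pos = (per_sample_log2fc > 0).mean(axis=1)
    mean_fc = per_sample_log2fc.mean(axis=1)
    ranked = (
        pd.DataFrame({"frac_pos": frac_pos, "mean_log2fc": mean_fc})
        .sort_values(["frac_pos", "mean_log2fc"], ascending=False, kind="stable")
        .head(n_top)
    )
    ranked.index.name = "feature_id"
    return ranked.reset_index()


def dam_met_tfs(
    motif_scores: pd.DataFrame,
    regulon_auc: pd.DataFrame,
    expression: pd.DataFrame,
    sample_of_cell: pd.Series,
    primary_cells,
    met_cells,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Metastasis-associated TFs from concordant motif and regulon shifts.

    All three inputs are TF x cell frames sharing a TF namespace (TFs
    missing from any frame are excluded).  A TF is retained when the
    met-vs-primary Wilcoxon test is BH-significant for both motif score
    and regulon activity with the same sign; its expression score is
    |log2FC of expression on per-sample averages|, kept only when its
    direction matches the motif-score shift (else 0).
    """
    tfs = sorted(set(motif_scores.index) & set(regulon_auc.index) & set(expression.index))
    pri = list(primary_cells)
    met = list(met_cells)
    rows = []
    for tf in tfs:
        m_met = motif_scores.loc[tf, met].to_numpy(float)
        m_pri = motif_scores.loc[tf, pri].to_numpy(float)
        a_met = regulon_auc.loc[tf, met].to_numpy(float)
        a_pri = regulon_auc.loc[tf, pri].to_numpy(float)
        p_m = stats.mannwhitneyu(m_met, m_pri, alternative="two-sided", method="asymptotic").pvalue
        p_a = stats.mannwhitneyu(a_met, a_pri, alternative="two-sided", method="asymptotic").pvalue
        rows.append((tf, m_met.mean() - m_pri.mean(), p_m, a_met.mean() - a_pri.mean(), p_a))
    res = pd.DataFrame(rows, columns=["tf", "dam_delta", "dam_p", "regulon_delta", "regulon_p"])
    if not len(res):
        return res.assign(dam_fdr=[], regulon_fdr=[], expression_score=[])
    res["dam_fdr"] = _adjust(res["dam_p"].to_numpy(), "bh")
    res["regulon_fdr"] = _adjust(res["regulon_p"].to_numpy(), "bh")
    keep = (
        (res["dam_fdr"] < fdr)
        & (res["regulon_fdr"] < fdr)
        & (np.sign(res["dam_delta"]) == np.sign(res["regulon_delta"]))
        & (res["dam_delta"] != 0)
    )
    res = res[keep].reset_index(drop=True)

    # expression score on per-sample averages
    sample_of_cell = pd.Series(sample_of_cell)
    met_samples = sample_of_cell.loc[met].unique()
    pri_samples = sample_of_cell.loc[pri].unique()
    scores = []
    for _, row in res.iterrows():
        expr = expression.loc[row["tf"]]
        per_sample = expr.groupby(sample_of_cell).mean()
        lfc = log2_fold_change(
            per_sample.reindex(met_samples).mean(), per_sample.reindex(pri_samples).mean()
        )
        scores.append(abs(float(lfc)) if np.sign(lfc) == np.sign(row["dam_delta"]) else 0.0)
    res["expression_score"] = scores
    return res
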
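"""Regulon consolidation, AUCell scoring against a hand-integrated
oracle, specificity rules and the sampling enrichment test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epidriver.regulons import (
    annotate_cancer_specific,
    auc_score,
    prioritize_specific_regulons,
    score_regulons,
    stability_filter,
    target_pathway_scores,
    tf_link_enrichment,
)


def auc_oracle(ranked_genes, targets, T):
    """Direct integration of the recovery curve for one cell."""
    hits = [g in targets for g in ranked_genes[:T]]
    H = np.cumsum(hits)
    n_t = len(targets)
    h_max = sum(min(k, n_t) for k in range(1, T + 1))
    return H.sum() / h_max


class TestStabilityFilter:
    def _runs(self, count, n_runs=10, n_targets=25):
        targets = {f"g{i}" for i in range(n_targets)}
        runs = []
        for r in range(n_runs):
            run_targets = set(targets) if r < count else set()
            runs.append({"tf1": run_targets | {f"stable{i}" for i in range(20)}})
        return runs

    def test_pair_in_8_of_10_kept(self):
        out = stability_filter(self._runs(8))
        assert set(out.loc[out["occurrence"] == 8, "target"]) == {f"g{i}" for i in range(25)}

    def test_pair_in_7_of_10_dropped(self):
        out = stability_filter(self._runs(7))
        assert not out["target"].str.startswith("g").any()

    def test_small_regulon_removed(self):
        runs = [{"tf1": {f"g{i}" for i in range(19)}} for _ in range(10)]
        assert len(stability_filter(runs)) == 0

    def test_exactly_20_targets_kept(self):
        runs = [{"tf1": {f"g{i}" for i in range(20)}} for _ in range(10)]
        assert stability_filter(runs)["tf"].nunique() == 1


class TestAucScore:
    def test_worked_example_eight_ninths(self):
        # 10 genes, T=5, targets at ranks 1 and 3
        expr = np.array([[10, 1, 8, 2, 3, 4, 0.5, 0.2, 0.1, 0.05]]).T
        genes = [f"g{i}" for i in range(10)]
        # descending ranks: g0 (rank 1), g2 (rank 2), g5 (rank 3), ...
        score = auc_score(expr, genes, {"g0", "g5"}, top_frac=0.5)
        assert score[0] == pytest.approx(8 / 9)

    def test_front_loaded_targets_score_one(self):
        expr = np.arange(10, 0, -1, dtype=float)[:, None]
        score = auc_score(expr, [f"g{i}" for i in range(10)], {"g0", "g1", "g2"}, top_frac=0.5)
        assert score[0] == pytest.approx(1.0)

    def test_no_target_in_top_scores_zero(self):
        expr = np.arange(10, 0, -1, dtype=float)[:, None]
        score = auc_score(expr, [f"g{i}" for i in range(10)], {"g8", "g9"}, top_frac=0.3)
        assert score[0] == 0.0

    def test_matches_oracle_on_enumerated_rankings(self, rng):
        genes = [f"g{i}" for i in range(12)]
        for rep in range(20):
            expr = rng.permutation(12).astype(float)[:, None]
            targets = set(rng.choice(genes, rng.integers(1, 5), replace=False))
            ranked = [genes[i] for i in np.argsort(-expr[:, 0], kind="stable")]
            T = int(np.ceil(0.4 * 12))
            assert auc_score(expr, genes, targets, top_frac=0.4)[0] == pytest.approx(
                auc_oracle(ranked, targets, T)
            )

    def test_monotone_transform_invariance(self, rng):
        expr = rng.uniform(1, 5, size=(30, 8))
        genes = [f"g{i}" for i in range(30)]
        targets = {"g3", "g11", "g20"}
        s1 = auc_score(expr, genes, targets)
        s2 = auc_score(np.log(expr) * 7 + 2, genes, targets)
        assert np.allclose(s1, s2)

    def test_empty_intersection_rejected(self, rng):
        with pytest.raises(ValueError):
            auc_score(rng.uniform(size=(5, 2)), ["a", "b", "c", "d", "e"], {"zz"})


class TestPrioritization:
    def _auc(self, rng, planted=True):
        cells = [f"c{i}" for i in range(90)]
        groups = ["A"] * 30 + ["B"] * 30 + ["C"] * 30
        mat = 0.1 + 0.02 * rng.random((5, 90))
        if planted:
            mat[0, :30] += 0.2  # regulon 0 specific to group A
        return pd.DataFrame(mat, index=[f"tf{i}" for i in range(5)], columns=cells), groups

    def test_constant_regulon_not_selected(self, rng):
        auc, groups = self._auc(rng, planted=False)
        auc.iloc[1] = 0.3
        out = prioritize_specific_regulons(auc, groups)
        assert all("tf1" not in t["tf"].tolist() for t in out.values())

    def test_planted_specific_regulon_recovered(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            auc, groups = self._auc(rng)
            out = prioritize_specific_regulons(auc, groups)
            assert out["A"]["tf"].tolist() == ["tf0"]
            assert len(out["B"]) == 0 and len(out["C"]) == 0

    def test_rule_application(self, rng):
        # focal mean 0.3 vs others 0.1 (ratio 3), median of means below focal
        cells = [f"c{i}" for i in range(60)]
        groups = ["A"] * 30 + ["B"] * 30
        mat = np.concatenate([0.3 + 0.01 * rng.random(30), 0.1 + 0.01 * rng.random(30)])[None, :]
        out = prioritize_specific_regulons(pd.DataFrame(mat, index=["tf0"], columns=cells), groups)
        assert out["A"]["tf"].tolist() == ["tf0"]


class TestCancerSpecific:
    def _run(self, rng, diff, log2fc_target=None, noise=0.001):
        cells = [f"c{i}" for i in range(80)]
        tum, cnc = cells[:40], cells[40:]
        base = 0.1
        mat = np.concatenate(
            [base + diff + noise * rng.random(40), base + noise * rng.random(40)]
        )[None, :]
        auc = pd.DataFrame(mat, index=["tf0"], columns=cells)
        return annotate_cancer_specific(auc, tum, cnc)

    def test_three_gates_pass(self, rng):
        out = self._run(rng, diff=0.02)
        assert out.iloc[0]["label"] == "cancer-cell-specific"

    def test_small_difference_fails(self, rng):
        out = self._run(rng, diff=0.005)
        assert out.iloc[0]["label"] == "tissue-specific"

    def test_equal_means_not_specific(self, rng):
        out = self._run(rng, diff=0.0)
        assert out.iloc[0]["label"] == "tissue-specific"


class TestEnrichment:
    def test_degenerate_whole_pool_linked(self):
        pool = [f"g{i}" for i in range(50)]
        res = tf_link_enrichment("tf", pool[:10], set(pool), pool, n_samplings=100, seed=0)
        assert res.sigma == 0 and res.p_one_sided == 0.5

    def test_z_matches_exact_hypergeometric_moments(self):
        # pool 100, 20 linked, N=5 targets, M=4 observed
        pool = [f"g{i}" for i in range(100)]
        linked = set(pool[:20])
        targets = set(pool[:4]) | {pool[50]}
        res = tf_link_enrichment("tf", targets, linked, pool, n_samplings=500, seed=1)
        assert res.M == 4
        hg = stats.hypergeom(100, 20, 5)
        z_exact = (4 - hg.mean()) / hg.std()
        assert res.z == pytest.approx(z_exact, rel=0.05)

    def test_null_p_approximately_uniform(self):
        pool = [f"g{i}" for i in range(400)]
        rng = np.random.default_rng(5)
        linked = set(rng.choice(np.array(pool, dtype=object), 120, replace=False))
        ps = []
        for rep in range(200):
            targ = set(
                np.random.default_rng(900 + rep).choice(np.array(pool, dtype=object), 40, replace=False)
            )
            ps.append(tf_link_enrichment("tf", targ, linked, pool, n_samplings=300, seed=rep).p_one_sided)
        frac = np.mean(np.array(ps) < 0.05)
        assert abs(frac - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / 200) + 0.01

    def test_seed_reproducibility(self):
        pool = [f"g{i}" for i in range(100)]
        linked = set(pool[:30])
        targets = set(pool[20:40])
        a = tf_link_enrichment("tf", targets, linked, pool, seed=3)
        b = tf_link_enrichment("tf", targets, linked, pool, seed=3)
        assert (a.mu, a.sigma, a.z) == (b.mu, b.sigma, b.z)

    def test_pool_must_contain_targets(self):
        with pytest.raises(ValueError):
            tf_link_enrichment("tf", {"x"}, set(), [f"g{i}" for i in range(10)])


class TestPathwayScores:
    def test_identical_sets_jaccard_one(self):
        genes = {f"g{i}" for i in range(10)}
        out = target_pathway_scores({"s": genes}, {"pw": genes}, genes)
        assert out.iloc[0]["jaccard"] == 1.0

    def test_disjoint_sets(self):
        uni = {f"g{i}" for i in range(40)}
        out = target_pathway_scores(
            {"s": {f"g{i}" for i in range(10)}}, {"pw": {f"g{i}" for i in range(20, 30)}}, uni
        )
        assert out.iloc[0]["jaccard"] == 0.0
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_hypergeometric_closed_form(self):
        # universe 100, pathway 10, selected 10, overlap 5
        uni = [f"g{i}" for i in range(100)]
        pw = set(uni[:10])
        sel = set(uni[:5]) | set(uni[50:55])
        out = target_pathway_scores({"s": sel}, {"pw": pw}, uni)
        from math import comb

        p_exact = sum(comb(10, k) * comb(90, 10 - k) for k in range(5, 11)) / comb(100, 10)
        assert out.iloc[0]["p"] == pytest.approx(p_exact, rel=1e-10)

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError):
            target_pathway_scores({"s": set()}, {"pw": {"g1"}}, {"g1", "g2"})


def test_score_regulons_separates_planted_groups(small_sim):
    """AUC activity of a planted regulon is highest in its focal group."""
    _, data, gt = small_sim
    regs = pd.DataFrame(
        [(tf, t, 10) for tf, targets in gt.true_regulons.items() for t in targets],
        columns=["tf", "target", "occurrence"],
    )
    auc = score_regulons(data.rna, data.gene_names, regs)
    groups = data.cells["cell_type"].to_numpy()
    for tf, focal in data.regulon_groups.items():
        means = pd.Series(auc.loc[tf].to_numpy(), index=groups).groupby(level=0).mean()
        assert means.idxmax() == focal
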
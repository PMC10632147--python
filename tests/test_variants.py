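"""Allele counting, DNP merging, somatic filters and segment-to-gene CNV
calls."""

import numpy as np
import pandas as pd
import pytest

from epidriver.simulate import SimConfig, dnp_variant_table, simulate_reads
from epidriver.variants import (
    filter_somatic,
    gene_cnv_call,
    merge_dnp,
    per_cell_allele_counts,
)


def _reads(rows):
    return pd.DataFrame(rows, columns=["barcode", "chrom", "pos", "allele", "read_id"])


class TestAlleleCounts:
    VARIANTS = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "ref": ["G"], "alt": ["A"]})

    def test_normalized_rate(self):
        reads = _reads([(f"bc{i}", "chr1", 100, "A", f"r{i}") for i in range(10)])
        groups = {f"bc{i}": "cancer" for i in range(100)}
        out = per_cell_allele_counts(reads, self.VARIANTS, groups)
        assert out.iloc[0]["alt_reads"] == 10
        assert out.iloc[0]["alt_rate"] == pytest.approx(0.1)

    def test_unmapped_barcode_ignored(self):
        reads = _reads([("bcX", "chr1", 100, "A", "r0"), ("bc0", "chr1", 100, "A", "r1")])
        out = per_cell_allele_counts(reads, self.VARIANTS, {"bc0": "cancer"})
        assert out.iloc[0]["alt_reads"] == 1
        assert out.attrs["unmapped_reads"] == 1

    def test_no_covering_reads_zero_counts(self):
        out = per_cell_allele_counts(_reads([]), self.VARIANTS, {"bc0": "cancer"})
        assert out.iloc[0]["alt_reads"] == 0 and out.iloc[0]["ref_reads"] == 0

    def test_matches_groupby_oracle(self, rng):
        barcodes = [f"bc{i}" for i in range(20)]
        groups = {b: ("cancer" if i < 12 else "normal") for i, b in enumerate(barcodes)}
        rows = [
            (str(rng.choice(barcodes)), "chr1", 100, str(rng.choice(["G", "A", "T"])), f"r{i}")
            for i in range(200)
        ]
        reads = _reads(rows)
        out = per_cell_allele_counts(reads, self.VARIANTS, groups).set_index("group")
        df = reads.assign(group=reads["barcode"].map(groups))
        for g, sub in df.groupby("group"):
            assert out.loc[g, "ref_reads"] == (sub["allele"] == "G").sum()
            assert out.loc[g, "alt_reads"] == (sub["allele"] == "A").sum()
            # conservation: ref + alt + other = all covering reads
            assert (
                out.loc[g, "ref_reads"] + out.loc[g, "alt_reads"] + out.loc[g, "other_reads"]
                == len(sub)
            )


class TestMergeDnp:
    VARIANTS = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "pos": [100, 101], "ref": ["G", "C"], "alt": ["A", "T"]}
    )

    def _spanning(self, n_both, n_single):
        rows = []
        for i in range(n_both + n_single):
            a1, a2 = ("A", "T") if i < n_both else ("A", "C")
            rows.append((f"bc", "chr1", 100, a1, f"r{i}"))
            rows.append((f"bc", "chrom1_wrong" if False else "chr1", 101, a2, f"r{i}"))
        return _reads(rows)

    def test_rate_at_threshold_merges(self):
        out = merge_dnp(self.VARIANTS, self._spanning(8, 2))
        assert (out["variant_type"] == "DNP").sum() == 1
        assert out.loc[out["variant_type"] == "DNP", "co_rate"].iloc[0] == pytest.approx(0.8)

    def test_rate_below_threshold_keeps_snvs(self):
        out = merge_dnp(self.VARIANTS, self._spanning(7, 3))
        assert (out["variant_type"] == "DNP").sum() == 0
        assert len(out) == 2

    def test_no_spanning_reads_flagged(self):
        reads = _reads([("bc", "chr1", 100, "A", "r0")])  # covers one site only
        out = merge_dnp(self.VARIANTS, reads)
        assert (out["variant_type"] == "SNV").all()
        assert out["no_read_support"].all()

    def test_distant_variants_not_candidates(self):
        variants = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [100, 200], "ref": ["G", "C"], "alt": ["A", "T"]}
        )
        out = merge_dnp(variants, self._spanning(10, 0))
        assert (out["variant_type"] == "SNV").all()

    @pytest.mark.parametrize("co_rate,expect_merge", [(0.9, True), (0.5, False)])
    def test_simulated_rates(self, co_rate, expect_merge):
        for seed in range(3):
            cfg = SimConfig(seed=seed, dnp_co_rates=(co_rate,), dnp_n_spanning=500)
            out = merge_dnp(dnp_variant_table(cfg), simulate_reads(cfg))
            assert bool((out["variant_type"] == "DNP").any()) is expect_merge

    def test_empirical_rate_converges(self):
        cfg = SimConfig(seed=0, dnp_co_rates=(0.7,), dnp_n_spanning=10_000)
        out = merge_dnp(dnp_variant_table(cfg), simulate_reads(cfg))
        assert out["co_rate"].iloc[0] == pytest.approx(0.7, abs=0.02)


class TestFilterSomatic:
    def _variant(self, **kw):
        base = dict(
            chrom="chr1", pos=1000, gene="GENE1", sample="s1", variant_type="SNV",
            tumour_depth=30, normal_depth=20, tumour_vaf=0.2, normal_vaf=0.0,
        )
        base.update(kw)
        return base

    def test_passing_variant_kept(self):
        out = filter_somatic(pd.DataFrame([self._variant()]))
        assert len(out) == 1 and not out.iloc[0]["rescued"]

    @pytest.mark.parametrize(
        "kw",
        [
            dict(tumour_depth=13),
            dict(normal_depth=7),
            dict(tumour_vaf=0.04),
            dict(normal_vaf=0.03),
        ],
    )
    def test_gate_failures(self, kw):
        out = filter_somatic(pd.DataFrame([self._variant(**kw)]))
        assert len(out) == 0

    def test_driver_rescue_interval(self):
        v = self._variant(tumour_vaf=0.04)
        out = filter_somatic(pd.DataFrame([v]), driver_genes={"GENE1"})
        assert len(out) == 1 and out.iloc[0]["rescued"]
        # below the rescue floor stays out
        v2 = self._variant(tumour_vaf=0.014)
        assert len(filter_somatic(pd.DataFrame([v2]), driver_genes={"GENE1"})) == 0

    def test_snv_near_same_sample_indel_removed(self):
        snv = self._variant(pos=1000)
        indel = self._variant(pos=1008, variant_type="indel")
        out = filter_somatic(pd.DataFrame([snv, indel]))
        assert 1000 not in set(out.loc[out["variant_type"] == "SNV", "pos"])
        # a different sample's indel does not trigger the rule
        indel_other = self._variant(pos=1008, variant_type="indel", sample="s2")
        out2 = filter_somatic(pd.DataFrame([snv, indel_other]))
        assert 1000 in set(out2["pos"])


class TestGeneCnv:
    def test_weighted_ratio_arithmetic(self):
        segments = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 600], "end": [600, 1200], "copy_ratio": [1.5, 1.0]}
        )
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "start": [0], "end": [1000]})
        out = gene_cnv_call(segments, genes)
        assert out.iloc[0]["weighted_ratio"] == pytest.approx(1.3)
        assert out.iloc[0]["call"] == "amplified"

    @pytest.mark.parametrize(
        "ratio,call",
        [(1.1, "neutral"), (0.9, "neutral"), (1.1000001, "amplified"), (0.89, "deleted"), (1.0, "neutral")],
    )
    def test_bound_strictness(self, ratio, call):
        segments = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "copy_ratio": [ratio]}
        )
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "start": [100], "end": [900]})
        assert gene_cnv_call(segments, genes).iloc[0]["call"] == call

    def test_no_overlap_unknown(self):
        segments = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100], "copy_ratio": [1.0]})
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "start": [0], "end": [100]})
        assert gene_cnv_call(segments, genes).iloc[0]["call"] == "unknown"

    def test_ratio_within_segment_range(self, rng):
        bounds = np.sort(rng.choice(np.arange(100, 10_000, 100), 8, replace=False))
        bounds = np.concatenate([[0], bounds, [12_000]])
        segments = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": bounds[:-1],
                "end": bounds[1:],
                "copy_ratio": rng.uniform(0.5, 2.0, len(bounds) - 1),
            }
        )
        genes = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(5)], "chrom": "chr1",
             "start": rng.integers(0, 10_000, 5)}
        )
        genes["end"] = genes["start"] + 1500
        out = gene_cnv_call(segments, genes)
        for _, row in out.iterrows():
            g = genes[genes["gene"] == row["gene"]].iloc[0]
            seg = segments[(segments["end"] > g["start"]) & (segments["start"] < g["end"])]
            assert seg["copy_ratio"].min() - 1e-12 <= row["weighted_ratio"] <= seg["copy_ratio"].max() + 1e-12
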
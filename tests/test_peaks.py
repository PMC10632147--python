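"""Peak catalog operations: resizing/SPM, greedy overlap removal against a
brute-force oracle, catalog composition, annotation and QC gates."""

import numpy as np
import pandas as pd
import pytest

from epidriver.peaks import (
    annotate_peaks,
    build_unified_catalog,
    iterative_overlap_removal,
    overlap_elements,
    qc_filter_cells,
    recenter_and_score,
)


def _peak_frame(rows, sample="S1"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "score"])
    df["name"] = [f"p{i}" for i in range(len(df))]
    df["sample_id"] = sample
    df["cohort"] = "C1"
    return df


def brute_force_greedy(peaks: pd.DataFrame, score_col: str) -> set:
    """Re-scan the full remaining set each round (the literal procedure)."""
    remaining = peaks.copy()
    kept = set()
    while len(remaining):
        ordered = remaining.sort_values(
            [score_col, "chrom", "start"], ascending=[False, True, True], kind="stable"
        )
        best = ordered.iloc[0]
        kept.add(best["name"])
        overlap = (
            (remaining["chrom"] == best["chrom"])
            & (remaining["start"] < best["end"])
            & (remaining["end"] > best["start"])
        )
        remaining = remaining[~overlap & (remaining["name"] != best["name"])]
    return kept


class TestRecenter:
    def test_window_around_summit(self):
        df = _peak_frame([("chr1", 900, 1100, 1000, 5.0)])
        out = recenter_and_score(df)
        assert out.iloc[0]["start"] == 750 and out.iloc[0]["end"] == 1251
        assert out.iloc[0]["end"] - out.iloc[0]["start"] == 501

    def test_spm_values(self):
        df = _peak_frame(
            [("chr1", 0, 0, 1000, 2.0), ("chr1", 0, 0, 3000, 3.0), ("chr1", 0, 0, 5000, 5.0)]
        )
        out = recenter_and_score(df)
        assert np.allclose(out["spm"], [200000.0, 300000.0, 500000.0])

    def test_spm_sums_per_sample(self):
        a = _peak_frame([("chr1", 0, 0, 1000, 2.0), ("chr1", 0, 0, 3000, 7.0)], sample="A")
        b = _peak_frame([("chr2", 0, 0, 9000, 11.0)], sample="B")
        out = recenter_and_score(pd.concat([a, b], ignore_index=True))
        sums = out.groupby("sample_id")["spm"].sum()
        assert np.allclose(sums, 1e6)

    def test_contig_start_crossing_is_error(self):
        df = _peak_frame([("chr1", 0, 300, 100, 5.0)])
        with pytest.raises(ValueError, match="contig start"):
            recenter_and_score(df)


class TestOverlapRemoval:
    def test_scored_chain(self):
        df = _peak_frame(
            [
                ("chr1", 100, 601, 350, 10.0),
                ("chr1", 400, 901, 650, 8.0),
                ("chr1", 1000, 1501, 1250, 5.0),
            ]
        )
        out = iterative_overlap_removal(df)
        assert set(out["name"]) == {"p0", "p2"}

    def test_disjoint_input_unchanged(self):
        df = _peak_frame([("chr1", 0, 100, 50, 1.0), ("chr1", 200, 300, 250, 2.0)])
        out = iterative_overlap_removal(df)
        assert out.equals(df)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(50, 200))
            start = rng.integers(0, 5000, n)
            df = pd.DataFrame(
                {
                    "chrom": rng.choice(["chr1", "chr2"], n),
                    "start": start,
                    "end": start + rng.integers(50, 600, n),
                    "summit": start,
                    "score": rng.uniform(0, 100, n).round(3),
                    "name": [f"p{i}" for i in range(n)],
                }
            )
            assert set(iterative_overlap_removal(df)["name"]) == brute_force_greedy(df, "score")

    def test_output_pairwise_nonoverlapping(self, rng):
        start = rng.integers(0, 2000, 300)
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": start,
                "end": start + 501,
                "summit": start,
                "score": rng.uniform(0, 10, 300),
                "name": [f"p{i}" for i in range(300)],
            }
        )
        out = iterative_overlap_removal(df).sort_values("start")
        assert (out["start"].to_numpy()[1:] >= out["end"].to_numpy()[:-1]).all()


class TestUnifiedCatalog:
    def test_single_disjoint_sample_identity(self):
        df = recenter_and_score(
            _peak_frame([("chr1", 0, 0, 1000, 2.0), ("chr1", 0, 0, 3000, 3.0)])
        )
        out = build_unified_catalog([df], level="cohort")
        assert set(out["name"]) == set(df["name"])
        assert out["spm"].sum() == pytest.approx(1e6)

    def test_shared_peak_survives_once(self):
        a = recenter_and_score(_peak_frame([("chr1", 0, 0, 1000, 2.0)], sample="A"))
        b = recenter_and_score(_peak_frame([("chr1", 0, 0, 1000, 3.0)], sample="B"))
        out = build_unified_catalog([a, b], level="cohort")
        assert len(out) == 1

    def test_two_stage_composition_matches_oracle(self, rng):
        samples = []
        for s in range(5):
            start = rng.integers(0, 30000, 100)
            samples.append(
                recenter_and_score(
                    pd.DataFrame(
                        {
                            "chrom": "chr1",
                            "start": start,
                            "end": start + 501,
                            "summit": start + 250,
                            "score": rng.uniform(1, 50, 100),
                            "name": [f"s{s}_p{i}" for i in range(100)],
                            "sample_id": f"S{s}",
                            "cohort": "C1",
                        }
                    )
                )
            )
        got = build_unified_catalog(samples, level="cohort")
        # oracle: renormalize spm per sample, then brute-force greedy on spm
        combined = pd.concat(samples, ignore_index=True)
        sums = combined.groupby("sample_id")["spm"].transform("sum")
        combined["spm"] = combined["spm"] * 1e6 / sums
        assert set(got["name"]) == brute_force_greedy(combined, "spm")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_unified_catalog([], level="cohort")


class TestAnnotate:
    GENES = pd.DataFrame(
        {
            "gene": ["gA", "gB"],
            "chrom": ["chr1", "chr1"],
            "tss": [10_000, 50_000],
            "strand": ["+", "-"],
        }
    )

    def _catalog(self, mid):
        return pd.DataFrame(
            {"name": ["p0"], "chrom": ["chr1"], "start": [mid - 250], "end": [mid + 251]}
        )

    def test_upstream_500_is_promoter(self):
        out = annotate_peaks(self._catalog(9_500), self.GENES)
        assert out.iloc[0]["region_class"] == "promoter"
        assert out.iloc[0]["tss_distance"] == -500

    def test_downstream_500_is_distal(self):
        out = annotate_peaks(self._catalog(10_500), self.GENES)
        assert out.iloc[0]["region_class"] == "distal"

    def test_minus_strand_window_flips(self):
        # 500 bp right of a minus-strand TSS is upstream -> promoter
        out = annotate_peaks(self._catalog(50_500), self.GENES)
        assert out.iloc[0]["nearest_gene"] == "gB"
        assert out.iloc[0]["region_class"] == "promoter"

    def test_matches_brute_force_nearest(self, rng):
        genes = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(30)],
                "chrom": rng.choice(["chr1", "chr2"], 30),
                "tss": rng.integers(0, 1_000_000, 30),
                "strand": rng.choice(["+", "-"], 30),
            }
        )
        mids = rng.integers(0, 1_000_000, 100)
        catalog = pd.DataFrame(
            {
                "name": [f"p{i}" for i in range(100)],
                "chrom": rng.choice(["chr1", "chr2"], 100),
                "start": mids - 250,
                "end": mids + 251,
            }
        )
        out = annotate_peaks(catalog, genes)
        for _, row in out.iterrows():
            mid = (row["start"] + row["end"]) // 2
            sub = genes[genes["chrom"] == row["chrom"]]
            dists = (sub["tss"] - mid).abs()
            assert abs(row["tss_distance"]) == dists.min()

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            annotate_peaks(self._catalog(100), self.GENES.iloc[:0])


class TestQC:
    def _metrics(self, **kw):
        base = dict(
            fragments_in_peaks=5000,
            pct_reads_in_peaks=40.0,
            blacklist_fraction=0.01,
            nucleosome_signal=1.2,
            tss_enrichment=5.0,
        )
        base.update(kw)
        return pd.DataFrame([base])

    def test_passing_cell(self):
        assert qc_filter_cells(self._metrics()).iloc[0]

    @pytest.mark.parametrize(
        "kw",
        [
            dict(fragments_in_peaks=1000),
            dict(fragments_in_peaks=20000),
            dict(pct_reads_in_peaks=15.0),
            dict(blacklist_fraction=0.05),
            dict(nucleosome_signal=5.0),
            dict(tss_enrichment=2.0),
        ],
    )
    def test_boundaries_are_strict(self, kw):
        assert not qc_filter_cells(self._metrics(**kw)).iloc[0]

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            qc_filter_cells(self._metrics().drop(columns=["tss_enrichment"]))


class TestOverlapElements:
    CATALOG = pd.DataFrame(
        {"name": ["p0"], "chrom": ["chr1"], "start": [1000], "end": [1501]}
    )

    @pytest.mark.parametrize(
        "elem,expected",
        [
            ((900, 1600), True),  # full containment, overlap 501
            ((1102, 2000), False),  # overlap 399
            ((1101, 2000), True),  # overlap 400 exactly
        ],
    )
    def test_min_overlap_rule(self, elem, expected):
        elements = pd.DataFrame(
            {"chrom": ["chr1"], "start": [elem[0]], "end": [elem[1]], "name": ["e0"]}
        )
        out = overlap_elements(self.CATALOG, elements, min_overlap=400)
        assert (len(out) == 1) is expected
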
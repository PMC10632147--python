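"""Peak catalog construction, annotation and cell QC.

Builds per-sample, per-cohort and pan-cancer non-overlapping peak
catalogs: peaks are resized to a fixed width around their summit,
significance scores are renormalized to score-per-million (SPM) within
each contributing unit, and overlapping peaks are resolved by iterative
removal keeping the most significant peak.  Intervals are 0-based
half-open; "overlap" means at least one shared base.
"""

from __future__ import annotations

import bisect

import numpy as np
import pandas as pd

QC_BOUNDS = {
    "fragments_in_peaks": (1000, 20000),  # strict: 1000 < x < 20000
    "pct_reads_in_peaks": 15.0,  # > 15
    "blacklist_fraction": 0.05,  # < 0.05
    "nucleosome_signal": 5.0,  # < 5
    "tss_enrichment": 2.0,  # > 2
}
QC_METRICS = list(QC_BOUNDS)


def recenter_and_score(peaks: pd.DataFrame, total_width: int = 501) -> pd.DataFrame:
    """Resize peaks around their summit and fill score-per-million.

    Each peak becomes ``[summit - w//2, summit + w//2 + 1)`` (width exactly
    ``total_width`` for odd widths) and ``spm = score * 1e6 / sum(score)``
    within each ``sample_id``, so SPM sums to 1e6 per sample.  A resized
    peak crossing a contig start is an error: the caller must pad or drop
    it, nothing is clipped silently.
    """
    half = total_width // 2
    out = peaks.copy()
    out["start"] = out["summit"].astype(int) - half
    out["end"] = out["summit"].astype(int) + (total_width - half)
    if (out["start"] < 0).any():
        bad = out.loc[out["start"] < 0].iloc[0]
        raise ValueError(f"peak at {bad['chrom']}:{bad['summit']} crosses the contig start after resizing")
    sums = out.groupby("sample_id")["score"].transform("sum")
    if (sums <= 0).any():
        raise ValueError("per-sample score sums must be positive for SPM normalization")
    out["spm"] = out["score"] * 1e6 / sums
    return out


def iterative_overlap_removal(peaks: pd.DataFrame, score_col: str = "score") -> pd.DataFrame:
    """Greedy non-overlapping subset: keep the most significant peak,
    drop everything overlapping it by >= 1 bp, repeat.

    Equivalent to the brute-force re-scan because removing peaks never
    changes the relative order of the survivors; ties in score break by
    (chrom, start) so the result is platform-stable.
    """
    order = peaks.sort_values(
        [score_col, "chrom", "start"], ascending=[False, True, True], kind="stable"
    )
    kept_idx = []
    kept_by_chrom: dict = {}  # chrom -> (sorted starts, ends aligned)
    for idx, row in order.iterrows():
        starts, ends = kept_by_chrom.setdefault(row["chrom"], ([], []))
        i = bisect.bisect_right(starts, row["start"])
        # neighbour on the left may extend over us; on the right may start before our end
        if i > 0 and ends[i - 1] > row["start"]:
            continue
        if i < len(starts) and starts[i] < row["end"]:
            continue
        starts.insert(i, row["start"])
        ends.insert(i, row["end"])
        kept_idx.append(idx)
    return peaks.loc[peaks.index.isin(kept_idx)]


def build_unified_catalog(peaksets, level: str = "cohort") -> pd.DataFrame:
    """Merge per-sample (level="cohort") or per-cohort (level="pan-cancer")
    peak sets into one non-overlapping catalog.

    The score column entering the stage (``spm`` if present, else raw
    ``score``) is renormalized to SPM within each contributing unit, then
    iterative removal runs on SPM across the concatenated set.
    """
    if level not in ("cohort", "pan-cancer"):
        raise ValueError("level must be 'cohort' or 'pan-cancer'")
    frames = [p for p in peaksets if len(p)]
    if not frames:
        raise ValueError("no peaks supplied")
    combined = pd.concat(frames, ignore_index=True)
    unit = "sample_id" if level == "cohort" else "cohort"
    col = "spm" if "spm" in combined.columns else "score"
    sums = combined.groupby(unit)[col].transform("sum")
    combined["spm"] = combined[col] * 1e6 / sums
    return iterative_overlap_removal(combined, score_col="spm").reset_index(drop=True)


def annotate_peaks(catalog: pd.DataFrame, gene_annotation: pd.DataFrame) -> pd.DataFrame:
    """Nearest-TSS gene and region class per peak.

    Distance is signed in the transcription direction of the assigned
    gene (negative upstream); the promoter window is (-1000, +100) around
    the TSS, so a peak midpoint 500 bp downstream is already distal.
    """
    if len(gene_annotation) == 0:
        raise ValueError("empty gene annotation")
    ann = []
    by_chrom = {c: g.sort_values("tss").reset_index(drop=True) for c, g in gene_annotation.groupby("chrom")}
    for _, p in catalog.iterrows():
        mid = (int(p["start"]) + int(p["end"])) // 2
        genes = by_chrom.get(p["chrom"])
        if genes is None:
            ann.append((None, np.nan, "intergenic"))
            continue
        d = (genes["tss"] - mid).abs()
        best = int(d.idxmin())
        g = genes.iloc[best]
        rel = mid - g["tss"] if g["strand"] == "+" else g["tss"] - mid
        klass = "promoter" if -1000 <= rel <= 100 else "distal"
        ann.append((g["gene"], int(rel), klass))
    out = catalog.copy()
    out[["nearest_gene", "tss_distance", "region_class"]] = pd.DataFrame(ann, index=catalog.index)
    return out


def qc_filter_cells(metrics: pd.DataFrame) -> pd.Series:
    """Per-cell pass/fail against the fixed accessibility QC gates.

    Pass iff 1000 < fragments_in_peaks < 20000, pct_reads_in_peaks > 15,
    blacklist_fraction < 0.05, nucleosome_signal < 5 and
    tss_enrichment > 2 -- every inequality strict.
    """
    missing = [m for m in QC_METRICS if m not in metrics.columns]
    if missing:
        raise ValueError(f"missing QC metrics: {missing}")
    if metrics[QC_METRICS].isna().any().any():
        raise ValueError("QC metrics contain missing values")
    lo, hi = QC_BOUNDS["fragments_in_peaks"]
    return (
        (metrics["fragments_in_peaks"] > lo)
        & (metrics["fragments_in_peaks"] < hi)
        & (metrics["pct_reads_in_peaks"] > QC_BOUNDS["pct_reads_in_peaks"])
        & (metrics["blacklist_fraction"] < QC_BOUNDS["blacklist_fraction"])
        & (metrics["nucleosome_signal"] < QC_BOUNDS["nucleosome_signal"])
        & (metrics["tss_enrichment"] > QC_BOUNDS["tss_enrichment"])
    )


def overlap_elements(
    catalog: pd.DataFrame, element_bed: pd.DataFrame, min_overlap: int = 400
) -> pd.DataFrame:
    """Label peaks with regulatory elements overlapping them by
    >= ``min_overlap`` bp (half-open arithmetic).

    Returns one row per (peak, element) pair meeting the rule, with the
    overlap length.
    """
    rows = []
    for chrom, elems in element_bed.groupby("chrom"):
        sub = catalog[catalog["chrom"] == chrom]
        if not len(sub):
            continue
        es = elems["start"].to_numpy()
        ee = elems["end"].to_numpy()
        for _, p in sub.iterrows():
            ov = np.minimum(ee, p["end"]) - np.maximum(es, p["start"])
            for j in np.flatnonzero(ov >= min_overlap):
                rows.append(
                    (p["name"], elems.iloc[j].get("name", f"{chrom}:{es[j]}-{ee[j]}"), int(ov[j]))
                )
    return pd.DataFrame(rows, columns=["peak", "element", "overlap_bp"])
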
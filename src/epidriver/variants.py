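"""Read-level allele utilities, DNP merging, somatic filters and CNV calls.

Read tables (barcode, chrom, pos, allele, read_id; 1-based positions)
replace BAM parsing so the logic carries no alignment dependency -- a
thin adapter can feed real alignments later.

``merge_dnp`` implements co-occurrence-based merging of adjacent SNVs
into double-nucleotide polymorphisms: candidate sets are variants whose
pairwise distance is at most 2 bp (transitive closure); with n_t reads
spanning all candidate positions and n_c carrying every alternate
allele, the set merges when r_c = n_c / n_t >= 0.8.

``gene_cnv_call`` maps copy-ratio segments to genes by a weighted ratio
over the overlap lengths and calls amplified / neutral / deleted against
the (0.9, 1.1) bounds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VALID_ALLELES = set("ACGTN")


def per_cell_allele_counts(
    reads: pd.DataFrame,
    variants: pd.DataFrame,
    barcode_groups: dict,
) -> pd.DataFrame:
    """Ref/alt read counts per (group, variant), with group-normalized rates.

    ``barcode_groups`` maps barcode -> group label (e.g. cancer vs
    normal).  The normalized rate divides supporting reads by the number
    of cells in the group.  Reads with unmapped barcodes are ignored and
    counted in ``attrs['unmapped_reads']``; a variant with no covering
    reads yields zero counts.
    """
    groups = pd.Series(barcode_groups)
    n_cells = groups.value_counts()
    mapped = reads["barcode"].isin(groups.index)
    unmapped = int((~mapped).sum())
    rr = reads[mapped].copy()
    rr["group"] = rr["barcode"].map(groups)
    rows = []
    for _, v in variants.iterrows():
        at_site = rr[(rr["chrom"] == v["chrom"]) & (rr["pos"] == v["pos"])]
        for g in n_cells.index:
            sub = at_site[at_site["group"] == g]
            ref_n = int((sub["allele"] == v["ref"]).sum())
            alt_n = int((sub["allele"] == v["alt"]).sum())
            other_n = len(sub) - ref_n - alt_n
            rows.append(
                (
                    g,
                    v["chrom"],
                    int(v["pos"]),
                    v["ref"],
                    v["alt"],
                    ref_n,
                    alt_n,
                    other_n,
                    ref_n / n_cells[g],
                    alt_n / n_cells[g],
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "group",
            "chrom",
            "pos",
            "ref",
            "alt",
            "ref_reads",
            "alt_reads",
            "other_reads",
            "ref_rate",
            "alt_rate",
        ],
    )
    out.attrs["unmapped_reads"] = unmapped
    return out


def _candidate_sets(variants: pd.DataFrame, window: int) -> list:
    """Transitive closure of variants within ``window`` bp on a chromosome."""
    sets = []
    for chrom, sub in variants.sort_values(["chrom", "pos"]).groupby("chrom"):
        current = []
        last = None
        for _, v in sub.iterrows():
            if last is not None and v["pos"] - last <= window:
                current.append(v)
            else:
                if len(current) > 1:
                    sets.append(current)
                current = [v]
            last = v["pos"]
        if len(current) > 1:
            sets.append(current)
    return sets


def merge_dnp(
    variants: pd.DataFrame,
    reads: pd.DataFrame,
    window: int = 2,
    min_rate: float = 0.8,
) -> pd.DataFrame:
    """Merge co-occurring nearby SNVs into DNP calls.

    Returns the updated variant table: merged constituents are replaced
    by one row with ``variant_type='DNP'`` and the observed co-occurrence
    rate; candidate sets without spanning reads stay unmerged with
    ``no_read_support=True``.
    """
    out_rows = []
    merged_positions = set()
    for cand in _candidate_sets(variants, window):
        chrom = cand[0]["chrom"]
        positions = [int(v["pos"]) for v in cand]
        alts = {int(v["pos"]): v["alt"] for v in cand}
        site_reads = reads[(reads["chrom"] == chrom) & (reads["pos"].isin(positions))]
        if len(site_reads):
            wide = site_reads.pivot_table(
                index="read_id", columns="pos", values="allele", aggfunc="first"
            ).reindex(columns=positions)
            spanning = wide.dropna()
            n_t = len(spanning)
            n_c = int((spanning == pd.Series(alts)).all(axis=1).sum()) if n_t else 0
        else:
            n_t = n_c = 0
        r_c = n_c / n_t if n_t else np.nan
        if n_t > 0 and r_c >= min_rate:
            for p in positions:
                merged_positions.add((chrom, p))
            out_rows.append(
                {
                    "chrom": chrom,
                    "pos": positions[0],
                    "ref": "".join(v["ref"] for v in cand),
                    "alt": "".join(v["alt"] for v in cand),
                    "variant_type": "DNP" if len(cand) == 2 else "MNP",
                    "co_rate": r_c,
                    "n_spanning": n_t,
                    "no_read_support": False,
                }
            )
        else:
            for v in cand:
                merged_positions.add((chrom, int(v["pos"])))
                out_rows.append(
                    {
                        "chrom": chrom,
                        "pos": int(v["pos"]),
                        "ref": v["ref"],
                        "alt": v["alt"],
                        "variant_type": "SNV",
                        "co_rate": r_c,
                        "n_spanning": n_t,
                        "no_read_support": n_t == 0,
                    }
                )
    for _, v in variants.iterrows():
        if (v["chrom"], int(v["pos"])) not in merged_positions:
            out_rows.append(
                {
                    "chrom": v["chrom"],
                    "pos": int(v["pos"]),
                    "ref": v["ref"],
                    "alt": v["alt"],
                    "variant_type": "SNV",
                    "co_rate": np.nan,
                    "n_spanning": 0,
                    "no_read_support": False,
                }
            )
    return (
        pd.DataFrame(out_rows)
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )


def filter_somatic(
    variants: pd.DataFrame,
    driver_genes=(),
    min_tumour_depth: int = 14,
    min_normal_depth: int = 8,
    min_tumour_vaf: float = 0.05,
    max_normal_vaf: float = 0.02,
    indel_proximity: int = 10,
    rescue_vaf: tuple = (0.015, 0.05),
) -> pd.DataFrame:
    """Coverage / VAF somatic filters with driver-gene rescue.

    Keep variants with tumour depth >= 14, normal depth >= 8, tumour
    VAF >= 0.05 and normal VAF <= 0.02, excluding SNVs within 10 bp of a
    same-sample indel.  Variants in driver genes with tumour VAF in
    [0.015, 0.05) that pass every other gate are rescued.

    Expected columns: chrom, pos, gene, sample, variant_type (SNV/indel),
    tumour_depth, normal_depth, tumour_vaf, normal_vaf.
    """
    v = variants.copy()
    drivers = set(driver_genes)
    is_indel = v["variant_type"].str.lower().str.contains("ins|del|indel")
    near_indel = np.zeros(len(v), dtype=bool)
    for i, row in enumerate(v.itertuples(index=False)):
        if row.variant_type.lower() == "snv":
            same = v[
                is_indel.to_numpy()
                & (v["sample"] == row.sample)
                & (v["chrom"] == row.chrom)
                & ((v["pos"] - row.pos).abs() <= indel_proximity)
            ]
            near_indel[i] = len(same) > 0
    base = (
        (v["tumour_depth"] >= min_tumour_depth)
        & (v["normal_depth"] >= min_normal_depth)
        & (v["normal_vaf"] <= max_normal_vaf)
        & ~near_indel
    )
    main = base & (v["tumour_vaf"] >= min_tumour_vaf)
    rescued = (
        base
        & v["gene"].isin(drivers)
        & (v["tumour_vaf"] >= rescue_vaf[0])
        & (v["tumour_vaf"] < rescue_vaf[1])
    )
    out = v[main | rescued].copy()
    out["rescued"] = rescued[main | rescued]
    return out.reset_index(drop=True)


def gene_cnv_call(
    segments: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    bounds: tuple = (0.9, 1.1),
) -> pd.DataFrame:
    """Weighted copy-ratio per gene and amplified/neutral/deleted calls.

    The weighted ratio is sum(ratio_s * overlap_s) / sum(overlap_s) over
    the segments a gene overlaps; a gene is deleted when the ratio falls
    below ``bounds[0]``, amplified when strictly above ``bounds[1]``,
    otherwise neutral.  Genes overlapping no segment are called
    "unknown".
    """
    lower, upper = bounds
    rows = []
    for _, g in gene_intervals.iterrows():
        seg = segments[
            (segments["chrom"] == g["chrom"])
            & (segments["end"] > g["start"])
            & (segments["start"] < g["end"])
        ]
        if not len(seg):
            rows.append((g["gene"], np.nan, "unknown"))
            continue
        ov = np.minimum(seg["end"], g["end"]) - np.maximum(seg["start"], g["start"])
        ratio = float((seg["copy_ratio"] * ov).sum() / ov.sum())
        call = "deleted" if ratio < lower else ("amplified" if ratio > upper else "neutral")
        rows.append((g["gene"], ratio, call))
    return pd.DataFrame(rows, columns=["gene", "weighted_ratio", "call"])
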
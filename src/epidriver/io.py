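"""Readers and writers for the plain-text formats used across the pipeline.

Coordinate conventions: interval files (BED, segments) are 0-based
half-open; variant and read positions are 1-based (VCF-style).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

BED_COLUMNS = ["chrom", "start", "end", "name", "spm", "strand", "summit_offset", "score"]


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """Write a peak table as BED6+2 (summit offset and -log10 q appended)."""
    out = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"].astype(int),
            "end": peaks["end"].astype(int),
            "name": peaks["name"],
            "spm": peaks.get("spm", pd.Series(0.0, index=peaks.index)),
            "strand": ".",
            "summit_offset": (peaks["summit"] - peaks["start"]).astype(int),
            "score": peaks["score"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    df["summit"] = df["start"] + df["summit_offset"]
    return df.drop(columns=["summit_offset", "strand"])


def write_matrix_mtx(matrix: np.ndarray, features, barcodes, prefix: Path, name: str) -> None:
    """Write a feature x cell matrix as MatrixMarket plus row/column TSVs."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix / f"{name}.mtx"), sparse.coo_matrix(matrix))
    pd.Series(list(features)).to_csv(prefix / f"{name}_features.tsv", index=False, header=False)
    pd.Series(list(barcodes)).to_csv(prefix / "barcodes.tsv", index=False, header=False)


def read_matrix_mtx(prefix: Path, name: str):
    prefix = Path(prefix)
    mat = np.asarray(spio.mmread(str(prefix / f"{name}.mtx")).todense())
    features = pd.read_csv(prefix / f"{name}_features.tsv", header=None)[0].tolist()
    barcodes = pd.read_csv(prefix / "barcodes.tsv", header=None)[0].tolist()
    return mat, features, barcodes


def write_gmt(gene_sets: dict, path) -> None:
    with open(path, "w") as fh:
        for set_name, genes in gene_sets.items():
            fh.write("\t".join([set_name, "synthetic"] + sorted(genes)) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
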
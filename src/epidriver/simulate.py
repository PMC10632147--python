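"""Synthetic multiome generator with planted ground truth.

The study this toolkit supports analyses real tumour atlases; no generative
model of the data exists there, so every distributional choice here is the
package's own.  The generator emulates the *inputs* each pipeline stage
consumes -- a scored peak catalog, peak x cell and gene x cell count
matrices over shared cells, cell metadata, gene annotation, read-level
allele tables and CNV segment tables -- while planting recoverable
structure:

* cell-type-structured accessibility (marker peaks per normal type plus a
  shared tumour signature derived from one designated normal type, the
  "closest normal cell" ground truth);
* enhancer-to-gene links: a gene's negative-binomial mean is
  ``base + link_effect * accessibility`` of its planted peak, with the peak
  placed within 500 kb of the gene TSS and decoy peaks both inside and
  outside that window;
* TF regulons whose target genes are over-expressed in a focal cell group;
* a normal -> primary -> metastatic continuum: per-cell pseudotime in
  [0, 1] drives the accessibility of a block of "metastatic program" peaks;
* read tables with co-occurring SNV pairs at configured rates, and segment
  tables whose intervals tile each chromosome and overlap genes.

Counts are Bernoulli per (cell, peak) for accessibility and negative
binomial for expression -- realism at minimal complexity.  One global seed
fans out to per-operation child seeds so stages can be re-run
independently; a fixed seed gives bit-identical output.

Genome layout: genes are placed 3 Mb apart (100 per chromosome) with the
TSS at the centre of each territory, so offsets up to 500 kb stay closer
to the own TSS than to any neighbour.  Peak summits sit on a 1-kb grid,
which guarantees the 501-bp recentred peaks never overlap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from epidriver import io as eio

GENES_PER_CHROM = 100
TERRITORY = 3_000_000  # bp of genome owned by each gene
IN_RANGE_KB = (10, 450)  # planted/decoy offsets inside the 500-kb window, in kb
OUT_RANGE_KB = (600, 1400)  # decoy offsets outside the window
LINK_PEAK_ACCESS = 0.3  # accessibility probability of link peaks (iid across cells)
MARKER_FRACTION = 0.3  # fraction of non-link peaks used as cell-type markers
TRAJECTORY_FRACTION = 0.2  # fraction used for the metastatic program
TUMOUR_MARKER_RETENTION = 0.8  # CNC markers kept accessible in tumour cells
REGULON_EFFECT = 2.0  # multiplicative target boost in the focal group


@dataclass
class SimConfig:
    """Parameters of one synthetic multiome study.

    ``n_cell_types`` counts *normal* cell types; tumour cells (primary and
    metastatic conditions) are perturbed copies of normal type 0, the
    planted closest-normal-cell (CNC).  Total cells =
    ``(n_cell_types + 2) * cells_per_type``.
    """

    n_cell_types: int = 3
    cells_per_type: int = 200
    n_peaks: int = 2000
    n_genes: int = 500
    n_planted_links: int = 30
    link_effect: float = 2.0
    n_regulons: int = 4
    targets_per_regulon: int = 30
    trajectory_groups: tuple = ("normal", "primary", "metastatic")
    noise_dispersion: float = 10.0
    background_access_prob: float = 0.05
    foreground_access_prob: float = 0.5
    seed: int = 0
    # read-level / CNV simulation
    dnp_co_rates: tuple = (0.9, 0.5)
    dnp_n_spanning: int = 200

    def __post_init__(self):
        for name in (
            "n_cell_types",
            "cells_per_type",
            "n_peaks",
            "n_genes",
            "n_regulons",
            "targets_per_regulon",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_planted_links < 0:
            raise ValueError("n_planted_links must be >= 0")
        for name in ("background_access_prob", "foreground_access_prob"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.foreground_access_prob <= self.background_access_prob:
            raise ValueError("foreground_access_prob must exceed background_access_prob")
        if self.n_planted_links > self.n_genes:
            raise ValueError("cannot plant more links than genes")
        if self.n_planted_links > self.n_peaks:
            raise ValueError("cannot plant more links than peaks")
        if len(self.trajectory_groups) != 3:
            raise ValueError("trajectory_groups must name (normal, primary, metastatic)")
        for c in self.dnp_co_rates:
            if not 0.0 <= c <= 1.0:
                raise ValueError("co-occurrence rates must be in [0, 1]")

    def child_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator fanned out from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence((self.seed, _STAGE_KEYS[stage]))
        )


_STAGE_KEYS = {
    "layout": 0,
    "accessibility": 1,
    "expression": 2,
    "reads": 3,
    "segments": 4,
    "grn_runs": 5,
    "sample_peaks": 6,
}


@dataclass
class GroundTruth:
    """Planted structure recorded for downstream recovery tests."""

    true_links: list  # (peak_name, gene, effect)
    true_regulons: dict  # tf gene -> set of target genes
    true_pseudotime: dict  # cell_id -> float in [0, 1], trajectory cells only
    true_cnc: dict  # cohort -> normal cell type
    true_dnp_pairs: list  # (variant_a, variant_b, co_rate)


@dataclass
class MultiomeData:
    """Peak x cell and gene x cell matrices over a shared cell panel."""

    atac: np.ndarray  # n_peaks x n_cells binary accessibility
    rna: np.ndarray  # n_genes x n_cells counts
    peaks: pd.DataFrame  # name, chrom, start, end, summit, score, category, ...
    genes: pd.DataFrame  # gene, chrom, tss, strand
    cells: pd.DataFrame  # cell_id, cell_type, sample, cohort, condition

    @property
    def peak_names(self):
        return self.peaks["name"].tolist()

    @property
    def gene_names(self):
        return self.genes["gene"].tolist()

    @property
    def cell_ids(self):
        return self.cells["cell_id"].tolist()


def _gene_layout(config: SimConfig) -> pd.DataFrame:
    genes = []
    for i in range(config.n_genes):
        chrom = f"chr{i // GENES_PER_CHROM + 1}"
        within = i % GENES_PER_CHROM
        tss = within * TERRITORY + TERRITORY // 2
        strand = "+" if i % 2 == 0 else "-"
        genes.append((f"gene_{i:04d}", chrom, tss, strand))
    return pd.DataFrame(genes, columns=["gene", "chrom", "tss", "strand"])


def _place_peaks(config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Place peak summits on a 1-kb grid around gene TSSs.

    Planted-link peaks and a minority of decoys fall inside the 500-kb
    candidate window; the remaining decoys fall 0.6-1.4 Mb away, outside
    the window for their own gene and for every neighbour.
    """
    n_decoys = config.n_peaks - config.n_planted_links
    n_in = int(round(0.1 * n_decoys))
    n_out = n_decoys - n_in

    taken = set()  # (gene_index, offset_kb) grid points
    rows = []

    def draw_offset(kb_range, gene_idx):
        lo, hi = kb_range
        for _ in range(200):
            off = int(rng.integers(lo, hi + 1)) * (1 if rng.random() < 0.5 else -1)
            if (gene_idx, off) not in taken:
                taken.add((gene_idx, off))
                return off
        raise RuntimeError("could not place peak without overlap after recentering")

    specs = [(g, "link") for g in range(config.n_planted_links)]
    specs += [(i % config.n_genes, "in") for i in range(n_in)]
    specs += [(i % config.n_genes, "out") for i in range(n_out)]

    for gene_idx, kind in specs:
        kb_range = OUT_RANGE_KB if kind == "out" else IN_RANGE_KB
        off = draw_offset(kb_range, gene_idx)
        g = genes.iloc[gene_idx]
        summit = g["tss"] + off * 1000
        rows.append(
            {
                "chrom": g["chrom"],
                "summit": summit,
                "start": summit - 250,
                "end": summit + 251,
                "score": float(rng.uniform(2.0, 100.0)),
                "category": "link" if kind == "link" else "decoy",
                "linked_gene": g["gene"] if kind == "link" else "",
            }
        )
    peaks = pd.DataFrame(rows)
    peaks = peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    peaks["name"] = [f"peak_{i:05d}" for i in range(len(peaks))]
    return peaks


def _assign_decoy_roles(config: SimConfig, peaks: pd.DataFrame, rng: np.random.Generator):
    """Split decoy peaks into per-type markers, tumour signature, trajectory
    program and flat background."""
    decoy_idx = peaks.index[peaks["category"] == "decoy"].to_numpy()
    decoy_idx = rng.permutation(decoy_idx)
    n_sig = config.n_cell_types + 1  # normal types + shared tumour signature
    n_marker = int(MARKER_FRACTION * len(decoy_idx))
    n_traj = int(TRAJECTORY_FRACTION * len(decoy_idx))
    per_sig = max(1, n_marker // n_sig)

    roles = pd.Series("background", index=peaks.index)
    owner = pd.Series("", index=peaks.index)
    pos = 0
    for t in range(config.n_cell_types):
        idx = decoy_idx[pos : pos + per_sig]
        roles.loc[idx] = "marker"
        owner.loc[idx] = f"normal_type_{t}"
        pos += per_sig
    idx = decoy_idx[pos : pos + per_sig]
    roles.loc[idx] = "marker"
    owner.loc[idx] = "tumour"
    pos += per_sig
    idx = decoy_idx[pos : pos + n_traj]
    roles.loc[idx] = "trajectory"
    pos += n_traj
    peaks = peaks.copy()
    peaks.loc[peaks["category"] == "link", "category"] = "link"
    peaks["category"] = np.where(roles != "background", roles, peaks["category"])
    peaks.loc[peaks["category"] == "decoy", "category"] = "background"
    peaks["marker_of"] = owner
    return peaks


def _cell_panel(config: SimConfig) -> pd.DataFrame:
    rows = []
    i = 0
    normal_label, primary_label, met_label = config.trajectory_groups
    for t in range(config.n_cell_types):
        for _ in range(config.cells_per_type):
            rows.append((f"cell_{i:05d}", f"normal_type_{t}", f"N{t + 1}", "SYN", normal_label))
            i += 1
    for cond, prefix in ((primary_label, "P"), (met_label, "M")):
        for j in range(config.cells_per_type):
            sample = f"{prefix}{1 + (j % 2)}"
            rows.append((f"cell_{i:05d}", cond, sample, "SYN", cond))
            i += 1
    return pd.DataFrame(rows, columns=["cell_id", "cell_type", "sample", "cohort", "condition"])


def simulate_multiome(config: SimConfig):
    """Generate a multiome dataset plus its ground truth.

    Returns
    -------
    (MultiomeData, GroundTruth)
    """
    rng_layout = config.child_rng("layout")
    genes = _gene_layout(config)
    peaks = _place_peaks(config, genes, rng_layout)
    peaks = _assign_decoy_roles(config, peaks, rng_layout)
    cells = _cell_panel(config)

    normal_label, primary_label, met_label = config.trajectory_groups
    n_peaks, n_cells = len(peaks), len(cells)
    bg, fg = config.background_access_prob, config.foreground_access_prob

    cond = cells["condition"].to_numpy()
    ctype = cells["cell_type"].to_numpy()
    is_tumour = (cond == primary_label) | (cond == met_label)
    cnc_type = "normal_type_0"

    # planted pseudotime on the trajectory cells (CNC normals + tumour)
    on_traj = is_tumour | (ctype == cnc_type)
    pt = np.zeros(n_cells)
    rng_acc = config.child_rng("accessibility")
    seg = {normal_label: (0.0, 1 / 3), primary_label: (1 / 3, 2 / 3), met_label: (2 / 3, 1.0)}
    for label, (lo, hi) in seg.items():
        mask = on_traj & (cond == label)
        pt[mask] = rng_acc.uniform(lo, hi, mask.sum())

    prob = np.full((n_peaks, n_cells), bg)
    category = peaks["category"].to_numpy()
    marker_of = peaks["marker_of"].to_numpy()

    for t in range(config.n_cell_types):
        sel = (category == "marker") & (marker_of == f"normal_type_{t}")
        prob[np.ix_(sel, ctype == f"normal_type_{t}")] = fg
        if t == 0:  # tumour cells inherit a perturbed copy of the CNC program
            keep = rng_acc.random(sel.sum()) < TUMOUR_MARKER_RETENTION
            rows = np.flatnonzero(sel)[keep]
            prob[np.ix_(rows, is_tumour)] = fg
    sel = (category == "marker") & (marker_of == "tumour")
    prob[np.ix_(sel, is_tumour)] = fg

    traj_rows = np.flatnonzero(category == "trajectory")
    prob[np.ix_(traj_rows, on_traj)] = bg + (fg - bg) * pt[on_traj][None, :]

    link_rows = np.flatnonzero(category == "link")
    prob[link_rows, :] = LINK_PEAK_ACCESS

    atac = rng_acc.binomial(1, prob).astype(np.uint8)

    # expression: NB around a per-gene base mean plus planted effects
    rng_expr = config.child_rng("expression")
    base = rng_expr.uniform(0.5, 2.0, config.n_genes)
    mean = np.tile(base[:, None], (1, n_cells)).astype(float)

    gene_index = {g: i for i, g in enumerate(genes["gene"])}
    true_links = []
    for row in np.flatnonzero(category == "link"):
        g = peaks.iloc[row]["linked_gene"]
        mean[gene_index[g], :] += config.link_effect * atac[row, :]
        true_links.append((peaks.iloc[row]["name"], g, config.link_effect))

    # regulons: focal-group boosted targets; TF gene boosted likewise
    groups = [f"normal_type_{t}" for t in range(config.n_cell_types)] + [
        primary_label,
        met_label,
    ]
    planted_genes = {gene_index[g] for _, g, _ in true_links}
    free = [i for i in range(config.n_genes) if i not in planted_genes]
    needed = config.n_regulons * (config.targets_per_regulon + 1)
    if needed > len(free):
        raise ValueError("not enough genes free of planted links for the requested regulons")
    pick = rng_expr.permutation(free)
    true_regulons = {}
    regulon_groups = {}
    pos = 0
    for r in range(config.n_regulons):
        focal = groups[r % len(groups)]
        in_group = (ctype == focal) if focal.startswith("normal_type") else (cond == focal)
        tf_idx = pick[pos]
        target_idx = pick[pos + 1 : pos + 1 + config.targets_per_regulon]
        pos += 1 + config.targets_per_regulon
        mean[tf_idx, in_group] *= 1.0 + REGULON_EFFECT
        mean[np.ix_(target_idx, in_group)] *= 1.0 + REGULON_EFFECT
        tf = genes["gene"].iloc[tf_idx]
        true_regulons[tf] = set(genes["gene"].iloc[target_idx])
        regulon_groups[tf] = focal

    size = config.noise_dispersion
    rna = rng_expr.negative_binomial(size, size / (size + mean)).astype(np.int64)

    peaks = peaks[
        ["name", "chrom", "start", "end", "summit", "score", "category", "marker_of", "linked_gene"]
    ].copy()
    data = MultiomeData(atac=atac, rna=rna, peaks=peaks, genes=genes, cells=cells)
    data.regulon_groups = regulon_groups  # convenience for tests / pipeline

    dnp_pairs = []
    for j, c in enumerate(config.dnp_co_rates):
        p1 = 1001 + 100 * j
        dnp_pairs.append((f"chr1:{p1}:G>A", f"chr1:{p1 + 1}:C>T", float(c)))

    gt = GroundTruth(
        true_links=true_links,
        true_regulons=true_regulons,
        true_pseudotime={
            cid: float(pt[i]) for i, cid in enumerate(cells["cell_id"]) if on_traj[i]
        },
        true_cnc={"SYN": cnc_type},
        true_dnp_pairs=dnp_pairs,
    )
    return data, gt


def default_motif_membership(data: MultiomeData) -> dict:
    """Motif -> member peak names derived from planted peak categories.

    One motif per normal-type marker program, one for the shared tumour
    signature, and ``MET_program`` for the pseudotime-driven block.
    """
    peaks = data.peaks
    membership = {}
    for owner, sub in peaks[peaks["category"] == "marker"].groupby("marker_of"):
        membership[f"motif_{owner}"] = sub["name"].tolist()
    traj = peaks.loc[peaks["category"] == "trajectory", "name"].tolist()
    if traj:
        membership["MET_program"] = traj
    return membership


def simulate_motif_scores(data: MultiomeData, motif_membership: dict) -> pd.DataFrame:
    """Cell x motif score matrix: z-scored mean accessibility of member peaks.

    A stand-in for bias-corrected motif deviation scores; each motif's score
    is the across-cell z-score of the mean accessibility of its member
    peaks (constant motifs score zero everywhere).
    """
    name_to_row = {n: i for i, n in enumerate(data.peaks["name"])}
    cols = {}
    for motif, members in motif_membership.items():
        if len(members) == 0:
            raise ValueError(f"motif {motif!r} has no member peaks")
        rows = [name_to_row[m] for m in members]
        mean_acc = data.atac[rows, :].mean(axis=0).astype(float)
        sd = mean_acc.std()
        cols[motif] = (mean_acc - mean_acc.mean()) / sd if sd > 0 else np.zeros_like(mean_acc)
    return pd.DataFrame(cols, index=data.cell_ids)


def dnp_variant_table(config: SimConfig) -> pd.DataFrame:
    """Variant calls (1-based positions) corresponding to the planted DNP pairs."""
    rows = []
    for j, _ in enumerate(config.dnp_co_rates):
        p1 = 1001 + 100 * j
        rows.append(("chr1", p1, "G", "A"))
        rows.append(("chr1", p1 + 1, "C", "T"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def simulate_reads(config: SimConfig) -> pd.DataFrame:
    """Read-level allele table with planted co-occurring SNV pairs.

    For each planted pair with co-occurrence rate ``c``, ``dnp_n_spanning``
    reads span both (1-based) positions; each carries both alternate
    alleles with probability ``c``, otherwise the alternate at exactly one
    site.  Extra reference-only reads cover each site.
    """
    rng = config.child_rng("reads")
    cells = _cell_panel(config)["cell_id"].to_numpy()
    rows = []
    read_no = 0
    for j, c in enumerate(config.dnp_co_rates):
        p1 = 1001 + 100 * j
        p2 = p1 + 1
        for _ in range(config.dnp_n_spanning):
            rid = f"read_{read_no:06d}"
            read_no += 1
            bc = str(rng.choice(cells))
            if rng.random() < c:
                alleles = ("A", "T")  # both alternates
            else:
                alleles = ("A", "C") if rng.random() < 0.5 else ("G", "T")
            rows.append((bc, "chr1", p1, alleles[0], rid))
            rows.append((bc, "chr1", p2, alleles[1], rid))
        for _ in range(20):  # reference-only coverage of the first site
            rid = f"read_{read_no:06d}"
            read_no += 1
            rows.append((str(rng.choice(cells)), "chr1", p1, "G", rid))
    return pd.DataFrame(rows, columns=["barcode", "chrom", "pos", "allele", "read_id"])


def simulate_segments(config: SimConfig):
    """Copy-ratio segments tiling each chromosome plus gene intervals.

    Segments are non-overlapping and cover each chromosome end to end;
    every gene interval (TSS +/- 10 kb) overlaps at least one segment, and
    the first genes of each chromosome straddle a forced breakpoint so the
    weighted-ratio path is exercised.
    """
    rng = config.child_rng("segments")
    genes = _gene_layout(config)
    seg_rows = []
    gene_rows = []
    ratios = np.array([0.5, 1.0, 1.0, 1.0, 1.5])
    for chrom, sub in genes.groupby("chrom", sort=False):
        chrom_len = len(sub) * TERRITORY
        forced = [int(t) for t in sub["tss"].iloc[:3]]  # breakpoints inside gene bodies
        cuts = {0, chrom_len, *forced}
        pos = 0
        while pos < chrom_len:
            pos += int(rng.uniform(0.8e6, 1.6e6))
            if pos < chrom_len:
                cuts.add(pos)
        bounds = sorted(cuts)
        for s, e in zip(bounds[:-1], bounds[1:]):
            seg_rows.append((chrom, s, e, float(rng.choice(ratios))))
        for _, g in sub.iterrows():
            gene_rows.append((g["gene"], chrom, g["tss"] - 10_000, g["tss"] + 10_000))
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "copy_ratio"])
    gene_intervals = pd.DataFrame(gene_rows, columns=["gene", "chrom", "start", "end"])
    return segments, gene_intervals


def simulate_grn_runs(
    gt: GroundTruth,
    gene_pool,
    n_runs: int = 10,
    true_rate: float = 0.9,
    spurious_per_tf: int = 10,
    spurious_rate: float = 0.2,
    rng: np.random.Generator | None = None,
) -> list:
    """Emulate repeated stochastic GRN-inference runs.

    Each run reports, per TF, its true targets with probability
    ``true_rate`` plus a TF-specific set of spurious targets each included
    with probability ``spurious_rate`` -- the input contract of the regulon
    stability filter.
    """
    rng = rng or np.random.default_rng(0)
    gene_pool = list(gene_pool)
    spurious = {
        tf: list(rng.choice(gene_pool, spurious_per_tf, replace=False))
        for tf in gt.true_regulons
    }
    runs = []
    for _ in range(n_runs):
        run = {}
        for tf, targets in gt.true_regulons.items():
            kept = {t for t in sorted(targets) if rng.random() < true_rate}
            kept |= {s for s in spurious[tf] if rng.random() < spurious_rate}
            run[tf] = kept
        runs.append(run)
    return runs


def simulate_diffuse_case(
    seed: int = 0,
    n_cells: int = 500,
    n_windows_diffuse: int = 15,
    n_windows_specific: int = 15,
    peaks_per_window: int = 6,
    window_size: int = 100_000,
):
    """Designed simulation for the diffuse-correlation correction.

    Two kinds of 100-kb windows, one gene each, windows placed far apart:

    * *diffuse* windows: every member peak follows a shared per-cell
      latent factor and the gene tracks the *summed* window accessibility
      -- each per-peak link is spurious (regional accessibility, not a
      specific element);
    * *specific* windows: a single planted peak drives the gene strongly
      while the remaining member peaks are background, so the window
      signal is diluted.

    A correct correction removes the diffuse per-peak links and keeps the
    specific ones.  Returns ``(MultiomeData, spurious_links,
    specific_links)`` with the planted (peak, gene) pairs.
    """
    rng = np.random.default_rng(seed)
    n_win = n_windows_diffuse + n_windows_specific
    peak_rows = []
    gene_rows = []
    prob = []
    gene_mean = []
    spurious, specific = [], []
    kinds = ["diffuse"] * n_windows_diffuse + ["specific"] * n_windows_specific
    for w, kind in enumerate(kinds):
        win_start = w * 10 * window_size  # windows 1 Mb apart on one contig
        gene = f"gene_w{w:02d}"
        tss = win_start + window_size + 5_000  # within 500 kb of the window
        gene_rows.append((gene, "chr1", tss, "+"))
        member_probs = []
        if kind == "diffuse":
            u = rng.uniform(0.1, 0.9, n_cells)  # shared regional openness
            for j in range(peaks_per_window):
                member_probs.append(u)
        else:
            causal = rng.binomial(1, 0.5, n_cells).astype(float)
            member_probs.append(np.where(causal > 0, 0.95, 0.05))
            for j in range(peaks_per_window - 1):
                member_probs.append(np.full(n_cells, 0.3))
        names = []
        for j, p in enumerate(member_probs):
            summit = win_start + 10_000 + j * 15_000
            name = f"peak_w{w:02d}_{j}"
            names.append(name)
            peak_rows.append(
                {
                    "name": name,
                    "chrom": "chr1",
                    "start": summit - 250,
                    "end": summit + 251,
                    "summit": summit,
                    "score": 10.0,
                    "category": kind,
                    "marker_of": "",
                    "linked_gene": gene if (kind == "specific" and j == 0) else "",
                }
            )
        X_w = rng.binomial(1, np.vstack(member_probs))
        prob.append(X_w)
        if kind == "diffuse":
            drive = X_w.sum(axis=0).astype(float)
            spurious.extend((nm, gene) for nm in names)
        else:
            drive = 4.0 * X_w[0].astype(float)
            specific.append((names[0], gene))
        gene_mean.append(1.0 + drive)
    atac = np.vstack(prob).astype(np.uint8)
    mean = np.vstack(gene_mean)
    size = 10.0
    rna = rng.negative_binomial(size, size / (size + mean)).astype(np.int64)
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell_{i:05d}" for i in range(n_cells)],
            "cell_type": "case",
            "sample": "S1",
            "cohort": "SYN",
            "condition": "primary",
        }
    )
    data = MultiomeData(
        atac=atac,
        rna=rna,
        peaks=pd.DataFrame(peak_rows),
        genes=pd.DataFrame(gene_rows, columns=["gene", "chrom", "tss", "strand"]),
        cells=cells,
    )
    return data, spurious, specific


def simulate_sample_peaksets(
    data: MultiomeData, n_samples: int = 3, detect_rate: float = 0.9, jitter: int = 50,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-sample peak calls around the true catalog, for merge exercises.

    Each sample detects a random subset of catalog peaks with its own
    significance scores and summit jitter; merging the per-sample sets
    should recover (a jittered copy of) the catalog.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for s in range(n_samples):
        detected = rng.random(len(data.peaks)) < detect_rate
        sub = data.peaks[detected]
        for _, p in sub.iterrows():
            summit = int(p["summit"] + rng.integers(-jitter, jitter + 1))
            rows.append(
                {
                    "chrom": p["chrom"],
                    "start": summit - 250,
                    "end": summit + 251,
                    "summit": summit,
                    "score": float(rng.uniform(2.0, 100.0)),
                    "name": f"S{s + 1}_{p['name']}",
                    "sample_id": f"S{s + 1}",
                    "cohort": "SYN",
                }
            )
    return pd.DataFrame(rows)


def write_simulation(outdir, config: SimConfig, data: MultiomeData, gt: GroundTruth) -> None:
    """Write all simulated inputs as plain-text files (see module docstring
    for the coordinate conventions)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eio.write_peaks_bed(data.peaks, outdir / "peaks.bed")
    eio.write_matrix_mtx(data.atac, data.peak_names, data.cell_ids, outdir, "atac")
    eio.write_matrix_mtx(data.rna, data.gene_names, data.cell_ids, outdir, "rna")
    data.cells.to_csv(outdir / "cell_metadata.tsv", sep="\t", index=False)
    data.genes.to_csv(outdir / "gene_annotation.tsv", sep="\t", index=False)
    data.peaks.to_csv(outdir / "peak_annotation.tsv", sep="\t", index=False)
    eio.write_gmt(gt.true_regulons, outdir / "regulon_targets.gmt")
    simulate_reads(config).to_csv(outdir / "reads.tsv", sep="\t", index=False)
    segments, gene_intervals = simulate_segments(config)
    segments.to_csv(outdir / "segments.tsv", sep="\t", index=False)
    gene_intervals.to_csv(outdir / "gene_intervals.tsv", sep="\t", index=False)
    eio.write_json(
        {
            "true_links": [list(t) for t in gt.true_links],
            "true_regulons": {k: sorted(v) for k, v in gt.true_regulons.items()},
            "true_pseudotime": gt.true_pseudotime,
            "true_cnc": gt.true_cnc,
            "true_dnp_pairs": [list(t) for t in gt.true_dnp_pairs],
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
        },
        outdir / "ground_truth.json",
    )


def read_simulation(outdir):
    """Round-trip reader for :func:`write_simulation` outputs."""
    outdir = Path(outdir)
    atac, peak_names, barcodes = eio.read_matrix_mtx(outdir, "atac")
    rna, gene_names, _ = eio.read_matrix_mtx(outdir, "rna")
    peaks = pd.read_csv(outdir / "peak_annotation.tsv", sep="\t").fillna({"marker_of": "", "linked_gene": ""})
    genes = pd.read_csv(outdir / "gene_annotation.tsv", sep="\t")
    cells = pd.read_csv(outdir / "cell_metadata.tsv", sep="\t")
    data = MultiomeData(
        atac=atac.astype(np.uint8),
        rna=rna.astype(np.int64),
        peaks=peaks,
        genes=genes,
        cells=cells,
    )
    raw = eio.read_json(outdir / "ground_truth.json")
    gt = GroundTruth(
        true_links=[tuple(t) for t in raw["true_links"]],
        true_regulons={k: set(v) for k, v in raw["true_regulons"].items()},
        true_pseudotime=raw["true_pseudotime"],
        true_cnc=raw["true_cnc"],
        true_dnp_pairs=[tuple(t) for t in raw["true_dnp_pairs"]],
    )
    return data, gt
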
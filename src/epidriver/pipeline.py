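"""End-to-end synthetic pipeline: orchestration, logging, provenance.

``run_pipeline`` executes the stages in dependency order

    simulate -> peaks -> embed -> diff -> cnc -> link -> regulon
             -> traj -> variants

on a synthetic dataset, writing each stage's outputs plus a provenance
manifest (stage list, parameters, seed fan-out, content hashes).  Reruns
with the same configuration are bit-identical; the manifest deliberately
records no timestamps.  A stage failure aborts the run naming the stage;
partial outputs are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from epidriver import cnc as cnc_mod
from epidriver import differential as diff_mod
from epidriver import io as eio
from epidriver import linking as link_mod
from epidriver import peaks as peaks_mod
from epidriver import regulons as reg_mod
from epidriver import trajectory as traj_mod
from epidriver import variants as var_mod
from epidriver.embedding import lsi, lsi_trajectory_components, tfidf
from epidriver.simulate import (
    SimConfig,
    default_motif_membership,
    dnp_variant_table,
    simulate_grn_runs,
    simulate_motif_scores,
    simulate_multiome,
    simulate_reads,
    simulate_sample_peaksets,
    simulate_segments,
    write_simulation,
)

log = logging.getLogger("epidriver")

STAGES = ["simulate", "peaks", "embed", "diff", "cnc", "link", "regulon", "traj", "variants"]

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": {s: True for s in STAGES},
    "simulate": {},  # SimConfig overrides
    "link": {"max_dist": 500_000, "n_background": 200},
    "regulon": {"n_samplings": 500, "min_frac": 0.8, "min_targets": 20},
    "traj": {"n_folds": 10},
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config (optional) and overrides onto the defaults;
    unknown top-level keys are rejected."""
    import yaml

    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for source in (
        yaml.safe_load(open(path)) if path else None,
        overrides,
    ):
        if not source:
            continue
        unknown = set(source) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in source.items():
            if isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: dict, outdir) -> dict:
    """Run the enabled stages on synthetic data; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)
    enabled = {s: bool(config.get("stages", {}).get(s, True)) for s in STAGES}
    seed = int(config.get("seed", 0))
    sim_cfg = SimConfig(**{**config.get("simulate", {}), "seed": seed})
    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "stages": [],
        "parameters": {},
        "outputs": {},
    }
    state: dict = {}

    def finish_stage(name: str, params: dict, files: list):
        manifest["stages"].append(name)
        manifest["parameters"][name] = params
        for f in files:
            manifest["outputs"][str(Path(f).relative_to(outdir))] = _sha256(Path(f))
        log.info("stage %s complete (%d output files)", name, len(files))

    def stage_simulate():
        data, gt = simulate_multiome(sim_cfg)
        simdir = outdir / "simulate"
        write_simulation(simdir, sim_cfg, data, gt)
        state["data"], state["gt"] = data, gt
        finish_stage(
            "simulate",
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in dataclasses.asdict(sim_cfg).items()},
            sorted(simdir.glob("*")),
        )

    def stage_peaks():
        data = state["data"]
        rng = sim_cfg.child_rng("sample_peaks")
        per_sample = simulate_sample_peaksets(data, rng=rng)
        per_sample = peaks_mod.recenter_and_score(per_sample, total_width=501)
        cohort = peaks_mod.build_unified_catalog(
            [g for _, g in per_sample.groupby("sample_id")], level="cohort"
        )
        pan = peaks_mod.build_unified_catalog([cohort], level="pan-cancer")
        pan = peaks_mod.annotate_peaks(pan, data.genes)
        # synthetic per-cell QC metrics, to exercise the cell gates
        n = len(data.cells)
        metrics = pd.DataFrame(
            {
                "fragments_in_peaks": rng.integers(500, 25000, n),
                "pct_reads_in_peaks": rng.uniform(5, 80, n),
                "blacklist_fraction": rng.uniform(0, 0.1, n),
                "nucleosome_signal": rng.uniform(0, 8, n),
                "tss_enrichment": rng.uniform(0, 10, n),
            },
            index=data.cell_ids,
        )
        qc_pass = peaks_mod.qc_filter_cells(metrics)
        d = outdir / "peaks"
        d.mkdir(exist_ok=True)
        _write_tsv(pan, d / "pan_catalog.tsv")
        _write_tsv(metrics.assign(qc_pass=qc_pass), d / "cell_qc.tsv")
        state["catalog"] = pan
        finish_stage(
            "peaks",
            {"total_width": 501, "qc_pass_fraction": float(qc_pass.mean())},
            [d / "pan_catalog.tsv", d / "cell_qc.tsv"],
        )

    def stage_embed():
        data = state["data"]
        norm = tfidf(data.atac)
        n_comp = min(50, min(norm.shape) - 1)
        res = lsi(norm, n_components=n_comp)
        state["lsi"] = res
        d = outdir / "embed"
        d.mkdir(exist_ok=True)
        emb = pd.DataFrame(
            res.embedding,
            index=data.cell_ids,
            columns=[f"LSI_{i + 1}" for i in range(res.embedding.shape[1])],
        )
        emb.to_csv(d / "lsi_embedding.tsv", sep="\t", float_format="%.8g")
        finish_stage("embed", {"n_components": n_comp}, [d / "lsi_embedding.tsv"])

    def stage_diff():
        data = state["data"]
        cond = data.cells["condition"].to_numpy()
        ctype = data.cells["cell_type"].to_numpy()
        cnc_type = state["gt"].true_cnc["SYN"]
        primary = np.flatnonzero(cond == sim_cfg.trajectory_groups[1])
        cnc_cells = np.flatnonzero(ctype == cnc_type)
        both = np.concatenate([primary, cnc_cells])
        y = np.concatenate([np.ones(len(primary)), np.zeros(len(cnc_cells))])
        latent = data.atac[:, both].mean(axis=0)  # fraction of peaks accessible
        dacr = diff_mod.lr_dacr_test(
            data.atac[:, both], y, latent, feature_ids=data.peak_names, adjust="bonferroni"
        )
        dacr = dacr.merge(
            state["catalog"][["name", "nearest_gene"]].rename(columns={"name": "feature_id"}),
            on="feature_id",
            how="left",
        ) if "catalog" in state else dacr.assign(nearest_gene=None)
        deg = diff_mod.wilcoxon_markers(
            data.rna,
            primary,
            cnc_cells,
            feature_ids=data.gene_names,
            adjust="bonferroni",
        )
        d = outdir / "diff"
        d.mkdir(exist_ok=True)
        _write_tsv(dacr, d / "dacr_primary_vs_cnc.tsv")
        _write_tsv(deg, d / "deg_primary_vs_cnc.tsv")
        state["dacr"], state["deg"] = dacr, deg
        finish_stage(
            "diff",
            {"adjust": "bonferroni", "n_dacr_tested": len(dacr), "n_deg_tested": len(deg)},
            [d / "dacr_primary_vs_cnc.tsv", d / "deg_primary_vs_cnc.tsv"],
        )

    def stage_cnc():
        data = state["data"]
        normal_mask = data.cells["condition"] == sim_cfg.trajectory_groups[0]
        tumour_mask = ~normal_mask
        # marker features: per-normal-type rank-sum markers + primary-vs-normal markers
        features = set()
        ctype = data.cells["cell_type"].to_numpy()
        for t in sorted(data.cells.loc[normal_mask, "cell_type"].unique()):
            a = np.flatnonzero(normal_mask & (ctype == t))
            b = np.flatnonzero(normal_mask & (ctype != t))
            res = diff_mod.wilcoxon_markers(
                data.atac, a, b, feature_ids=data.peak_names, only_pos=True, adjust="bh"
            )
            features |= set(res.nsmallest(50, "p")["feature_id"])
        res = diff_mod.wilcoxon_markers(
            data.atac,
            np.flatnonzero(tumour_mask.to_numpy()),
            np.flatnonzero(normal_mask.to_numpy()),
            feature_ids=data.peak_names,
            only_pos=True,
            adjust="bh",
        )
        features |= set(res.nsmallest(50, "p")["feature_id"])
        features = sorted(features)

        tum_profiles = cnc_mod.pseudobulk_profiles(
            data.atac[:, tumour_mask.to_numpy()],
            data.peak_names,
            data.cells.loc[tumour_mask, "sample"],
        )
        norm_profiles = cnc_mod.pseudobulk_profiles(
            data.atac[:, normal_mask.to_numpy()],
            data.peak_names,
            data.cells.loc[normal_mask, "cell_type"],
        )
        medians, chosen = cnc_mod.infer_cnc(tum_profiles, norm_profiles, features)
        d = outdir / "cnc"
        d.mkdir(exist_ok=True)
        _write_tsv(
            medians.rename("median_r").rename_axis("cell_type").reset_index().assign(selected=lambda f: f["cell_type"] == chosen),
            d / "cnc_medians.tsv",
        )
        state["cnc_choice"] = chosen
        finish_stage(
            "cnc",
            {"n_features": len(features), "selected": chosen, "true_cnc": state["gt"].true_cnc["SYN"]},
            [d / "cnc_medians.tsv"],
        )

    def stage_link():
        data, gt = state["data"], state["gt"]
        p = config.get("link", {})
        links = link_mod.link_peaks_to_genes(
            data.atac,
            data.rna,
            data.peaks,
            data.genes,
            max_dist=p.get("max_dist", 500_000),
            n_background=min(p.get("n_background", 200), len(data.peaks) - 1),
        )
        truth = {(pk, gn) for pk, gn, _ in gt.true_links}
        sig0 = links[links["retained"]]  # significance gate, before corrections
        found = set(zip(sig0["peak_id"], sig0["gene_id"]))
        recall = len(found & truth) / len(truth) if truth else np.nan
        precision = len(found & truth) / len(found) if found else np.nan
        links = link_mod.diffuse_window_filter(links, data.atac, data.rna, data.peaks, data.genes)
        blocked = link_mod.exclude_cnv_genes(
            pd.DataFrame({"gene": [], "amp_fraction": [], "amp_cells": []})
        )
        links = links[~links["gene_id"].isin(blocked)]
        sig = links[links["retained"]]
        trans = link_mod.transition_links(sig, state["dacr"], state["deg"]) if "dacr" in state else None
        d = outdir / "link"
        d.mkdir(exist_ok=True)
        _write_tsv(links, d / "links.tsv")
        files = [d / "links.tsv"]
        if trans is not None:
            _write_tsv(trans, d / "transition_links.tsv")
            files.append(d / "transition_links.tsv")
        state["links"] = links
        finish_stage(
            "link",
            {**p, "n_links": len(links), "n_significant": len(sig0),
             "n_retained_after_diffuse": int(links["retained"].sum()),
             "recall_vs_truth": recall, "precision_vs_truth": precision},
            files,
        )

    def stage_regulon():
        data, gt = state["data"], state["gt"]
        p = config.get("regulon", {})
        rng = sim_cfg.child_rng("grn_runs")
        runs = simulate_grn_runs(gt, data.gene_names, rng=rng)
        regs = reg_mod.stability_filter(
            runs, min_frac=p.get("min_frac", 0.8), min_targets=p.get("min_targets", 20)
        )
        auc = reg_mod.score_regulons(data.rna, data.gene_names, regs)
        auc.columns = data.cell_ids
        top = reg_mod.prioritize_specific_regulons(auc, data.cells["cell_type"])
        cnc_type = gt.true_cnc["SYN"]
        tum = data.cells.loc[
            data.cells["condition"] != sim_cfg.trajectory_groups[0], "cell_id"
        ]
        cnc_cells = data.cells.loc[data.cells["cell_type"] == cnc_type, "cell_id"]
        labels = reg_mod.annotate_cancer_specific(auc, tum, cnc_cells)
        # enrichment of targets among genes linked to TF-motif peaks
        sig = state["links"][state["links"]["retained"]] if "links" in state else None
        enrich_rows = []
        if sig is not None and len(sig):
            linked_by_peak = sig.groupby("peak_id")["gene_id"].apply(set)
            membership = default_motif_membership(data)
            pool = set(data.gene_names)
            for i, tf in enumerate(sorted(regs["tf"].unique())):
                motif_peaks = membership.get("motif_tumour", [])
                linked = set().union(
                    *[linked_by_peak.get(pk, set()) for pk in motif_peaks]
                ) if motif_peaks else set()
                targets = set(regs.loc[regs["tf"] == tf, "target"])
                res = reg_mod.tf_link_enrichment(
                    tf, targets, linked, pool,
                    n_samplings=p.get("n_samplings", 500), seed=seed * 1000 + i,
                )
                enrich_rows.append(dataclasses.asdict(res))
        d = outdir / "regulon"
        d.mkdir(exist_ok=True)
        _write_tsv(regs, d / "regulons.tsv")
        auc.rename_axis("tf").reset_index().to_csv(d / "auc_scores.tsv", sep="\t", index=False, float_format="%.8g")
        _write_tsv(labels, d / "regulon_labels.tsv")
        files = [d / "regulons.tsv", d / "auc_scores.tsv", d / "regulon_labels.tsv"]
        if enrich_rows:
            _write_tsv(pd.DataFrame(enrich_rows), d / "tf_link_enrichment.tsv")
            files.append(d / "tf_link_enrichment.tsv")
        state["auc"] = auc
        finish_stage(
            "regulon",
            {**p, "n_regulons": regs["tf"].nunique(),
             "recovered_true": sorted(set(regs["tf"]) & set(gt.true_regulons))},
            files,
        )

    def stage_traj():
        data, gt = state["data"], state["gt"]
        p = config.get("traj", {})
        normal_label, primary_label, met_label = sim_cfg.trajectory_groups
        cnc_type = gt.true_cnc["SYN"]
        on_traj = (
            (data.cells["cell_type"] == cnc_type)
            | data.cells["condition"].isin([primary_label, met_label])
        ).to_numpy()
        X = lsi_trajectory_components(state["lsi"])[on_traj]
        conds = data.cells.loc[on_traj, "condition"]
        Xa, clusters, start, mode = traj_mod.assemble_trajectory_input(
            X, conds, normal_label=normal_label,
            primary_label=primary_label, met_label=met_label,
        )
        result = traj_mod.fit_pseudotime(Xa, clusters, start, mode=mode)
        cells_on = data.cells.loc[on_traj, "cell_id"]
        true_pt = np.array([gt.true_pseudotime[c] for c in cells_on])
        from scipy.stats import spearmanr

        rho = float(spearmanr(result.pseudotime, true_pt).statistic)
        motifs = simulate_motif_scores(data, default_motif_membership(data)).loc[cells_on]
        tf_corr = traj_mod.correlate_pseudotime_tf(result.pseudotime, motifs)
        lasso = traj_mod.lasso_select_peaks(
            result.pseudotime,
            data.atac[:, on_traj].T,
            peak_ids=data.peak_names,
            n_folds=p.get("n_folds", 10),
            seed=seed,
        )
        ann = state.get("catalog")
        files = []
        d = outdir / "traj"
        d.mkdir(exist_ok=True)
        pd.DataFrame(
            {"cell_id": cells_on, "pseudotime": result.pseudotime, "cluster": clusters.to_numpy()}
        ).to_csv(d / "pseudotime.tsv", sep="\t", index=False, float_format="%.8g")
        _write_tsv(tf_corr, d / "tf_pseudotime_correlation.tsv")
        _write_tsv(lasso, d / "lasso_selected_peaks.tsv")
        files += [d / "pseudotime.tsv", d / "tf_pseudotime_correlation.tsv", d / "lasso_selected_peaks.tsv"]
        if ann is not None and len(lasso):
            name_to_gene = data.peaks.merge(
                ann[["name", "nearest_gene"]], on="name", how="left"
            ).set_index("name")["nearest_gene"]
            sel_genes = {name_to_gene.get(pk) for pk in lasso["peak_id"]} - {None}
            ora = traj_mod.peak_ora(sel_genes, gt.true_regulons, set(data.gene_names))
            _write_tsv(ora, d / "pathway_ora.tsv")
            files.append(d / "pathway_ora.tsv")
        state["pseudotime_rho"] = rho
        finish_stage(
            "traj",
            {**p, "mode": mode, "spearman_vs_truth": rho,
             "n_lasso_selected": len(lasso)},
            files,
        )

    def stage_variants():
        gt = state["gt"]
        reads = simulate_reads(sim_cfg)
        variants = dnp_variant_table(sim_cfg)
        cancer = set(
            state["data"].cells.loc[
                state["data"].cells["condition"] != sim_cfg.trajectory_groups[0], "cell_id"
            ]
        )
        groups = {
            c: ("cancer" if c in cancer else "normal")
            for c in state["data"].cells["cell_id"]
        }
        counts = var_mod.per_cell_allele_counts(reads, variants, groups)
        dnp = var_mod.merge_dnp(variants, reads)
        segments, gene_intervals = simulate_segments(sim_cfg)
        calls = var_mod.gene_cnv_call(segments, gene_intervals)
        d = outdir / "variants"
        d.mkdir(exist_ok=True)
        _write_tsv(counts, d / "allele_counts.tsv")
        _write_tsv(dnp, d / "dnp_calls.tsv")
        _write_tsv(calls, d / "gene_cnv_calls.tsv")
        merged_pairs = set(dnp.loc[dnp["variant_type"] == "DNP", "pos"])
        finish_stage(
            "variants",
            {"n_dnp_merged": int((dnp["variant_type"] == "DNP").sum()),
             "true_pairs": [list(t) for t in gt.true_dnp_pairs]},
            [d / "allele_counts.tsv", d / "dnp_calls.tsv", d / "gene_cnv_calls.tsv"],
        )

    runners = {
        "simulate": stage_simulate,
        "peaks": stage_peaks,
        "embed": stage_embed,
        "diff": stage_diff,
        "cnc": stage_cnc,
        "link": stage_link,
        "regulon": stage_regulon,
        "traj": stage_traj,
        "variants": stage_variants,
    }
    for name in STAGES:
        if not enabled[name]:
            log.info("stage %s disabled", name)
            continue
        try:
            runners[name]()
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    eio.write_json(manifest, manifest_path)
    return manifest
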
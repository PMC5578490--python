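"""End-to-end pipeline: simulate -> call peaks -> differential accessibility
-> motif enrichment -> footprints -> annotation -> target genes -> TF
prioritization, from a single config, with a manifest and deterministic
outputs (rerunning one config/seed is byte-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__, annotation, expression_tools, footprinting
from .genomics_io import (
    GenomicInterval,
    write_cleavage_bed,
    write_expression_table,
    write_fasta,
    write_gene_table,
    write_narrowpeak,
)
from .integration_targets import (
    TargetFilterSpec,
    high_confidence_targets,
    prioritization_to_frame,
    prioritize_tfs,
)
from .motif_analysis import (
    DEFAULT_MOTIFS,
    MotifModel,
    enrichment,
    matched_background,
    region_hit_flags,
)
from .peaks_accessibility import (
    count_matrix,
    differential_accessibility,
    pool_and_recall,
    summit_windows,
    top_regions,
    write_differential_bed,
)
from .synthetic_data import (
    MOTIF_TO_TFS,
    SimulationConfig,
    generate_genome,
    plant_regulatory_landscape,
    save_truth,
    simulate_expression,
    simulate_tracks,
)

#: Analysis thresholds mirroring the published defaults: 500 bp summit
#: windows on the top 50k regions, >5-fold / p<0.05 differential screen,
#: +/-1 kb promoters, 100 kb gene assignment, 500 bp motif windows,
#: +/-75 bp footprint flanks, FPKM>5 and >1.3-fold perturbation cuts.
DEFAULT_THRESHOLDS: Dict[str, float] = {
    "peak_window": 300,
    "peak_qcut": 0.01,
    "top_n": 50_000,
    "window": 500,
    "fold_cut": 5.0,
    "p_cut": 0.05,
    "promoter_halfwidth": 1000,
    "gene_max_distance": 100_000,
    "motif_window": 500,
    "footprint_flank": 75,
    "expression_floor": 5.0,
    "reduction_cut": 1.3,
    "tf_fold_threshold": 1.5,
    "background_per_target": 10,
}

STAGES = (
    "simulate",
    "callpeaks",
    "windows",
    "diffacc",
    "motifs",
    "footprint",
    "annotate",
    "targets",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def run_pipeline(
    config: dict,
    outdir: str,
    seed: Optional[int] = None,
) -> dict:
    """Run all stages; writes stage-prefixed outputs plus manifest.json.

    ``config`` has optional "simulation" (SimulationConfig fields) and
    "thresholds" (DEFAULT_THRESHOLDS overrides) sections. Returns the
    manifest dict. Any stage failure raises PipelineError naming the stage;
    outputs written so far are renamed with a .partial suffix.
    """
    os.makedirs(outdir, exist_ok=True)
    sim_kwargs = dict(config.get("simulation", {}))
    if seed is not None:
        sim_kwargs["seed"] = seed
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    sim_config = SimulationConfig(**sim_kwargs)

    effective = {
        "simulation": dataclasses.asdict(sim_config),
        "thresholds": thresholds,
    }
    manifest = {
        "config_hash": _config_hash(effective),
        "seed": sim_config.seed,
        "version": __version__,
        "thresholds": thresholds,
        "stages": {},
    }
    written: List[str] = []

    def out(name: str) -> str:
        path = os.path.join(outdir, name)
        written.append(path)
        return path

    current_stage = STAGES[0]
    try:
        # 1. simulate ------------------------------------------------------
        current_stage = "simulate"
        genome = generate_genome(sim_config)
        genome, truth = plant_regulatory_landscape(genome, sim_config)
        tracks, groups = simulate_tracks(truth)
        fpkm, perturb = simulate_expression(truth)
        sizes = sim_config.chrom_lengths()
        write_fasta(genome, out("simulate_genome.fa"))
        for track in tracks:
            write_cleavage_bed(track, out(f"simulate_cleavage_{track.sample_id}.bed"))
        write_gene_table(truth.genes, out("simulate_genes.tsv"))
        write_expression_table(fpkm, out("simulate_expression_fpkm.tsv"))
        write_expression_table(perturb, out("simulate_expression_dnfos.tsv"))
        save_truth(truth, out("simulate_truth.json"))
        manifest["stages"]["simulate"] = {
            "n_tracks": len(tracks),
            "n_genes": len(truth.genes),
            "n_planted_peaks": len(truth.planted_peaks),
        }

        # 2. call peaks on the pooled track --------------------------------
        current_stage = "callpeaks"
        peaks = pool_and_recall(
            tracks, sizes,
            window=int(thresholds["peak_window"]), qcut=thresholds["peak_qcut"],
        )
        write_narrowpeak(peaks, out("callpeaks_pooled.narrowPeak"))
        manifest["stages"]["callpeaks"] = {"n_peaks": len(peaks)}

        # 3. top regions and summit windows --------------------------------
        current_stage = "windows"
        top = top_regions(peaks, int(thresholds["top_n"]))
        windows, clipped = summit_windows(top, sizes, width=int(thresholds["window"]))
        summits = [p.summit for p in top]
        from .genomics_io import write_bed

        write_bed(windows, out("windows_summit.bed"))
        manifest["stages"]["windows"] = {
            "n_windows": len(windows), "n_clipped": int(sum(clipped)),
        }

        # 4. count matrix + differential accessibility ----------------------
        current_stage = "diffacc"
        matrix = count_matrix(windows, tracks)
        _write_tsv(
            matrix.to_frame().reset_index(names="region"),
            out("diffacc_norm_counts.tsv"),
        )
        diffs = differential_accessibility(
            matrix, groups,
            fold_cut=thresholds["fold_cut"], p_cut=thresholds["p_cut"],
        )
        write_differential_bed(diffs, out("diffacc_regions.bed"))
        manifest["stages"]["diffacc"] = {
            "n_differential": len(diffs),
            "n_open_in_cancer": sum(d.direction == "open-in-cancer" for d in diffs),
            "n_open_in_normal": sum(d.direction == "open-in-normal" for d in diffs),
        }

        # 5. motif enrichment over cancer-open regions ----------------------
        current_stage = "motifs"
        cancer_open = [d.region for d in diffs if d.direction == "open-in-cancer"]
        motif_rows = []
        enrichments = []
        if cancer_open:
            background = matched_background(
                cancer_open, genome,
                n_per_target=int(thresholds["background_per_target"]),
                seed=sim_config.seed,
            )
            for motif_id, consensus in DEFAULT_MOTIFS.items():
                result = enrichment(
                    cancer_open, background, genome, MotifModel(motif_id, consensus)
                )
                enrichments.append(result)
                motif_rows.append(
                    {
                        "motif_id": motif_id,
                        "target_hits": result.target_hits,
                        "target_total": result.target_total,
                        "background_fraction": result.background_fraction,
                        "fold_enrichment": result.fold_enrichment,
                        "neglog10_p": result.neglog10_p,
                    }
                )
        _write_tsv(pd.DataFrame(motif_rows), out("motifs_enrichment.tsv"))
        manifest["stages"]["motifs"] = {"n_motifs": len(motif_rows)}

        # 6. footprint profile at AP1 hits in cancer-open regions -----------
        current_stage = "footprint"
        ap1 = MotifModel("AP1", DEFAULT_MOTIFS["AP1"])
        from .motif_analysis import scan

        anchors = []
        for region in cancer_open:
            seq = genome[region.chrom][region.start:region.end]
            for hit in scan(seq, ap1, chrom=region.chrom, offset=region.start):
                anchors.append((hit.chrom, int(hit.centre), hit.strand))
        if anchors:
            cancer_track = next(t for t in tracks if groups[t.sample_id] == "cancer")
            profile = footprinting.cleavage_profile(
                cancer_track, anchors, flank=int(thresholds["footprint_flank"]),
                description="AP1 hits in cancer-open regions",
            )
            _write_tsv(profile.to_frame(), out("footprint_ap1_profile.tsv"))
        manifest["stages"]["footprint"] = {"n_anchors": len(anchors)}

        # 7. annotation ------------------------------------------------------
        current_stage = "annotate"
        diff_regions = [d.region for d in diffs]
        diff_summits = [r.midpoint for r in diff_regions]
        dist = annotation.genomic_distribution(
            diff_regions or windows, truth.genes,
            promoter_halfwidth=int(thresholds["promoter_halfwidth"]),
        )
        gene_map = annotation.nearest_gene_map(
            [(r.chrom, s) for r, s in zip(diff_regions, diff_summits)],
            truth.genes, max_distance=int(thresholds["gene_max_distance"]),
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "chrom": [r.chrom for r in diff_regions],
                    "start": [r.start for r in diff_regions],
                    "end": [r.end for r in diff_regions],
                    "direction": [d.direction for d in diffs],
                    "nearest_gene": [g or "" for g in gene_map],
                }
            ),
            out("annotate_nearest_gene.tsv"),
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "category": list(dist["counts"]),
                    "count": list(dist["counts"].values()),
                    "fraction": list(dist["fractions"].values()),
                }
            ),
            out("annotate_distribution.tsv"),
        )
        manifest["stages"]["annotate"] = {
            "n_assigned": sum(g is not None for g in gene_map),
            "promoter_fraction": dist["fractions"]["promoter"],
        }

        # 8. targets + prioritization ---------------------------------------
        current_stage = "targets"
        spec = TargetFilterSpec(
            motif_window=int(thresholds["motif_window"]),
            expression_floor=thresholds["expression_floor"],
            reduction_cut=thresholds["reduction_cut"],
        )
        hit_flags = (
            region_hit_flags(diff_regions, genome, ap1, window=spec.motif_window,
                             summits=diff_summits)
            if diff_regions else np.zeros(0, dtype=bool)
        )
        cancer_samples = [s for s, g in groups.items() if g == "cancer"]
        normal_samples = [s for s, g in groups.items() if g == "normal"]
        expression = fpkm.values[cancer_samples].mean(axis=1).to_dict()
        control = [c for c in perturb.samples if c.startswith("control")]
        dn = [c for c in perturb.samples if c.startswith("dnfos")]
        reductions = expression_tools.group_fold_changes(perturb, control, dn)
        call = high_confidence_targets(
            [d.direction for d in diffs], list(hit_flags), gene_map,
            expression, reductions, spec,
        )
        with open(out("targets_ap1_genes.txt"), "w") as fh:
            for gene in sorted(call.genes):
                fh.write(gene + "\n")
        rows = prioritize_tfs(
            enrichments, fpkm, MOTIF_TO_TFS, cancer_samples, normal_samples,
            fold_threshold=thresholds["tf_fold_threshold"],
        )
        _write_tsv(prioritization_to_frame(rows), out("targets_prioritization.tsv"))
        manifest["stages"]["targets"] = {
            "n_target_genes": len(call.genes),
            "top_motif": rows[0].motif_id if rows else "",
        }
    except Exception as exc:
        for path in written:
            if os.path.exists(path):
                os.replace(path, path + ".partial")
        raise PipelineError(current_stage, exc) from exc

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def manifest_hash(outdir: str) -> str:
    """SHA-256 over every non-partial output file, for determinism checks."""
    digest = hashlib.sha256()
    for name in sorted(os.listdir(outdir)):
        if name.endswith(".partial"):
            continue
        path = os.path.join(outdir, name)
        if os.path.isfile(path):
            digest.update(name.encode())
            with open(path, "rb") as fh:
                digest.update(fh.read())
    return digest.hexdigest()
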
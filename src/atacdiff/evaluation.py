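"""Recovery and calibration benchmarks of the pipeline on generator data.

Each function builds a synthetic dataset with known truth, runs the relevant
pipeline stages end to end, and scores the outcome against the generator's
ledger: type-I error of the differential test at a null fold, sensitivity and
FDR for planted differential regions, motif-enrichment strength, footprint
depths at occupied vs unoccupied instances, and Jaccard recovery of the
planted AP1-driven gene set plus driver-motif ranking.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import annotation, expression_tools, footprinting
from .genomics_io import GenomicInterval
from .integration_targets import (
    TargetFilterSpec,
    high_confidence_targets,
    prioritize_tfs,
)
from .motif_analysis import DEFAULT_MOTIFS, MotifModel, enrichment, matched_background
from .peaks_accessibility import (
    count_matrix,
    differential_accessibility,
    differential_table,
    pool_and_recall,
    summit_windows,
    top_regions,
)
from .synthetic_data import (
    MOTIF_TO_TFS,
    SimulationConfig,
    TruthRecord,
    generate_genome,
    plant_regulatory_landscape,
    simulate_expression,
    simulate_tracks,
)


def _dataset(config: SimulationConfig):
    genome = generate_genome(config)
    genome, truth = plant_regulatory_landscape(genome, config)
    tracks, groups = simulate_tracks(truth)
    return genome, truth, tracks, groups


def tiled_windows(config: SimulationConfig, width: int = 500) -> List[GenomicInterval]:
    windows = []
    for chrom, length in sorted(config.chrom_lengths().items()):
        for s in range(0, length - width + 1, width):
            windows.append(GenomicInterval(chrom, s, s + width))
    return windows


def null_calibration(
    seed: int, config: Optional[SimulationConfig] = None, p_cut: float = 0.05
) -> Dict[str, float]:
    """Empirical fraction of tiled regions with p < p_cut at accessibility fold 1.

    Every region is null (both groups share the cleavage field), so the
    fraction estimates the differential test's type-I error at p_cut.
    """
    config = config or SimulationConfig()
    config = dataclasses.replace(config, accessibility_fold=1.0, seed=seed)
    _, truth, tracks, groups = _dataset(config)
    windows = tiled_windows(config)
    table = differential_table(count_matrix(windows, tracks), groups)
    return {
        "rate": float((table["p"] < p_cut).mean()),
        "n_regions": len(windows),
    }


def differential_recovery(
    seed: int,
    config: Optional[SimulationConfig] = None,
    top_n: int = 50_000,
    window: int = 500,
    fold_cut: float = 5.0,
    p_cut: float = 0.05,
) -> Dict[str, float]:
    """Sensitivity/FDR of the full call-count-test chain on planted regions.

    Sensitivity: fraction of planted differential peaks (cancer-only and
    normal-only) overlapped by a retained region with the matching direction.
    FDR: fraction of retained regions that overlap no planted differential
    peak of their direction.
    """
    config = config or SimulationConfig()
    config = dataclasses.replace(config, seed=seed)
    _, truth, tracks, groups = _dataset(config)
    sizes = config.chrom_lengths()
    peaks = pool_and_recall(tracks, sizes)
    windows, _ = summit_windows(top_regions(peaks, top_n), sizes, width=window)
    matrix = count_matrix(windows, tracks)
    diffs = differential_accessibility(matrix, groups, fold_cut=fold_cut, p_cut=p_cut)

    wanted = {
        "cancer_only": "open-in-cancer",
        "normal_only": "open-in-normal",
    }
    planted = [
        (p.interval, wanted[p.peak_class])
        for p in truth.planted_peaks
        if p.peak_class in wanted
    ]
    recovered = 0
    for interval, direction in planted:
        if any(d.direction == direction and d.region.overlaps(interval) for d in diffs):
            recovered += 1
    false = sum(
        1
        for d in diffs
        if not any(
            d.direction == direction and d.region.overlaps(interval)
            for interval, direction in planted
        )
    )
    return {
        "sensitivity": recovered / len(planted) if planted else float("nan"),
        "fdr": false / len(diffs) if diffs else 0.0,
        "n_planted": len(planted),
        "n_called": len(diffs),
    }


def ap1_enrichment_in_cancer_open(
    seed: int, config: Optional[SimulationConfig] = None, n_per_target: int = 10
) -> Dict[str, float]:
    """Binomial AP1 enrichment of planted cancer-open regions vs GC-matched background."""
    config = config or SimulationConfig()
    config = dataclasses.replace(config, seed=seed)
    genome = generate_genome(config)
    genome, truth = plant_regulatory_landscape(genome, config)
    targets = [p.interval for p in truth.planted_peaks if p.peak_class == "cancer_only"]
    background = matched_background(targets, genome, n_per_target=n_per_target, seed=seed)
    result = enrichment(targets, background, genome, MotifModel("AP1", DEFAULT_MOTIFS["AP1"]))
    return {
        "neglog10_p": result.neglog10_p,
        "fold": result.fold_enrichment,
        "n_targets": result.target_total,
    }


def footprint_contrast(
    seed: int,
    config: Optional[SimulationConfig] = None,
    flank: int = 75,
    core_halfwidth: int = 3,
    flank_band: Tuple[int, int] = (25, 70),
) -> Dict[str, Optional[float]]:
    """Footprint depth at occupied vs unoccupied AP1 instances in one cancer sample."""
    config = config or SimulationConfig()
    config = dataclasses.replace(config, seed=seed)
    _, truth, tracks, groups = _dataset(config)
    cancer_track = next(t for t in tracks if groups[t.sample_id] == "cancer")
    out: Dict[str, Optional[float]] = {}
    for label, occupied in (("occupied", True), ("unoccupied", False)):
        anchors = truth.motif_anchors("AP1", occupied=occupied)
        if not anchors:
            out[f"depth_{label}"] = None
            continue
        profile = footprinting.cleavage_profile(cancer_track, anchors, flank=flank)
        out[f"depth_{label}"] = footprinting.footprint_depth(
            profile, core_halfwidth, flank_band
        )
        out[f"n_{label}"] = len(anchors)
    return out


def target_recovery(
    seed: int,
    config: Optional[SimulationConfig] = None,
    spec: TargetFilterSpec = TargetFilterSpec(),
) -> Dict[str, object]:
    """Run the AP1 target filter chain and score it against the planted truth.

    Returns the Jaccard index of predicted vs planted AP1-driven genes and
    the TF prioritization rows for the default motif set.
    """
    config = config or SimulationConfig()
    config = dataclasses.replace(config, seed=seed)
    genome = generate_genome(config)
    genome, truth = plant_regulatory_landscape(genome, config)
    tracks, groups = simulate_tracks(truth)
    fpkm, perturb = simulate_expression(truth)
    sizes = config.chrom_lengths()

    peaks = pool_and_recall(tracks, sizes)
    windows, _ = summit_windows(top_regions(peaks, 50_000), sizes, width=500)
    matrix = count_matrix(windows, tracks)
    diffs = differential_accessibility(matrix, groups)

    regions = [d.region for d in diffs]
    summits = [r.midpoint for r in regions]
    from .motif_analysis import region_hit_flags

    ap1 = MotifModel("AP1", DEFAULT_MOTIFS["AP1"])
    hit_flags = region_hit_flags(regions, genome, ap1, window=spec.motif_window,
                                 summits=summits)
    gene_map = annotation.nearest_gene_map(
        [(r.chrom, s) for r, s in zip(regions, summits)], truth.genes
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
    truth_set = truth.ap1_driven_genes()
    union = call.genes | truth_set
    jaccard = len(call.genes & truth_set) / len(union) if union else float("nan")

    cancer_open = [d.region for d in diffs if d.direction == "open-in-cancer"]
    background = matched_background(cancer_open, genome, n_per_target=10, seed=seed)
    enrichments = [
        enrichment(cancer_open, background, genome, MotifModel(mid, cons))
        for mid, cons in DEFAULT_MOTIFS.items()
    ]
    rows = prioritize_tfs(
        enrichments, fpkm, MOTIF_TO_TFS, cancer_samples, normal_samples,
        accessibility_direction="open-in-cancer",
    )
    return {
        "jaccard": jaccard,
        "n_predicted": len(call.genes),
        "n_truth": len(truth_set),
        "prioritization": rows,
        "top_motif": rows[0].motif_id if rows else None,
        "top_motif_significant": rows[0].significant if rows else False,
    }
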
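"""Cross-dataset filter chains and statistics: high-confidence AP1 targets,
ETV1 target selection, hypergeometric set overlap, and the motif-enrichment
x TF-expression prioritization scatter.

The AP1 target chain mirrors the published definition: regions more
accessible in cancer, carrying an AP1 motif within 500 bp of the summit,
assigned to their nearest gene, filtered for expression above 5 FPKM and a
>1.3-fold reduction under dominant-negative FOS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genomics_io import ValidationError
from .motif_analysis import EnrichmentResult


@dataclass
class TargetFilterSpec:
    """Cuts for the high-confidence target chain; all strict."""

    direction: str = "open-in-cancer"
    motif_ids: Tuple[str, ...] = ("AP1",)
    motif_window: int = 500
    expression_floor: float = 5.0
    reduction_cut: float = 1.3

    def __post_init__(self):
        if self.motif_window <= 0:
            raise ValidationError("motif_window must be > 0")
        if self.expression_floor <= 0 or self.reduction_cut <= 0:
            raise ValidationError("cuts must be > 0")


@dataclass
class TargetCallResult:
    genes: Set[str]
    provenance: Dict[str, List[int]] = field(default_factory=dict)  # gene -> region idx
    missing_expression: int = 0


def high_confidence_targets(
    directions: Sequence[str],
    hit_flags: Sequence[bool],
    gene_map: Sequence[Optional[str]],
    expression: Mapping[str, float],
    perturbation_folds: Mapping[str, float],
    spec: TargetFilterSpec = TargetFilterSpec(),
) -> TargetCallResult:
    """Genes of qualifying regions passing expression and perturbation cuts.

    Inputs are parallel per-region lists: the differential direction, the
    motif-presence flag (already evaluated over the spec's summit window) and
    the nearest-gene assignment. A gene is retained iff it is the nearest
    gene of >= 1 region in the required direction with a motif hit, its
    expression exceeds the floor, and its perturbation fold-reduction exceeds
    the cut — all strictly. Candidates without an expression value are
    dropped and counted.
    """
    if not (len(directions) == len(hit_flags) == len(gene_map)):
        raise ValidationError("per-region inputs must be parallel")
    result = TargetCallResult(set())
    for i, (direction, flag, gene) in enumerate(zip(directions, hit_flags, gene_map)):
        if direction != spec.direction or not flag or gene is None:
            continue
        if gene not in expression:
            result.missing_expression += 1
            continue
        if expression[gene] <= spec.expression_floor:
            continue
        if perturbation_folds.get(gene, 1.0) <= spec.reduction_cut:
            continue
        result.genes.add(gene)
        result.provenance.setdefault(gene, []).append(i)
    return result


def etv1_target_selection(
    gene_map: Sequence[Optional[str]],
    open_flags: Sequence[bool],
    motif_flags_ap1: Sequence[bool],
    motif_flags_ets: Sequence[bool],
) -> Set[str]:
    """Genes of ChIP peaks that are open AND carry an AP1 or ETS motif (or both)."""
    n = len(gene_map)
    if not (len(open_flags) == len(motif_flags_ap1) == len(motif_flags_ets) == n):
        raise ValidationError("per-peak inputs must be parallel")
    return {
        g
        for g, is_open, ap1, ets in zip(gene_map, open_flags, motif_flags_ap1, motif_flags_ets)
        if g is not None and is_open and (ap1 or ets)
    }


def overlap_hypergeometric(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> Tuple[float, int]:
    """Upper-tail hypergeometric P(X >= |A n B|) for two sets from one universe.

    Population universe_size, |B| successes, |A| draws. The universe must be
    supplied by the caller; it is part of the test's definition.
    """
    a, b = set(set_a), set(set_b)
    overlap = len(a & b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValidationError("set larger than universe")
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(b), len(a)))
    return min(max(p, 0.0), 1.0), overlap


@dataclass
class TFPrioritizationRow:
    """One point of the enrichment-vs-expression scatter."""

    motif_id: str
    neglog10_p: float                    # x: motif enrichment
    log2_expression_fold: Optional[float]  # y: mean TF expression, cancer/normal
    significant: bool


def prioritize_tfs(
    enrichments: Sequence[EnrichmentResult],
    tf_expression,
    motif_to_tfs: Mapping[str, Sequence[str]],
    cancer_samples: Sequence[str],
    normal_samples: Sequence[str],
    accessibility_direction: str = "open-in-cancer",
    fold_threshold: float = 1.5,
    pseudocount: float = 0.01,
) -> List[TFPrioritizationRow]:
    """Motif enrichment (x) vs log2 fold of mapped-TF mean expression (y).

    y aggregates mean-of-means: per TF the group mean expression, then the
    mean over the motif's TFs, then log2(cancer/normal). A row is significant
    iff its linear fold is >= fold_threshold (inclusive) in the same
    direction as the accessibility change of the scanned region set. Motifs
    with no mapped TF present in the table get a missing y and a false flag.
    Rows are sorted by x descending.
    """
    if accessibility_direction not in ("open-in-cancer", "open-in-normal"):
        raise ValidationError(f"bad direction {accessibility_direction!r}")
    values = tf_expression.values if hasattr(tf_expression, "values") else tf_expression
    rows = []
    for enr in enrichments:
        tfs = [t for t in motif_to_tfs.get(enr.motif_id, ()) if t in values.index]
        if not tfs:
            rows.append(TFPrioritizationRow(enr.motif_id, enr.neglog10_p, None, False))
            continue
        sub = values.loc[tfs]
        mean_c = float(sub[list(cancer_samples)].mean(axis=1).mean()) + pseudocount
        mean_n = float(sub[list(normal_samples)].mean(axis=1).mean()) + pseudocount
        y = math.log2(mean_c / mean_n)
        linear = mean_c / mean_n
        if accessibility_direction == "open-in-cancer":
            significant = linear >= fold_threshold
        else:
            significant = linear <= 1.0 / fold_threshold
        rows.append(TFPrioritizationRow(enr.motif_id, enr.neglog10_p, y, significant))
    rows.sort(key=lambda r: (-r.neglog10_p, r.motif_id))
    return rows


def prioritization_to_frame(rows: Sequence[TFPrioritizationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in rows],
            "neglog10_p": [r.neglog10_p for r in rows],
            "log2_expression_fold": [
                np.nan if r.log2_expression_fold is None else r.log2_expression_fold
                for r in rows
            ],
            "significant": [r.significant for r in rows],
        }
    )


def percent_of(numerator: int, denominator: int) -> int:
    """Round-half-up integer percentage, e.g. 121/398 -> 30."""
    if denominator == 0:
        raise ValidationError("denominator must be > 0")
    return int(math.floor(100.0 * numerator / denominator + 0.5))
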
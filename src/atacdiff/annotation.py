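"""Genomic-context classification and nearest-gene assignment.

Promoter is +/- 1 kb from a TSS; classification is by region midpoint with
precedence promoter > exonic > intronic > intergenic. Nearest-gene assignment
follows the 100 kb rule: by default a symmetric 100 kb window around each TSS
(nearest TSS wins, lexicographically smallest gene id on ties), with an
upstream-only mode for the stricter reading.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

from .genomics_io import GeneRecord, GenomicInterval, ValidationError

CATEGORIES = ("promoter", "exonic", "intronic", "intergenic")


def classify_region(
    region: GenomicInterval,
    genes: Sequence[GeneRecord],
    promoter_halfwidth: int = 1000,
) -> str:
    """One of promoter/exonic/intronic/intergenic for the region's midpoint.

    Promoter: midpoint within [tss - 1 kb, tss + 1 kb]. Exonic/intronic are
    tested against the transcript span; genes without declared exon structure
    count their whole span as intronic for non-promoter overlaps.
    """
    mid = region.midpoint
    category = "intergenic"
    for gene in genes:
        if gene.chrom != region.chrom:
            continue
        if abs(mid - gene.tss) <= promoter_halfwidth:
            return "promoter"
        if gene.span.contains(region.chrom, mid):
            if gene.exons and any(e.contains(region.chrom, mid) for e in gene.exons):
                category = "exonic"
            elif gene.exons:
                if category != "exonic":
                    category = "intronic"
            else:
                if category != "exonic":
                    category = "intronic"
    return category


def genomic_distribution(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    promoter_halfwidth: int = 1000,
) -> Dict[str, Dict[str, float]]:
    """Category counts and fractions (fractions sum to 1) across regions."""
    if not regions:
        raise ValidationError("no regions")
    counts = {c: 0 for c in CATEGORIES}
    for region in regions:
        counts[classify_region(region, genes, promoter_halfwidth)] += 1
    n = len(regions)
    return {
        "counts": {c: counts[c] for c in CATEGORIES},
        "fractions": {c: counts[c] / n for c in CATEGORIES},
    }


def nearest_gene(
    chrom: str,
    summit: int,
    genes: Sequence[GeneRecord],
    max_distance: int = 100_000,
    mode: str = "symmetric",
) -> Optional[str]:
    """Gene whose TSS is nearest the summit within the distance rule, or None.

    ``symmetric`` (default): candidates are genes with |summit - TSS| <=
    max_distance or with the summit inside the transcript span. ``upstream``:
    the summit must lie within max_distance on the gene's upstream side of
    the TSS (strand-aware), or inside the span. Ties by |distance| break to
    the lexicographically smallest gene id.
    """
    if mode not in ("symmetric", "upstream"):
        raise ValidationError(f"unknown mode {mode!r}")
    best: Optional[tuple] = None
    for gene in genes:
        if gene.chrom != chrom:
            continue
        dist = summit - gene.tss
        in_span = gene.span.contains(chrom, summit)
        if mode == "symmetric":
            ok = abs(dist) <= max_distance or in_span
        else:
            upstream = -dist if gene.strand == "+" else dist
            ok = (0 <= upstream <= max_distance) or in_span
        if not ok:
            continue
        key = (abs(dist), gene.gene_id)
        if best is None or key < best:
            best = key
    return best[1] if best else None


def nearest_gene_map(
    summits: Sequence[tuple],
    genes: Sequence[GeneRecord],
    max_distance: int = 100_000,
    mode: str = "symmetric",
) -> List[Optional[str]]:
    """nearest_gene for a list of (chrom, summit) pairs."""
    return [nearest_gene(c, s, genes, max_distance, mode) for c, s in summits]
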
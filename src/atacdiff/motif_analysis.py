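"""IUPAC consensus motif scanning, GC-matched backgrounds and binomial enrichment.

Scanning uses a 4-bit base encoding so a consensus match is a bitwise AND
over positions; both strands are scanned and a minus-strand hit that has a
plus-strand twin over the same span is suppressed (palindromic consensi such
as the AP1 site TGASTCA would otherwise be double-counted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .genomics_io import GenomicInterval, ValidationError

IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}

#: Motifs the downstream analyses use by default: the AP1 recognition site
#: TGA(G/C)TCA, the ETS core CCGGAA, a degenerate ETS reading CMGGAW, and a
#: GATA-family site included as a non-planted comparator in prioritization.
DEFAULT_MOTIFS: Dict[str, str] = {
    "AP1": "TGASTCA",
    "ETS_core": "CCGGAA",
    "ETS_degenerate": "CMGGAW",
    "GATA": "WGATAR",
}


def _complement_bits(mask: int) -> int:
    return (
        ((mask & 1) << 3) | ((mask & 8) >> 3) | ((mask & 2) << 1) | ((mask & 4) >> 1)
    )


@dataclass(frozen=True)
class MotifModel:
    """An IUPAC consensus motif."""

    motif_id: str
    consensus: str

    def __post_init__(self):
        bad = [c for c in self.consensus.upper() if c not in IUPAC_BITS]
        if bad or not self.consensus:
            raise ValidationError(
                f"motif {self.motif_id}: invalid IUPAC letters {bad!r}"
            )
        object.__setattr__(self, "consensus", self.consensus.upper())

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def masks(self) -> np.ndarray:
        return np.array([IUPAC_BITS[c] for c in self.consensus], dtype=np.uint8)

    @property
    def revcomp_masks(self) -> np.ndarray:
        return np.array(
            [_complement_bits(IUPAC_BITS[c]) for c in reversed(self.consensus)],
            dtype=np.uint8,
        )

    def match_probability(self, gc: float = 0.5) -> float:
        """Per-position single-strand match probability on i.i.d. sequence."""
        p = 1.0
        for c in self.consensus:
            bits = IUPAC_BITS[c]
            prob = 0.0
            for bit, base_p in ((1, (1 - gc) / 2), (2, gc / 2), (4, gc / 2), (8, (1 - gc) / 2)):
                if bits & bit:
                    prob += base_p
            p *= prob
        return p


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    chrom: str
    start: int  # 0-based
    strand: str
    matched: str

    @property
    def centre(self) -> float:
        return self.start + len(self.matched) / 2


_ENC = np.zeros(256, dtype=np.uint8)
for base, bits in (("A", 1), ("C", 2), ("G", 4), ("T", 8)):
    _ENC[ord(base)] = bits
    _ENC[ord(base.lower())] = bits


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string to the 4-bit encoding; N (and anything else) maps to 0."""
    return _ENC[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _match_positions(code: np.ndarray, masks: np.ndarray) -> np.ndarray:
    w = len(masks)
    n = code.size - w + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    ok = (code[:n] & masks[0]) != 0
    for k in range(1, w):
        ok &= (code[k:n + k] & masks[k]) != 0
    return ok


def scan(sequence: str, motif: MotifModel, chrom: str = "seq",
         offset: int = 0) -> List[MotifHit]:
    """Report every position where the consensus matches on either strand.

    N in the sequence never matches. Overlapping hits are all reported. A
    minus-strand match whose span also matches on the plus strand is reported
    once, as a plus-strand hit.
    """
    code = encode_sequence(sequence)
    plus = _match_positions(code, motif.masks)
    minus = _match_positions(code, motif.revcomp_masks)
    hits = []
    w = len(motif)
    for i in np.flatnonzero(plus | minus):
        strand = "+" if plus[i] else "-"
        hits.append(MotifHit(motif.motif_id, chrom, offset + int(i), strand,
                             sequence[i:i + w].upper()))
    return hits


def scan_genome(genome: Dict[str, str], motif: MotifModel) -> List[MotifHit]:
    hits: List[MotifHit] = []
    for chrom in sorted(genome):
        hits.extend(scan(genome[chrom], motif, chrom=chrom))
    return hits


def region_hit_flags(
    regions: Sequence[GenomicInterval],
    genome: Dict[str, str],
    motif: MotifModel,
    window: Optional[int] = None,
    summits: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Flag each region that has >=1 motif hit starting inside it.

    With ``window`` (and per-region ``summits``), the test span is the
    summit-centred window instead of the region itself, clipped to the
    chromosome ("AP1 motif within a 500 bp window of the peak summit").
    """
    if window is not None and summits is None:
        summits = [r.midpoint for r in regions]
    flags = np.zeros(len(regions), dtype=bool)
    for i, region in enumerate(regions):
        seq = genome.get(region.chrom)
        if seq is None or region.end > len(seq):
            raise ValidationError(
                f"region {region.chrom}:{region.start}-{region.end} outside genome"
            )
        if window is None:
            lo, hi = region.start, region.end
        else:
            lo = max(0, summits[i] - window // 2)
            hi = min(len(seq), summits[i] + window // 2)
        # scan wide enough that any hit *starting* in [lo, hi) is seen
        sub = seq[lo:min(len(seq), hi + len(motif) - 1)]
        flags[i] = any(h.start + lo < hi for h in scan(sub, motif))
    return flags


def region_gc(region: GenomicInterval, genome: Dict[str, str]) -> float:
    seq = genome[region.chrom][region.start:region.end]
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def matched_background(
    targets: Sequence[GenomicInterval],
    genome: Dict[str, str],
    n_per_target: int = 10,
    bins: int = 10,
    seed: int = 0,
    max_attempt_factor: int = 400,
) -> List[GenomicInterval]:
    """Sample background regions GC-matched to the targets.

    Regions have the same width distribution as the targets (each background
    region copies a target's width), are sampled uniformly outside the target
    set, and are accepted so the per-GC-bin histogram matches the targets'
    scaled by ``n_per_target``, each bin within +/- ``n_per_target`` regions.
    Deterministic per seed.
    """
    if not targets:
        raise ValidationError("no target regions")
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, 1.0, bins + 1)

    def gc_bin(gc: float) -> int:
        return min(bins - 1, int(np.searchsorted(edges, gc, side="right") - 1))

    required = np.zeros(bins, dtype=int)
    widths_by_bin: Dict[int, List[int]] = {}
    for t in targets:
        b = gc_bin(region_gc(t, genome))
        required[b] += n_per_target
        widths_by_bin.setdefault(b, []).append(len(t))

    target_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for t in targets:
        target_by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    if lengths.sum() <= max(len(t) for t in targets):
        raise ValidationError("genome too small to sample backgrounds from")
    chrom_p = lengths / lengths.sum()
    width_pool = [len(t) for t in targets]

    filled = np.zeros(bins, dtype=int)
    out: List[GenomicInterval] = []
    total_required = int(required.sum())
    attempts = 0
    max_attempts = max_attempt_factor * max(total_required, 1)
    while filled.sum() < total_required and attempts < max_attempts:
        attempts += 1
        ci = rng.choice(len(chroms), p=chrom_p)
        chrom = chroms[ci]
        width = width_pool[rng.integers(len(width_pool))]
        if len(genome[chrom]) <= width:
            continue
        start = int(rng.integers(0, len(genome[chrom]) - width))
        end = start + width
        if any(start < te and ts < end for ts, te in target_by_chrom.get(chrom, ())):
            continue
        cand = GenomicInterval(chrom, start, end)
        b = gc_bin(region_gc(cand, genome))
        if filled[b] < required[b]:
            filled[b] += 1
            out.append(cand)
    short = required - filled
    if short.max() >= n_per_target:
        worst = int(np.argmax(short))
        raise ValidationError(
            f"could not GC-match background: bin [{edges[worst]:.1f},"
            f"{edges[worst + 1]:.1f}) short by {short[worst]} regions"
        )
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    target_hits: int
    target_total: int
    background_fraction: float
    fold_enrichment: float
    p_value: float

    @property
    def neglog10_p(self) -> float:
        return -math.log10(self.p_value)


def enrichment(
    targets: Sequence[GenomicInterval],
    background: Sequence[GenomicInterval],
    genome: Dict[str, str],
    motif: MotifModel,
    window: Optional[int] = None,
    target_summits: Optional[Sequence[int]] = None,
) -> EnrichmentResult:
    """Binomial motif enrichment of targets against a background region set.

    p = upper-tail Binomial(k = targets with >=1 hit; n = target count;
    pi = background fraction with a hit, floored at half a pseudo-hit so the
    p-value stays finite when the background is hit-free).
    """
    if not background:
        raise ValidationError("empty background set")
    if not targets:
        raise ValidationError("empty target set")
    k = int(region_hit_flags(targets, genome, motif, window, target_summits).sum())
    n = len(targets)
    bg_hits = int(region_hit_flags(background, genome, motif).sum())
    pi = max(bg_hits / len(background), 1.0 / (2 * len(background)))
    p = float(stats.binom.sf(k - 1, n, pi))
    p = min(max(p, 5e-324), 1.0)
    fold = (k / n) / pi
    return EnrichmentResult(motif.motif_id, k, n, bg_hits / len(background) if bg_hits else pi, fold, p)


def binomial_tail_bruteforce(k: int, n: int, pi: float) -> float:
    """Independent upper-tail binomial sum for cross-checking small cases."""
    return sum(
        math.comb(n, j) * pi ** j * (1 - pi) ** (n - j) for j in range(k, n + 1)
    )


def motif_density_profile(
    centres: Sequence[Tuple[str, int]],
    genome: Dict[str, str],
    motif: MotifModel,
    half_width: int = 250,
    bin_size: int = 10,
) -> Tuple[np.ndarray, np.ndarray]:
    """Motifs-per-bp around region centres, as in centred motif-density plots.

    Returns (bin centre offsets, density) where density[b] is the number of
    motif hits whose centre falls in bin b, across regions, divided by
    (bin width x region count). The x-axis is symmetric about the centre.
    """
    n_bins = (2 * half_width) // bin_size
    counts = np.zeros(n_bins)
    w = len(motif)
    for chrom, centre in centres:
        seq = genome[chrom]
        lo = max(0, centre - half_width - w)
        hi = min(len(seq), centre + half_width + w)
        for hit in scan(seq[lo:hi], motif, chrom=chrom, offset=lo):
            off = hit.centre - centre
            b = int((off + half_width) // bin_size)
            if 0 <= b < n_bins:
                counts[b] += 1
    offsets = -half_width + bin_size * (np.arange(n_bins) + 0.5)
    if not centres:
        return offsets, counts
    return offsets, counts / (bin_size * len(centres))
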
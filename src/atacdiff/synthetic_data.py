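"""Synthetic ATAC-seq landscape generator with recorded ground truth.

The generator emulates the two-condition ("normal" vs "cancer") design of an
open-chromatin study: a random genome carries planted accessible regions
whose Tn5 cleavage rate differs between conditions by a controlled linear
fold; a subset of the condition-specific regions carries written-in AP1
(TGASTCA) and ETS (CCGGAA) motif instances; occupied instances shape the
cleavage field into a protein-binding footprint (depleted core, elevated
1-5 bp flanks); and an expression table links genes near cancer-open regions
to higher expression in cancer samples and to a simulated dominant-negative
FOS perturbation that knocks their expression down.

Every random draw flows from (config.seed, stream label[, sample id]) so a
config is a complete, reproducible description of a dataset; the
:class:`TruthRecord` is the oracle downstream recovery tests compare against.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomics_io import (
    CleavageTrack,
    ExpressionTable,
    GeneRecord,
    GenomicInterval,
    ValidationError,
)
from .motif_analysis import MotifModel, DEFAULT_MOTIFS

PEAK_CLASSES = ("shared", "cancer_only", "normal_only")
GROUPS = ("normal", "cancer")

# Named TF genes carried in the expression table so motif-vs-expression
# prioritization has real rows to aggregate: AP1 subunits are upregulated in
# cancer, PEA3 family more weakly, GATA family flat.
AP1_TFS = ("FOS", "JUN", "JUNB", "FOSL1")
PEA3_TFS = ("ETV1", "ETV4", "ETV5")
GATA_TFS = ("GATA4", "GATA6")

MOTIF_TO_TFS: Dict[str, Tuple[str, ...]] = {
    "AP1": AP1_TFS,
    "ETS_core": PEA3_TFS,
    "ETS_degenerate": PEA3_TFS,
    "GATA": GATA_TFS,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the standard benchmark: a 2 Mb genome over two
    chromosomes, 125 planted 500 bp accessible regions (50 shared,
    50 cancer-only, 25 normal-only) at an 8-fold accessibility difference,
    ~1e6 cleavage events per sample with 60% of a cancer sample's events in
    peaks, 3 cancer vs 2 normal samples, footprints at 80% core protection,
    and a 4-fold expression link with a 2-fold dominant-negative response.
    """

    genome_length: int = 2_000_000
    n_chroms: int = 2
    gc_content: float = 0.41
    n_peaks: Dict[str, int] = field(
        default_factory=lambda: {"shared": 50, "cancer_only": 50, "normal_only": 25}
    )
    peak_width: int = 500
    accessibility_fold: float = 8.0
    events_per_sample: int = 1_000_000
    peak_signal_fraction: float = 0.6
    footprint_protection: float = 0.8
    flank_boost: float = 0.5
    flank_width: int = 5
    ap1_motif_fraction: float = 0.6
    ets_motif_fraction: float = 0.4
    n_genes: int = 180
    promoter_fraction: float = 0.1
    expression_link_fold: float = 4.0   # 0 disables the accessibility-expression link
    dn_perturbation_fold: float = 2.0
    pea3_tf_fold: float = 2.0
    expression_noise_sd: float = 0.1    # sd of multiplicative exp(N(0, sd)) noise
    baseline_fpkm: float = 20.0
    n_cancer_samples: int = 3
    n_normal_samples: int = 2
    seed: int = 0

    def __post_init__(self):
        if set(self.n_peaks) != set(PEAK_CLASSES):
            raise ValidationError(f"n_peaks must have keys {PEAK_CLASSES}")
        for name in ("genome_length", "n_chroms", "peak_width", "events_per_sample",
                     "n_genes", "n_cancer_samples", "n_normal_samples"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("gc_content", "peak_signal_fraction", "footprint_protection",
                     "ap1_motif_fraction", "ets_motif_fraction", "promoter_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.accessibility_fold < 1.0:
            raise ValidationError("accessibility_fold must be >= 1")
        if any(v < 0 for v in self.n_peaks.values()) or sum(self.n_peaks.values()) == 0:
            raise ValidationError("peak counts must be nonnegative, at least one > 0")

    def total_peaks(self) -> int:
        return sum(self.n_peaks.values())

    def chrom_lengths(self) -> Dict[str, int]:
        per = self.genome_length // self.n_chroms
        return {f"chr{i + 1}": per for i in range(self.n_chroms)}

    def sample_plan(self) -> List[Tuple[str, str]]:
        """(group, sample_id) pairs for the default design."""
        plan = [("cancer", f"cancer_{i + 1}") for i in range(self.n_cancer_samples)]
        plan += [("normal", f"normal_{i + 1}") for i in range(self.n_normal_samples)]
        return plan


@dataclass
class PlantedPeak:
    interval: GenomicInterval
    peak_class: str            # shared | cancer_only | normal_only
    rate_cancer: float         # expected events / bp / sample
    rate_normal: float


@dataclass
class PlantedMotif:
    motif_id: str
    chrom: str
    start: int
    strand: str
    occupied: bool
    peak_index: int
    instance: str


@dataclass
class TruthRecord:
    """The generator's ledger of everything planted; the recovery oracle."""

    seed: int
    config: SimulationConfig
    planted_peaks: List[PlantedPeak] = field(default_factory=list)
    planted_motifs: List[PlantedMotif] = field(default_factory=list)
    genes: List[GeneRecord] = field(default_factory=list)
    gene_peak: Dict[str, int] = field(default_factory=dict)  # gene_id -> peak index
    expression_effects: Dict[str, Tuple[float, float, float]] = field(default_factory=dict)

    def peaks_of_class(self, peak_class: str) -> List[Tuple[int, PlantedPeak]]:
        return [(i, p) for i, p in enumerate(self.planted_peaks)
                if p.peak_class == peak_class]

    def motif_anchors(self, motif_id: str, occupied: bool) -> List[Tuple[str, int, str]]:
        """(chrom, centre, strand) anchors for planted instances of one motif."""
        w = len(DEFAULT_MOTIFS[motif_id])
        return [
            (m.chrom, m.start + w // 2, m.strand)
            for m in self.planted_motifs
            if m.motif_id == motif_id and m.occupied == occupied
        ]

    def ap1_driven_genes(self) -> set:
        """Genes linked to a cancer-open peak bearing an occupied AP1 motif."""
        ap1_peaks = {
            m.peak_index for m in self.planted_motifs
            if m.motif_id == "AP1" and m.occupied
        }
        return {
            g for g, pi in self.gene_peak.items()
            if pi in ap1_peaks and self.planted_peaks[pi].peak_class == "cancer_only"
        }


def _stream(config: SimulationConfig, label: int, extra: Optional[int] = None):
    key = [int(config.seed), label]
    if extra is not None:
        key.append(extra)
    return np.random.default_rng(key)


def generate_genome(config: SimulationConfig) -> Dict[str, str]:
    """I.i.d. random genome at the requested GC content; deterministic per seed."""
    rng = _stream(config, 0)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for chrom, length in config.chrom_lengths().items():
        draw = rng.choice(bases, size=length, p=probs)
        genome[chrom] = draw.tobytes().decode("ascii")
    return genome


def _write_instance(genome: Dict[str, str], chrom: str, start: int, instance: str) -> None:
    seq = genome[chrom]
    genome[chrom] = seq[:start] + instance + seq[start + len(instance):]


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _realize(consensus: str, rng) -> str:
    from .motif_analysis import IUPAC_BITS

    out = []
    for c in consensus:
        bits = IUPAC_BITS[c]
        allowed = [b for b, bit in zip("ACGT", (1, 2, 4, 8)) if bits & bit]
        out.append(allowed[rng.integers(len(allowed))])
    return "".join(out)


def plant_regulatory_landscape(
    genome: Dict[str, str], config: SimulationConfig
) -> Tuple[Dict[str, str], TruthRecord]:
    """Plant peaks, motif instances and genes; returns the edited genome + truth.

    Peaks are placed on a non-overlapping slot grid wide enough that each
    peak's linked gene is unambiguously its nearest gene. Cancer-only peaks
    have cancer:normal cleavage-rate ratio equal to ``accessibility_fold``
    (normal-only peaks the inverse). A fraction of cancer-only peaks receives
    an occupied AP1 instance (and some an occupied ETS instance) written into
    the sequence within 250 bp of the peak centre; shared peaks receive
    unoccupied AP1 instances at the same fraction, so footprint contrasts have
    a matched negative set.
    """
    rng = _stream(config, 1)
    genome = dict(genome)
    truth = TruthRecord(seed=config.seed, config=config)

    max_gene_offset = 4000
    slot = config.peak_width + 2 * max_gene_offset + 2500
    slots: List[Tuple[str, int]] = []  # (chrom, slot start)
    for chrom, length in sorted(config.chrom_lengths().items()):
        for s in range(1000, length - slot, slot):
            slots.append((chrom, s))
    n_tf = len(AP1_TFS) + len(PEA3_TFS) + len(GATA_TFS)
    n_extra_genes = max(0, config.n_genes - config.total_peaks())
    if config.n_genes < config.total_peaks() + n_tf:
        raise ValidationError(
            f"n_genes must be >= total peaks + {n_tf} TF genes "
            f"({config.total_peaks() + n_tf})"
        )
    needed = config.total_peaks() + n_extra_genes
    if needed > len(slots):
        raise ValidationError(
            f"cannot pack {config.total_peaks()} peaks and {n_extra_genes} extra "
            f"genes into {len(slots)} slots; use fewer/narrower peaks or a "
            "longer genome"
        )
    order = rng.permutation(len(slots))
    chosen = [slots[i] for i in order[:needed]]
    peak_slots = chosen[: config.total_peaks()]
    gene_slots = chosen[config.total_peaks():]

    # rates: background soaks up (1 - psf) of a cancer sample's events,
    # peaks the rest; normal-only peaks run at 1/fold in cancer samples
    fold = config.accessibility_fold
    sig_bp = config.peak_width * (
        config.n_peaks["shared"] + config.n_peaks["cancer_only"]
        + config.n_peaks["normal_only"] / fold
    )
    peak_rate = config.peak_signal_fraction * config.events_per_sample / sig_bp

    classes = (
        ["shared"] * config.n_peaks["shared"]
        + ["cancer_only"] * config.n_peaks["cancer_only"]
        + ["normal_only"] * config.n_peaks["normal_only"]
    )
    for (chrom, s), peak_class in zip(peak_slots, classes):
        jitter = int(rng.integers(0, slot - config.peak_width - 2 * max_gene_offset))
        start = s + max_gene_offset + jitter
        iv = GenomicInterval(chrom, start, start + config.peak_width)
        rc = peak_rate if peak_class != "normal_only" else peak_rate / fold
        rn = peak_rate if peak_class != "cancer_only" else peak_rate / fold
        truth.planted_peaks.append(PlantedPeak(iv, peak_class, rc, rn))

    _plant_motifs(genome, truth, config, rng)
    _place_genes(genome, truth, config, rng, gene_slots, max_gene_offset)
    return genome, truth


def _plant_motifs(genome, truth: TruthRecord, config: SimulationConfig, rng) -> None:
    ap1 = MotifModel("AP1", DEFAULT_MOTIFS["AP1"])
    ets = MotifModel("ETS_core", DEFAULT_MOTIFS["ETS_core"])

    def pick(indices: List[int], fraction: float) -> List[int]:
        count = int(round(fraction * len(indices)))
        if count == 0:
            return []
        sel = rng.choice(len(indices), size=count, replace=False)
        return [indices[i] for i in sorted(sel)]

    cancer_idx = [i for i, p in enumerate(truth.planted_peaks)
                  if p.peak_class == "cancer_only"]
    shared_idx = [i for i, p in enumerate(truth.planted_peaks)
                  if p.peak_class == "shared"]

    taken: Dict[int, List[Tuple[int, int]]] = {}

    def place(peak_index: int, motif: MotifModel, occupied: bool, strand_choice: bool):
        peak = truth.planted_peaks[peak_index]
        w = len(motif)
        centre = peak.interval.midpoint
        # keep a +/-75 bp footprint window (plus boosted flanks) inside the
        # accessible region: instances sit within 250 bp of the centre but at
        # least ~100 bp from the peak edge
        half = min(250, max(20, len(peak.interval) // 2 - 100))
        lo = max(peak.interval.start, centre - half)
        hi = min(peak.interval.end, centre + half) - w
        spans = taken.setdefault(peak_index, [])
        for _ in range(50):
            start = int(rng.integers(lo, hi))
            if all(start + w <= a or start >= b for a, b in spans):
                break
        else:  # pragma: no cover - 500 bp peak never this crowded
            return
        instance = _realize(motif.consensus, rng)
        strand = "+"
        if strand_choice and rng.integers(2):
            strand = "-"
            instance_written = _revcomp(instance)
        else:
            instance_written = instance
        _write_instance(genome, peak.interval.chrom, start, instance_written)
        spans.append((start, start + w))
        truth.planted_motifs.append(
            PlantedMotif(motif.motif_id, peak.interval.chrom, start, strand,
                         occupied, peak_index, instance_written)
        )

    # AP1's consensus is strand-symmetric as a set, and the scanner reports
    # such matches on '+': plant it forward so recorded strand == scanned strand.
    for i in pick(cancer_idx, config.ap1_motif_fraction):
        place(i, ap1, occupied=True, strand_choice=False)
    for i in pick(cancer_idx, config.ets_motif_fraction):
        place(i, ets, occupied=True, strand_choice=True)
    for i in pick(shared_idx, config.ap1_motif_fraction):
        place(i, ap1, occupied=False, strand_choice=False)


def _place_genes(genome, truth: TruthRecord, config: SimulationConfig, rng,
                 gene_slots: List[Tuple[str, int]], max_gene_offset: int) -> None:
    sizes = {c: len(s) for c, s in genome.items()}
    n_promoter = int(round(config.promoter_fraction * len(truth.planted_peaks)))
    promoter_peaks = set(
        int(i) for i in rng.choice(len(truth.planted_peaks), size=n_promoter,
                                   replace=False)
    ) if n_promoter else set()

    def make_gene(gene_id: str, chrom: str, tss: int) -> GeneRecord:
        strand = "+" if rng.integers(2) else "-"
        length = int(rng.integers(2000, 8000))
        if strand == "+":
            start, end = tss, min(sizes[chrom], tss + length)
        else:
            start, end = max(0, tss - length + 1), tss + 1
        return GeneRecord(gene_id, chrom, strand, tss, GenomicInterval(chrom, start, end, strand))

    for i, peak in enumerate(truth.planted_peaks):
        centre = peak.interval.midpoint
        if i in promoter_peaks:
            offset = int(rng.integers(-900, 901))
        else:
            mag = int(rng.integers(1500, max_gene_offset + 1))
            offset = mag if rng.integers(2) else -mag
        tss = int(np.clip(centre + offset, 0, sizes[peak.interval.chrom] - 1))
        gene_id = f"G{i + 1:04d}"
        truth.genes.append(make_gene(gene_id, peak.interval.chrom, tss))
        truth.gene_peak[gene_id] = i

    extra_names = list(AP1_TFS + PEA3_TFS + GATA_TFS)
    extra_names += [f"BG{j + 1:04d}"
                    for j in range(len(gene_slots) - len(extra_names))]
    for (chrom, s), name in zip(gene_slots, extra_names):
        tss = s + max_gene_offset + int(rng.integers(0, config.peak_width))
        truth.genes.append(make_gene(name, chrom, tss))


def cleavage_rate_field(truth: TruthRecord, group: str) -> Dict[str, np.ndarray]:
    """Per-bp expected cleavage rates for one condition, footprints applied."""
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
    config = truth.config
    sizes = config.chrom_lengths()
    bg_rate = (
        (1 - config.peak_signal_fraction) * config.events_per_sample
        / config.genome_length
    )
    field_ = {c: np.full(n, bg_rate) for c, n in sizes.items()}
    for peak in truth.planted_peaks:
        rate = peak.rate_cancer if group == "cancer" else peak.rate_normal
        iv = peak.interval
        field_[iv.chrom][iv.start:iv.end] += rate
    for m in truth.planted_motifs:
        if not m.occupied:
            continue
        w = len(m.instance)
        arr = field_[m.chrom]
        arr[m.start:m.start + w] *= 1 - config.footprint_protection
        fw = config.flank_width
        arr[max(0, m.start - fw):m.start] *= 1 + config.flank_boost
        arr[m.start + w:m.start + w + fw] *= 1 + config.flank_boost
    return field_


def simulate_cleavage(
    truth: TruthRecord, group: str, sample_id: str,
    config: Optional[SimulationConfig] = None,
) -> CleavageTrack:
    """Draw one sample's cleavage events from the condition's Poisson field.

    Deterministic given (config.seed, sample_id); different sample ids give
    independent replicate streams.
    """
    config = config or truth.config
    rates = cleavage_rate_field(truth, group)
    rng = _stream(config, 2, zlib.crc32(sample_id.encode()) & 0x7FFFFFFF)
    positions = {}
    for chrom in sorted(rates):
        counts = rng.poisson(rates[chrom])
        positions[chrom] = np.repeat(
            np.arange(counts.size, dtype=np.int64), counts
        )
    return CleavageTrack(sample_id, positions)


def simulate_tracks(truth: TruthRecord) -> Tuple[List[CleavageTrack], Dict[str, str]]:
    """All samples of the default design; returns (tracks, sample_id -> group)."""
    tracks, groups = [], {}
    for group, sample_id in truth.config.sample_plan():
        tracks.append(simulate_cleavage(truth, group, sample_id))
        groups[sample_id] = group
    return tracks, groups


def simulate_expression(
    truth: TruthRecord, config: Optional[SimulationConfig] = None
) -> Tuple[ExpressionTable, ExpressionTable]:
    """FPKM tables for the normal/cancer design and the DN-FOS perturbation.

    Genes whose linked peak is cancer-open are multiplied by the link fold in
    cancer samples (divided for normal-open peaks); genes linked to an
    occupied AP1 motif lose a ``dn_perturbation_fold`` factor in the
    perturbed condition. Multiplicative log-normal noise throughout; every
    effect is recorded in ``truth.expression_effects``.
    """
    config = config or truth.config
    rng = _stream(config, 3)
    link = config.expression_link_fold
    ap1_driven = truth.ap1_driven_genes()

    gene_ids, baselines, cancer_folds, dn_folds = [], [], [], []
    for gene in truth.genes:
        g = gene.gene_id
        baseline = float(config.baseline_fpkm * np.exp(rng.normal(0.0, 0.6)))
        cancer_fold = 1.0
        if link > 0:
            if g in truth.gene_peak:
                cls = truth.planted_peaks[truth.gene_peak[g]].peak_class
                if cls == "cancer_only":
                    cancer_fold = link
                elif cls == "normal_only":
                    cancer_fold = 1.0 / link
            elif g in AP1_TFS:
                cancer_fold = link
            elif g in PEA3_TFS:
                cancer_fold = config.pea3_tf_fold
        dn_fold = config.dn_perturbation_fold if g in ap1_driven else 1.0
        gene_ids.append(g)
        baselines.append(baseline)
        cancer_folds.append(cancer_fold)
        dn_folds.append(dn_fold)
        truth.expression_effects[g] = (baseline, cancer_fold, dn_fold)

    baselines = np.asarray(baselines)
    cancer_folds = np.asarray(cancer_folds)
    dn_folds = np.asarray(dn_folds)
    sd = config.expression_noise_sd

    def noisy(mean: np.ndarray) -> np.ndarray:
        if sd == 0:
            return mean.copy()
        return mean * np.exp(rng.normal(0.0, sd, size=mean.size))

    cols = {}
    for group, sample_id in config.sample_plan():
        mean = baselines * (cancer_folds if group == "cancer" else 1.0)
        cols[sample_id] = noisy(mean)
    fpkm = ExpressionTable(pd.DataFrame(cols, index=gene_ids), unit="FPKM")

    pert_cols = {}
    cancer_mean = baselines * cancer_folds
    for j in range(config.n_cancer_samples):
        pert_cols[f"control_{j + 1}"] = noisy(cancer_mean)
    for j in range(config.n_cancer_samples):
        pert_cols[f"dnfos_{j + 1}"] = noisy(cancer_mean / dn_folds)
    perturb = ExpressionTable(pd.DataFrame(pert_cols, index=gene_ids), unit="FPKM")
    return fpkm, perturb


# ---------------------------------------------------------------------------
# Serialization


def truth_to_dict(truth: TruthRecord) -> dict:
    return {
        "seed": truth.seed,
        "config": dataclasses.asdict(truth.config),
        "planted_peaks": [
            {
                "chrom": p.interval.chrom, "start": p.interval.start,
                "end": p.interval.end, "class": p.peak_class,
                "rate_cancer": p.rate_cancer, "rate_normal": p.rate_normal,
            }
            for p in truth.planted_peaks
        ],
        "planted_motifs": [dataclasses.asdict(m) for m in truth.planted_motifs],
        "genes": [
            {
                "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                "start": g.span.start, "end": g.span.end,
            }
            for g in truth.genes
        ],
        "gene_peak": truth.gene_peak,
        "expression_effects": {
            g: list(v) for g, v in truth.expression_effects.items()
        },
    }


def truth_from_dict(data: dict) -> TruthRecord:
    config = SimulationConfig(**data["config"])
    truth = TruthRecord(seed=data["seed"], config=config)
    for p in data["planted_peaks"]:
        truth.planted_peaks.append(
            PlantedPeak(
                GenomicInterval(p["chrom"], p["start"], p["end"]),
                p["class"], p["rate_cancer"], p["rate_normal"],
            )
        )
    for m in data["planted_motifs"]:
        truth.planted_motifs.append(PlantedMotif(**m))
    for g in data["genes"]:
        span = GenomicInterval(g["chrom"], g["start"], g["end"], g["strand"])
        tss = span.start if g["strand"] == "+" else span.end - 1
        truth.genes.append(GeneRecord(g["gene_id"], g["chrom"], g["strand"], tss, span))
    truth.gene_peak = {k: int(v) for k, v in data["gene_peak"].items()}
    truth.expression_effects = {
        g: tuple(v) for g, v in data["expression_effects"].items()
    }
    return truth


def save_truth(truth: TruthRecord, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth_to_dict(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_truth(path: str) -> TruthRecord:
    with open(path) as fh:
        return truth_from_dict(json.load(fh))


def generate_dataset(config: SimulationConfig):
    """One-call convenience: genome, truth, cleavage tracks and expression."""
    genome = generate_genome(config)
    genome, truth = plant_regulatory_landscape(genome, config)
    tracks, groups = simulate_tracks(truth)
    fpkm, perturb = simulate_expression(truth)
    return genome, truth, tracks, groups, fpkm, perturb
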
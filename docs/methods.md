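# Methods

This note documents the models and procedures implemented in `atacdiff`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that were genuinely
open.

## Coordinates and units

All coordinates are 0-based half-open (BED native) everywhere internally;
1-based dialects must be converted at the I/O boundary. Gene TSS is
`span.start` on `+` and `span.end − 1` on `−`. Cleavage counts are
normalized to events per million library events; heatmap/clustering inputs
are `log2(norm + 1)`. Fragment BED rows contribute their two end positions
(start, end−1) as cleavage events; the ATAC +4/−5 Tn5 shift is assumed
already applied upstream and is only performed when
`read_cleavage_bed(..., apply_tn5_shift=True)` is requested explicitly, to
avoid silent double-shifting.

## Peak calling

A local-λ Poisson sliding-window scan (stride 1). For each window of width
*w* (default 300 bp, q < 0.01), the count is tested against
λ = max(genome-wide rate, 1 kb rate, 10 kb rate) × *w*; the local rates make
the caller robust to broad background variation, the genome-wide floor keeps
empty neighbourhoods from producing spurious calls. p-values are BH-corrected
across all windows jointly; significant overlapping windows merge into peaks.
The summit is the argmax of ±25 bp moving-average-smoothed cleavage within
the merged region (leftmost on ties; the smoothing halfwidth is a small,
documented choice — the raw argmax is noisy at single-base resolution).
Pooled calling ("merge and recall") concatenates the event multisets, so it
is permutation-invariant by construction.

This caller is an implemented equivalent of the external tools normally used
for this step; exact concordance with any specific caller is a non-goal.

## Differential accessibility

Counts are taken over 500 bp summit-centred windows of the top-50,000
peaks by score. The two-group test models raw counts as negative binomial
with a **single** dispersion α shared across regions, estimated by moments:
per region, within-group variance in excess of the Poisson expectation is
pooled as α̂ = Σ(s²_g − μ̂_g·c̄_g) / Σμ̂_g², and the median over regions is
used (robust to regions with real condition structure); α̂ ≤ 0 falls back to
Poisson. The test statistic is a Wald z on log(μ̂_c/μ̂_n) with model-based
variance Var(log μ̂_g) ≈ c̄_g/(μ̂_g n_g) + α/n_g, where c_j = 10⁶/library_j.
Because the variance is model-based (α comes from thousands of regions, not
from 5 samples), the null distribution is close to N(0,1) even at 3-vs-2
designs; the measured type-I error at p < 0.05 on a null landscape is
within a point of nominal (`analysis/08_calibration.py`).

A region is reported when the pseudocounted fold (pseudocount 0.5 on
normalized means, keeping folds finite at zero counts) is > 5 in either
direction **and** p < 0.05 — both strict inequalities, matching the
published wording of the screen. No multiple-testing correction is applied
to this screen itself (the upstream screen was defined on raw p); BH
q-values are emitted alongside as optional output.

## Clustering and PCA

Distance is 1 − Pearson correlation on log2(norm+1); average linkage.
Items with (numerically) constant vectors have undefined correlation; they
are reported and their distances set to 1. Dendrogram leaf order is made
deterministic by putting the subtree with the smaller minimum leaf index on
the left at each merge. PCA is an SVD of region-centred log2 values; each
component's largest-magnitude region loading is made positive so coordinate
signs are reproducible.

## Motif scanning and enrichment

Motifs are IUPAC consensus strings; matching is exact set membership per
position (a 4-bit base encoding makes a match a bitwise AND), with no PWM
scoring. Both strands are scanned; `N` in the sequence never matches; a
minus-strand hit whose span also matches on the plus strand is reported once
as `+` — without this, strand-symmetric consensi such as the AP1 site
TGASTCA would count every occurrence twice. Shipped motifs: AP1 `TGASTCA`,
ETS core `CCGGAA`, a degenerate ETS reading `CMGGAW` (one defensible reading
of the C(C/A)GGA(A/T) family consensus; alternates can be supplied as custom
IUPAC strings), and GATA `WGATAR` as a non-planted comparator.

Backgrounds are sampled uniformly outside the target set, copying target
widths, and accepted per GC bin until each decile holds `n_per_target` ×
(targets in that bin); a shortfall of a full target-equivalent in any bin is
an error naming the worst bin. This matches GC composition only — tools that
normalize CpG dinucleotide content jointly will differ on CpG-island-heavy
target sets. Enrichment is the upper-tail binomial on regions-with-hit, with
the background fraction floored at half a pseudo-hit (1/(2·n_background)) so
hit-free backgrounds give finite p.

## Footprints

Profiles average events per offset in [−F, F) over anchors (default
F = 75 bp), strand-flipping minus-strand motif anchors, per-anchor and
per-million normalized so anchor sets of different sizes and libraries of
different depths overlay directly. The scalar depth
1 − mean(core)/mean(flank) uses |offset| ≤ 3 as core (covering a 7 bp motif)
and 25 ≤ |offset| ≤ 70 as flank; flank mean 0 yields a missing value. No
Tn5 sequence-bias correction is attempted.

## Annotation

Classification is by region midpoint, precedence promoter > exonic >
intronic > intergenic, promoter = TSS ± 1 kb; genes without exon structure
count their whole span as intronic. Nearest-gene assignment defaults to a
symmetric 100 kb window around the TSS (nearest TSS wins; lexicographic
gene id on ties), because upstream-only assignment cannot explain
downstream/intronic region-to-gene annotation; an `upstream` mode implements
the stricter reading.

## Expression

−ΔCT = mean(housekeeping CT) − CT, using the arithmetic mean on the CT
scale, which equals the geometric mean on the expression scale (cycle
thresholds are log₂ expression). Row Z scores use the population SD;
constant rows are zeroed and flagged. The differential-expression screen
(ratio of pseudocounted group means, t-test on log2 values, BH q) is a
declared stand-in for running a full RNA-seq DE tool — it exists so the
pipeline runs end to end on synthetic replicates; real fold-change tables
can be supplied to the downstream filters directly.

## Target chains and prioritization

The high-confidence target chain retains nearest genes of regions in the
required direction with a motif hit within 500 bp of the summit, expression
above 5 FPKM and perturbation fold-reduction above 1.3 — all strict, and
monotone in every cut by construction. The hypergeometric overlap test
requires the caller to supply the universe size explicitly: there is no
defensible default, and the p-value is meaningless without it. In the
prioritization scatter, multiple TFs mapping to one motif aggregate as the
mean over TFs of per-TF group means; the 1.5-fold significance boundary is
inclusive (≥), unlike the strict ">" screens, because the source wording for
this particular rule gives a bare "1.5 fold change".
`percent_of` rounds half up (121/398 → 30).

## The synthetic-data generator

The generator is the package's test bed: an i.i.d. genome (default 2 Mb over
2 chromosomes at GC 0.41, roughly human-like) with 125 planted 500 bp
accessible regions — 50 shared, 50 cancer-only, 25 normal-only — placed on a
non-overlapping slot grid wide enough (≈13 kb) that each region's linked
gene is unambiguously its nearest gene. Cleavage events are drawn per base
from a Poisson field: a uniform background absorbing 40% of a cancer
sample's expected 10⁶ events, peak rates set so that peaks absorb the rest,
and cancer:normal rate ratio 8 in condition-specific peaks. These settings
put condition-specific windows at observed folds ≈7 with thousands of
counts, so the 5-fold screen is attainable with margin rather than at the
boundary. Samples (3 cancer, 2 normal) use independent RNG streams keyed by
(seed, sample id), so replicates are reproducible yet independent.

60% of cancer-only peaks receive an occupied AP1 instance and 40% an
occupied ETS instance (concrete realizations written into the sequence);
shared peaks receive **unoccupied** AP1 instances at the same fraction, so
footprint contrasts have a matched negative set. Occupied instances deplete
the local rate by 80% over the motif core and elevate the five flanking
bases by 50%. Instances are placed within ±150 bp of the peak centre so a
±75 bp profile window plus flanks stays inside the accessible region —
placement at the region edge would mix background into the flank band and
bias the depth statistic. AP1 instances are planted on the plus strand
(its consensus set is strand-symmetric, and the scanner normalizes such
matches to `+`); ETS instances take random strands.

Expression links genes to their nearest planted peak: cancer-open peaks
multiply the gene's log-normal baseline (median 20 FPKM, log-sd 0.6) by 4
in cancer samples, normal-open peaks divide by 4, and genes linked to
occupied AP1 motifs lose a factor 2 in the simulated dominant-negative FOS
condition (3 control vs 3 perturbed replicates), all under multiplicative
exp(N(0, 0.1)) noise. Named TF genes ride along so prioritization has real
rows: AP1 subunits (FOS, JUN, JUNB, FOSL1) up 4-fold in cancer, PEA3
factors (ETV1/4/5) up 2-fold, GATA factors flat. The 4-fold link, 2-fold
perturbation and 0.1 log-noise were chosen once as effect sizes a real
perturbation experiment of this design could detect without being trivial
(a 2-fold reduction is ≈9 noise-SDs above the 1.3-fold cut at 3v3).

**What the generator does not emulate:** mappability, repeats and sequence
composition structure; Tn5 insertion sequence bias; nucleosome positioning;
fragment-length structure (events are drawn directly, not via read pairs);
correlated biological replicate structure; and graded (non-binary) motif
occupancy. Passing recovery tests therefore demonstrates the statistical
machinery is correct and calibrated under its stated model — not that real
ATAC-seq libraries meet that model.

## Benchmark problem sizes

The calibration and recovery benchmarks (`atacdiff.evaluation`, the
acceptance script, `analysis/08`) run at the full default conditions:
5 samples × ~10⁶ events on 2 Mb, 4,000 tiled null windows for type-I error,
75 planted differential regions for sensitivity/FDR, 50 cancer-open regions
(+500 GC-matched backgrounds) for enrichment, 30 occupied / 30 unoccupied
AP1 instances for footprint depth, and 30 planted AP1-driven genes for the
target-chain Jaccard. The unit-test fixture uses a 600 kb / 25-peak /
2×10⁵-event version of the same landscape, which preserves every structural
feature at a fraction of the cost.

## Known limitations

- The NB Wald test needs moderate counts for its normal approximation;
  sparse libraries (window means of a few events) would need an exact or
  quasi-likelihood test.
- The peak caller does not model fragment-length or strand cross-correlation
  evidence, and its 1 kb/10 kb local λ convention, while standard, is not
  tuned to any specific external tool.
- GC matching is marginal (per-region GC deciles), not joint over CpG
  content.
- IUPAC consensus scanning has no affinity model; weak/strong sites are
  indistinguishable.
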
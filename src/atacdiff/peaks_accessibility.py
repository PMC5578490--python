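"""Peak calling, summit-window count matrices, differential accessibility,
clustering and PCA.

The caller is a local-lambda Poisson sliding-window scan (the same idea MACS
popularized): each window is tested against the most conservative of the
genome-wide, 1 kb and 10 kb local rates, BH-corrected across windows, and
significant overlapping windows are merged into peaks. Differential
accessibility between two sample groups uses a negative-binomial Wald test
with a single moment-estimated dispersion pooled across regions (Poisson when
the estimate is <= 0), then the strict ">5-fold and p<0.05" screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genomics_io import (
    CleavageTrack,
    GenomicInterval,
    Peak,
    ValidationError,
)

DIRECTIONS = ("open-in-cancer", "open-in-normal")


# ---------------------------------------------------------------------------
# Peak calling


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _local_rate(cumsum: np.ndarray, centres: np.ndarray, span: int, L: int) -> np.ndarray:
    lo = np.clip(centres - span // 2, 0, L)
    hi = np.clip(centres + span // 2, 0, L)
    return (cumsum[hi] - cumsum[lo]) / np.maximum(hi - lo, 1)


def _smooth_counts(counts: np.ndarray, halfwidth: int = 25) -> np.ndarray:
    width = 2 * halfwidth + 1
    cs = np.concatenate([[0.0], np.cumsum(counts)])
    idx = np.arange(counts.size)
    lo = np.clip(idx - halfwidth, 0, counts.size)
    hi = np.clip(idx + halfwidth + 1, 0, counts.size)
    return (cs[hi] - cs[lo]) / (hi - lo)


def call_peaks(
    track: CleavageTrack,
    chrom_sizes: Dict[str, int],
    window: int = 300,
    qcut: float = 0.01,
    summit_smooth: int = 25,
) -> List[Peak]:
    """Sliding-window Poisson peak caller with local background.

    Per window of ``window`` bp (stride 1): p = upper-tail
    Poisson(count; lambda_local) where lambda_local is the max of the
    genome-wide, 1 kb and 10 kb rates times the window width. Windows with
    BH q < ``qcut`` are merged where they overlap; the summit is the maximum
    of +/-``summit_smooth`` bp smoothed cleavage inside the merged region
    (leftmost on ties) and the score is -log10 q of the summit-centred window.
    """
    if track.library_size == 0:
        raise ValidationError("cannot call peaks on an empty track")
    genome_size = sum(chrom_sizes.values())
    genome_rate = track.library_size / genome_size

    per_chrom = {}
    all_p = []
    for chrom in sorted(chrom_sizes):
        L = chrom_sizes[chrom]
        if L < window:
            continue
        pos = track.positions.get(chrom, np.zeros(0, dtype=np.int64))
        counts = np.bincount(pos, minlength=L).astype(np.float64)
        if counts.size > L:
            raise ValidationError(f"event beyond {chrom} length {L}")
        cs = np.concatenate([[0.0], np.cumsum(counts)])
        starts = np.arange(L - window + 1)
        k = cs[window:] - cs[:-window]
        centres = starts + window // 2
        lam = np.maximum(
            genome_rate,
            np.maximum(
                _local_rate(cs, centres, 1_000, L),
                _local_rate(cs, centres, 10_000, L),
            ),
        ) * window
        p = stats.poisson.sf(k - 1, lam)
        per_chrom[chrom] = (counts, p)
        all_p.append(p)

    if not all_p:
        return []
    q_all = _bh_qvalues(np.concatenate(all_p))
    peaks: List[Peak] = []
    offset = 0
    for chrom in sorted(per_chrom):
        counts, p = per_chrom[chrom]
        q = q_all[offset:offset + p.size]
        offset += p.size
        sig = np.flatnonzero(q < qcut)
        if sig.size == 0:
            continue
        smoothed = _smooth_counts(counts, summit_smooth)
        breaks = np.flatnonzero(np.diff(sig) >= window)
        for run in np.split(sig, breaks + 1):
            rs, re = int(run[0]), int(run[-1]) + window
            summit = rs + int(np.argmax(smoothed[rs:re]))
            wstart = int(np.clip(summit - window // 2, 0, p.size - 1))
            qv = max(float(q[wstart]), 1e-300)
            score = -np.log10(qv)
            peaks.append(Peak(GenomicInterval(chrom, rs, re), summit, score, score))
    return peaks


def pool_and_recall(
    tracks: Sequence[CleavageTrack],
    chrom_sizes: Dict[str, int],
    window: int = 300,
    qcut: float = 0.01,
) -> List[Peak]:
    """Call peaks on the event-union of all tracks (merge-and-recall strategy)."""
    if not tracks:
        raise ValidationError("no tracks to pool")
    chroms = sorted({c for t in tracks for c in t.positions})
    pooled = CleavageTrack(
        "pooled",
        {
            c: np.concatenate(
                [t.positions.get(c, np.zeros(0, dtype=np.int64)) for t in tracks]
            )
            for c in chroms
        },
    )
    return call_peaks(pooled, chrom_sizes, window=window, qcut=qcut)


def top_regions(peaks: Sequence[Peak], n: int) -> List[Peak]:
    """Highest-scoring ``n`` peaks; ties broken by (chrom, start) ascending."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    ranked = sorted(
        peaks, key=lambda p: (-p.score, p.interval.chrom, p.interval.start)
    )
    return ranked[:n]


def summit_windows(
    peaks: Sequence[Peak],
    chrom_sizes: Dict[str, int],
    width: int = 500,
) -> Tuple[List[GenomicInterval], List[bool]]:
    """Fixed windows centred on peak summits, clipped to chromosome bounds.

    Returns (windows, clipped flags); the flag marks windows shorter than
    ``width`` because the summit sat near a chromosome end.
    """
    if width <= 0:
        raise ValidationError("width must be > 0")
    if width % 2:
        raise ValidationError("width must be even")
    windows, clipped = [], []
    for pk in peaks:
        chrom = pk.interval.chrom
        L = chrom_sizes[chrom]
        lo = max(0, pk.summit - width // 2)
        hi = min(L, pk.summit + width // 2)
        windows.append(GenomicInterval(chrom, lo, hi))
        clipped.append(hi - lo < width)
    return windows, clipped


# ---------------------------------------------------------------------------
# Count matrix


@dataclass
class AccessibilityMatrix:
    """Regions x samples cleavage counts over summit windows.

    ``norm_counts`` are counts per million library events, the "normalised
    Tn5 cleavage events" unit used throughout the heatmaps and profiles.
    """

    regions: List[GenomicInterval]
    samples: List[str]
    raw_counts: np.ndarray       # (n_regions, n_samples) ints
    library_sizes: np.ndarray    # per sample

    def __post_init__(self):
        if len(set(self.regions)) != len(self.regions):
            raise ValidationError("duplicate regions in matrix")
        if self.raw_counts.shape != (len(self.regions), len(self.samples)):
            raise ValidationError("count matrix shape mismatch")
        if (self.raw_counts < 0).any():
            raise ValidationError("negative raw counts")

    @property
    def norm_counts(self) -> np.ndarray:
        return self.raw_counts * 1e6 / self.library_sizes[None, :]

    def log_norm(self) -> np.ndarray:
        return np.log2(self.norm_counts + 1.0)

    def to_frame(self, normalized: bool = True) -> pd.DataFrame:
        labels = [f"{r.chrom}:{r.start}-{r.end}" for r in self.regions]
        data = self.norm_counts if normalized else self.raw_counts
        return pd.DataFrame(data, index=labels, columns=self.samples)


def count_matrix(
    windows: Sequence[GenomicInterval], tracks: Sequence[CleavageTrack]
) -> AccessibilityMatrix:
    """Count events whose position falls in [start, end) per window per sample."""
    raw = np.zeros((len(windows), len(tracks)), dtype=np.int64)
    for j, track in enumerate(tracks):
        for i, w in enumerate(windows):
            raw[i, j] = track.count_in(w)
    return AccessibilityMatrix(
        list(windows),
        [t.sample_id for t in tracks],
        raw,
        np.array([t.library_size for t in tracks], dtype=float),
    )


# ---------------------------------------------------------------------------
# Differential accessibility


@dataclass(frozen=True)
class DifferentialRegion:
    region: GenomicInterval
    mean_cancer: float
    mean_normal: float
    fold_change: float     # cancer/normal, pseudocounted
    p_value: float
    direction: str

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"bad direction {self.direction}")


def _pooled_dispersion(norm: np.ndarray, scales: np.ndarray,
                       group_cols: Sequence[np.ndarray]) -> float:
    """Moment estimate of the shared NB dispersion alpha (var = mu*c + alpha*mu^2).

    Per region, within-group variances in excess of the Poisson expectation
    are pooled; the median over regions is robust to the handful of regions
    with real between-condition structure leaking in.
    """
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    any_var = False
    for cols in group_cols:
        if cols.size < 2:
            continue
        any_var = True
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        cbar = scales[cols].mean()
        num += var - mu * cbar
        den += mu ** 2
    if not any_var:
        return 0.0
    ok = den > 0
    if not ok.any():
        return 0.0
    alpha = float(np.median(num[ok] / den[ok]))
    return max(alpha, 0.0)


def differential_table(
    matrix: AccessibilityMatrix,
    groups: Dict[str, str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-region fold change and NB Wald p-value, cancer vs normal.

    ``groups`` maps every sample id to "cancer" or "normal"; each group needs
    at least one sample. Returns a DataFrame with one row per region
    (chrom, start, end, mean_cancer, mean_normal, fold, p, q, direction).
    """
    labels = [groups.get(s) for s in matrix.samples]
    if any(l is None for l in labels):
        missing = [s for s, l in zip(matrix.samples, labels) if l is None]
        raise ValidationError(f"samples without group label: {missing}")
    cancer_cols = np.array([i for i, l in enumerate(labels) if l == "cancer"])
    normal_cols = np.array([i for i, l in enumerate(labels) if l == "normal"])
    if cancer_cols.size == 0 or normal_cols.size == 0:
        raise ValidationError("both groups need >= 1 sample")

    norm = matrix.norm_counts
    scales = 1e6 / matrix.library_sizes
    alpha = _pooled_dispersion(norm, scales, [cancer_cols, normal_cols])

    mu_c = norm[:, cancer_cols].mean(axis=1) + pseudocount
    mu_n = norm[:, normal_cols].mean(axis=1) + pseudocount
    fold = mu_c / mu_n

    var_log_c = scales[cancer_cols].mean() / (mu_c * cancer_cols.size) + alpha / cancer_cols.size
    var_log_n = scales[normal_cols].mean() / (mu_n * normal_cols.size) + alpha / normal_cols.size
    se = np.sqrt(var_log_c + var_log_n)
    z = np.log(fold) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 5e-324, 1.0)

    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in matrix.regions],
            "start": [r.start for r in matrix.regions],
            "end": [r.end for r in matrix.regions],
            "mean_cancer": mu_c - pseudocount,
            "mean_normal": mu_n - pseudocount,
            "fold": fold,
            "p": p,
            "q": _bh_qvalues(p),
            "direction": np.where(fold >= 1.0, DIRECTIONS[0], DIRECTIONS[1]),
        }
    )


def differential_accessibility(
    matrix: AccessibilityMatrix,
    groups: Dict[str, str],
    fold_cut: float = 5.0,
    p_cut: float = 0.05,
    pseudocount: float = 0.5,
) -> List[DifferentialRegion]:
    """Regions passing the strict ">fold_cut-fold and p < p_cut" screen."""
    table = differential_table(matrix, groups, pseudocount=pseudocount)
    out = []
    for i, row in table.iterrows():
        passes_fold = row["fold"] > fold_cut or row["fold"] < 1.0 / fold_cut
        if passes_fold and row["p"] < p_cut:
            out.append(
                DifferentialRegion(
                    matrix.regions[i],
                    float(row["mean_cancer"]),
                    float(row["mean_normal"]),
                    float(row["fold"]),
                    float(row["p"]),
                    str(row["direction"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Clustering and PCA


@dataclass
class ClusterResult:
    labels: List[str]
    order: List[int]            # deterministic leaf order
    linkage: np.ndarray
    constant_items: List[str]   # items whose vector was constant (distance set to 1)


def _correlation_distance(X: np.ndarray, labels: Sequence[str]) -> Tuple[np.ndarray, List[str]]:
    sd = X.std(axis=1)
    tol = 1e-9 * np.maximum(1.0, np.abs(X).max(axis=1))
    constant = [labels[i] for i in np.flatnonzero(sd <= tol)]
    n = X.shape[0]
    D = np.ones((n, n))
    np.fill_diagonal(D, 0.0)
    ok = np.flatnonzero(sd > tol)
    if ok.size >= 2:
        corr = np.corrcoef(X[ok])
        D[np.ix_(ok, ok)] = 1.0 - corr
        np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    return D, constant


def _deterministic_leaf_order(Z: np.ndarray, n: int) -> List[int]:
    """Leaf order with the smaller-minimum-leaf subtree on the left at each merge."""

    def leaves(node: int) -> List[int]:
        if node < n:
            return [node]
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        la, lb = leaves(left), leaves(right)
        if min(la) > min(lb):
            la, lb = lb, la
        return la + lb

    return leaves(2 * n - 2) if n > 1 else [0]


def _cluster(X: np.ndarray, labels: Sequence[str]) -> ClusterResult:
    if X.shape[0] < 2:
        raise ValidationError("need >= 2 items to cluster")
    D, constant = _correlation_distance(X, labels)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    order = _deterministic_leaf_order(Z, X.shape[0])
    return ClusterResult(list(labels), order, Z, constant)


def cluster_samples(matrix: AccessibilityMatrix) -> ClusterResult:
    """Average-linkage clustering of samples with 1 - Pearson correlation
    distance on log2(norm + 1) values."""
    return _cluster(matrix.log_norm().T, matrix.samples)


def cluster_regions(matrix: AccessibilityMatrix) -> ClusterResult:
    labels = [f"{r.chrom}:{r.start}-{r.end}" for r in matrix.regions]
    return _cluster(matrix.log_norm(), labels)


@dataclass
class PCAResult:
    samples: List[str]
    coordinates: np.ndarray       # (n_samples, k)
    variance_fractions: np.ndarray


def pca_samples(matrix: AccessibilityMatrix, k: int = 2) -> PCAResult:
    """PCA of samples over log2(norm + 1), region-centred.

    Sign convention: each component's largest-magnitude region loading is
    made positive, so coordinates are reproducible across runs.
    """
    n = len(matrix.samples)
    if n < 2:
        raise ValidationError("need >= 2 samples")
    if k > n - 1:
        raise ValidationError(f"k={k} exceeds n_samples-1={n - 1}")
    X = matrix.log_norm().T                       # samples x regions
    X = X - X.mean(axis=0, keepdims=True)         # centre each region
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for comp in range(k):
        lead = np.argmax(np.abs(Vt[comp]))
        if Vt[comp, lead] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    coords = U[:, :k] * S[:k]
    total_var = float((S ** 2).sum())
    fractions = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PCAResult(list(matrix.samples), coords, fractions)


# ---------------------------------------------------------------------------
# Output


def differential_regions_to_frame(regions: Sequence[DifferentialRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [d.region.chrom for d in regions],
            "start": [d.region.start for d in regions],
            "end": [d.region.end for d in regions],
            "fold": [d.fold_change for d in regions],
            "p": [d.p_value for d in regions],
            "direction": [d.direction for d in regions],
        }
    )


def write_differential_bed(regions: Sequence[DifferentialRegion], path: str) -> None:
    """BED6+3: name/score/strand placeholders then fold, p, direction."""
    with open(path, "w") as fh:
        for i, d in enumerate(regions):
            fh.write(
                f"{d.region.chrom}\t{d.region.start}\t{d.region.end}\t"
                f"dar_{i + 1}\t0\t.\t{d.fold_change:.5g}\t{d.p_value:.5g}\t"
                f"{d.direction}\n"
            )
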
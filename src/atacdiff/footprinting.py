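"""Aggregate Tn5 cleavage around anchors into footprint/summit profiles.

A bound transcription factor shields its motif from the transposase, so
cleavage dips over the occupied core and piles up at the edges. Profiles are
per-anchor means in counts-per-million units so anchor sets of different
sizes and libraries of different depths are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomics_io import CleavageTrack, ValidationError

Anchor = Tuple[str, int, str]  # (chrom, centre, strand)


@dataclass
class CleavageProfile:
    description: str
    offsets: np.ndarray   # -F .. F-1
    values: np.ndarray    # mean normalized cleavage per position per anchor
    n_anchors: int

    def __post_init__(self):
        if self.n_anchors < 1:
            raise ValidationError("profile needs >= 1 anchor")
        if self.offsets.size != self.values.size:
            raise ValidationError("offsets/values length mismatch")
        if (self.values < 0).any():
            raise ValidationError("negative profile values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.values})


def cleavage_profile(
    track: CleavageTrack,
    anchors: Sequence[Anchor],
    flank: int = 75,
    description: str = "",
) -> CleavageProfile:
    """Mean normalized cleavage at each offset in [-flank, flank) over anchors.

    Minus-strand anchors are reversed so offsets are motif-relative; summit
    anchors should be passed unstranded ("." or "+"). Values are per-offset
    event totals / n_anchors, scaled to events per million library events.
    """
    if not anchors:
        raise ValidationError("no anchors supplied")
    if flank < 1:
        raise ValidationError("flank must be >= 1")
    width = 2 * flank
    totals = np.zeros(width)
    for chrom, centre, strand in anchors:
        arr = track.positions.get(chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr, centre - flank, side="left")
        hi = np.searchsorted(arr, centre + flank, side="left")
        offs = arr[lo:hi] - (centre - flank)      # 0 .. width-1
        if strand == "-":
            offs = width - 1 - offs
        np.add.at(totals, offs, 1.0)
    scale = 1e6 / track.library_size if track.library_size else 0.0
    values = totals / len(anchors) * scale
    return CleavageProfile(
        description or f"{len(anchors)} anchors, flank {flank}",
        np.arange(-flank, flank),
        values,
        len(anchors),
    )


def footprint_depth(
    profile: CleavageProfile,
    core_halfwidth: int,
    flank_band: Tuple[int, int],
) -> Optional[float]:
    """Scalar footprint contrast: 1 - mean(core)/mean(flank), in [-inf, 1].

    Core is |offset| <= core_halfwidth; flank is flank_band[0] <= |offset|
    <= flank_band[1]. A flat profile gives 0, a fully protected core 1.
    Returns None (missing) when the flank mean is 0. Overlapping bands error.
    """
    lo, hi = flank_band
    if lo <= core_halfwidth:
        raise ValidationError("core and flank bands overlap")
    absoff = np.abs(profile.offsets)
    core = profile.values[absoff <= core_halfwidth]
    flank = profile.values[(absoff >= lo) & (absoff <= hi)]
    if core.size == 0 or flank.size == 0:
        raise ValidationError("bands outside profile")
    flank_mean = float(flank.mean())
    if flank_mean == 0.0:
        return None
    return 1.0 - float(core.mean()) / flank_mean


def summit_anchors(intervals, summits: Optional[Sequence[int]] = None) -> List[Anchor]:
    """Unstranded anchors at summits (or midpoints) of regions."""
    if summits is None:
        return [(iv.chrom, iv.midpoint, ".") for iv in intervals]
    return [(iv.chrom, s, ".") for iv, s in zip(intervals, summits)]
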
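"""Expression-side computations: delta-CT normalization, row Z scores, and a
fold/threshold differential-expression screen.

The delta-CT convention: -dCT(g, s) = mean(housekeeping CTs of s) - CT(g, s),
using the arithmetic mean on the CT scale, which is the geometric mean on the
expression scale. -dCT increases with expression. The DE screen is a plainly
labelled stand-in (log2 t-test + BH) for use on synthetic replicates;
fold-change tables from real pipelines can be fed to the downstream filters
directly instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genomics_io import ExpressionTable, ValidationError


@dataclass
class CtTable:
    """qPCR cycle-threshold values (genes x samples) with housekeeping genes."""

    ct: pd.DataFrame
    housekeeping: List[str]

    def __post_init__(self):
        if not self.housekeeping:
            raise ValidationError("housekeeping list must be nonempty")
        missing = [g for g in self.housekeeping if g not in self.ct.index]
        if missing:
            raise ValidationError(f"housekeeping genes absent from table: {missing}")


def delta_ct(table: CtTable) -> ExpressionTable:
    """-dCT values normalized to the housekeeping-gene mean CT per sample.

    Missing CTs propagate as missing; a sample with every housekeeping CT
    missing is an error.
    """
    hk = table.ct.loc[table.housekeeping]
    hk_mean = hk.mean(axis=0, skipna=True)
    dead = hk_mean.index[hk.isna().all(axis=0)]
    if len(dead):
        raise ValidationError(
            f"all housekeeping CTs missing for samples: {list(dead)}"
        )
    neg_dct = hk_mean - table.ct  # broadcast over rows
    return ExpressionTable(neg_dct, unit="-dCT")


def row_zscore(values: pd.DataFrame) -> Tuple[pd.DataFrame, List[str]]:
    """Per-gene standardization (x - row mean) / row SD, population SD.

    Constant rows come back as all zeros and are returned in the flag list.
    """
    mean = values.mean(axis=1, skipna=True)
    sd = values.std(axis=1, ddof=0, skipna=True)
    constant = list(values.index[(sd == 0) | sd.isna()])
    safe_sd = sd.replace(0, np.nan)
    z = values.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return z, constant


def de_screen(
    table: ExpressionTable,
    test_samples: Sequence[str],
    ref_samples: Sequence[str],
    fold_cut: float = 1.5,
    p_cut: Optional[float] = None,
    q_cut: Optional[float] = None,
    fpkm_floor: Optional[float] = None,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Fold/p/q screen of test vs reference samples; strict inequalities.

    fold = ratio of group means (pseudocounted); p = two-group t-test on
    log2 values, q = BH. A gene passes iff every supplied cut is met
    strictly: |linear fold| beyond fold_cut in either direction, p < p_cut,
    q < q_cut, and reference-group mean > fpkm_floor. With fewer than two
    samples in a group, p and q are NaN and only the fold/floor cuts apply.
    """
    for name, samples in (("test", test_samples), ("ref", ref_samples)):
        missing = [s for s in samples if s not in table.values.columns]
        if missing or not samples:
            raise ValidationError(f"{name} group missing samples: {missing or 'all'}")
    test = table.values[list(test_samples)].to_numpy(float)
    ref = table.values[list(ref_samples)].to_numpy(float)
    mean_test = test.mean(axis=1) + pseudocount
    mean_ref = ref.mean(axis=1) + pseudocount
    fold = mean_test / mean_ref

    if test.shape[1] >= 2 and ref.shape[1] >= 2:
        log_test = np.log2(test + pseudocount)
        log_ref = np.log2(ref + pseudocount)
        p = stats.ttest_ind(log_test, log_ref, axis=1).pvalue
        p = np.where(np.isnan(p), 1.0, p)
        order = np.argsort(p, kind="stable")
        m = p.size
        ranked = p[order] * m / np.arange(1, m + 1)
        q = np.empty(m)
        q[order] = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    else:
        p = np.full(fold.size, np.nan)
        q = np.full(fold.size, np.nan)

    passed = (fold > fold_cut) | (fold < 1.0 / fold_cut)
    if p_cut is not None:
        passed &= p < p_cut
    if q_cut is not None:
        passed &= q < q_cut
    if fpkm_floor is not None:
        passed &= (mean_ref - pseudocount) > fpkm_floor
    return pd.DataFrame(
        {"fold": fold, "p": p, "q": q, "passed": passed},
        index=table.values.index,
    )


def group_fold_changes(
    table: ExpressionTable,
    num_samples: Sequence[str],
    den_samples: Sequence[str],
    pseudocount: float = 0.01,
) -> Dict[str, float]:
    """Per-gene ratio of group means (numerator/denominator), pseudocounted."""
    num = table.values[list(num_samples)].mean(axis=1) + pseudocount
    den = table.values[list(den_samples)].mean(axis=1) + pseudocount
    return (num / den).to_dict()
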
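"""Knockout-vs-control differential expression.

Normalization is median-of-ratios (per-sample factor = median across
all-nonzero genes of count / per-gene geometric mean). The test is a Welch
two-sample t-test on log2(normalized count + 1); the module deliberately
keeps the testing machinery simple and also accepts externally computed
(fold, p) tables so the downstream significance/fold filter can be applied
to any upstream engine. The filter itself is: at least ``min_fold``-fold
difference (inclusive) and p strictly below ``max_p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["CountMatrix", "size_factors", "de_test", "de_filter"]


@dataclass
class CountMatrix:
    counts: pd.DataFrame  # genes x samples, non-negative integers
    condition: pd.Series  # sample -> {"control", "knockout"}

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise ValueError("count matrix is empty")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer) and not np.allclose(
            arr, np.round(arr)
        ):
            raise ValueError("counts must be integers")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            raise ValueError("samples without condition label")
        bad = set(self.condition.unique()) - {"control", "knockout"}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")


def size_factors(counts: CountMatrix, rescale: str = "none") -> pd.Series:
    """Median-of-ratios size factors.

    For genes with nonzero counts in every sample, each sample's factor is
    the median of count / (per-gene geometric mean across samples). By
    default the raw factors are returned; ``rescale="median"`` divides by
    the median factor so a majority of unscaled samples sit at 1.0.
    """
    if rescale not in ("none", "median"):
        raise ValueError(f"unknown rescale mode {rescale!r}")
    arr = counts.counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; consider adding a "
            "pseudocount before normalization"
        )
    sub = arr[all_nonzero]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = sub / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    if rescale == "median":
        factors = factors / np.median(factors)
    return pd.Series(factors, index=counts.counts.columns, name="size_factor")


def de_test(counts: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene Welch t-test on log2(normalized + pseudocount).

    log2 fold change is the difference of condition means of the transformed
    values (knockout minus control). Genes with zero variance in both groups
    get p = 1 when the group means agree and the smallest positive p when
    they differ (the t statistic degenerates either way).
    """
    ctrl = counts.condition.index[counts.condition == "control"]
    ko = counts.condition.index[counts.condition == "knockout"]
    if len(ctrl) < 2 or len(ko) < 2:
        raise ValueError("need >= 2 replicates per condition")
    factors = size_factors(counts)
    norm = counts.counts / factors
    logv = np.log2(norm + pseudocount)
    a = logv[ko].to_numpy()
    b = logv[ctrl].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = np.finfo(float).tiny
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {"log2_fold_change": log2fc, "p_value": p}, index=counts.counts.index
    )


def de_filter(
    results: pd.DataFrame,
    min_fold: float = 2.0,
    max_p: float = 0.01,
    adjust: bool = False,
) -> pd.DataFrame:
    """Differential-expression call: |fold| >= min_fold and p < max_p.

    The fold bound is inclusive ("at least min_fold-fold") and applies to
    the fold change in either direction; the p bound is strict. ``adjust``
    switches the p operand to Benjamini-Hochberg adjusted values (off by
    default — the raw-p rule is the primary convention here).
    """
    if min_fold <= 0 or max_p <= 0:
        raise ValueError("thresholds must be positive")
    out = results.copy()
    p = out["p_value"].to_numpy()
    if adjust:
        p = multipletests(p, method="fdr_bh")[1]
        out["p_adjusted"] = p
    out["is_de"] = (np.abs(out["log2_fold_change"]) >= math.log2(min_fold)) & (
        p < max_p
    )
    return out
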
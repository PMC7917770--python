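"""Stage 1 of the screen: target-type-specific dependency selection.

A gene is a susceptibility candidate for the target cancer type when its
knockout depletes the target-type cell lines (strongly negative average
dependency score) while leaving the background panel largely unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DependencyMatrix",
    "mean_scores_by_group",
    "select_susceptibility_candidates",
]


@dataclass
class DependencyMatrix:
    """Gene x cell-line dependency scores with a target/other line grouping.

    Negative scores mean the knockout reduces proliferation in that line.
    Missing observations are carried as NaN and excluded from group means.
    """

    scores: pd.DataFrame  # genes x cell lines
    group: pd.Series  # cell line -> {"target", "other"}

    def __post_init__(self) -> None:
        if self.scores.empty:
            raise ValueError("dependency matrix is empty")
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.scores.columns.duplicated().any():
            raise ValueError("duplicate cell-line ids")
        self.group = self.group.reindex(self.scores.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()].tolist()
            raise ValueError(f"cell lines without group label: {missing[:5]}")
        bad = set(self.group.unique()) - {"target", "other"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for label in ("target", "other"):
            if (self.group == label).sum() == 0:
                raise ValueError(f"group {label!r} has no cell lines")


def mean_scores_by_group(
    dep: DependencyMatrix, summary: str = "mean"
) -> pd.DataFrame:
    """Per-gene average dependency score in each cell-line group.

    Returns a frame indexed by gene with columns ``mean_target``,
    ``mean_other``, ``n_target``, ``n_other`` (counts of non-missing
    observations). ``summary`` may be ``"mean"`` (default) or ``"median"``.
    """
    if summary not in ("mean", "median"):
        raise ValueError(f"unknown summary {summary!r}")
    out = {}
    for label in ("target", "other"):
        cols = dep.group.index[dep.group == label]
        block = dep.scores[cols]
        agg = block.mean(axis=1) if summary == "mean" else block.median(axis=1)
        out[f"mean_{label}"] = agg
        out[f"n_{label}"] = block.notna().sum(axis=1)
    return pd.DataFrame(out, index=dep.scores.index)


def select_susceptibility_candidates(
    means: pd.DataFrame,
    thr_target: float = -0.5,
    thr_other: float = -0.2,
    strict: bool = True,
    min_obs: int = 1,
) -> tuple[set[str], pd.DataFrame]:
    """Dual-threshold selection of target-specific essential genes.

    A gene is selected when its target-group average lies below
    ``thr_target`` while its background-group average stays above
    ``thr_other`` (strict inequalities by default, so boundary genes are
    excluded). Genes with fewer than ``min_obs`` observations in either
    group are ineligible. Returns the selected gene-id set and the full
    flagged table.
    """
    if thr_target >= thr_other:
        raise ValueError(
            f"thr_target ({thr_target}) must be below thr_other ({thr_other}); "
            "the selection region is otherwise empty or inverted"
        )
    eligible = (means["n_target"] >= min_obs) & (means["n_other"] >= min_obs)
    if strict:
        hit = (means["mean_target"] < thr_target) & (means["mean_other"] > thr_other)
    else:
        hit = (means["mean_target"] <= thr_target) & (means["mean_other"] >= thr_other)
    flagged = means.copy()
    flagged["eligible"] = eligible
    flagged["selected"] = np.asarray(eligible & hit)
    return set(flagged.index[flagged["selected"]]), flagged
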
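"""Stage 2 of the screen: tumor-vs-reference expression enrichment.

Candidates from the dependency stage are kept only when they are highly
expressed in the tumor and clearly above the reference tissue: fold change
above a multiple (default 3x) and average tumor TPM above a floor
(default 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "expression_enrichment", "select_overexpressed"]


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM matrix with a tumor/reference sample grouping.

    ``sample_factor`` optionally carries a per-sample latent covariate (used
    by the synthetic survival generator); analyses ignore it.
    """

    tpm: pd.DataFrame
    sample_group: pd.Series  # sample -> {"tumor", "reference"}
    sample_factor: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.tpm.empty:
            raise ValueError("expression matrix is empty")
        if self.tpm.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.tpm.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        self.sample_group = self.sample_group.reindex(self.tpm.columns)
        if self.sample_group.isna().any():
            raise ValueError("samples without group label")
        bad = set(self.sample_group.unique()) - {"tumor", "reference"}
        if bad:
            raise ValueError(f"unknown sample labels: {sorted(bad)}")
        for label in ("tumor", "reference"):
            if (self.sample_group == label).sum() == 0:
                raise ValueError(f"group {label!r} has no samples")


def expression_enrichment(
    expr: ExpressionMatrix,
    pseudocount: float = 1.0,
    summary: str = "mean",
    scale: str = "linear",
) -> pd.DataFrame:
    """Per-gene tumor/reference fold change on the linear TPM scale.

    fold_change = (avg_tumor + pseudocount) / (avg_reference + pseudocount).
    ``summary`` selects mean (default) or median as the group average;
    ``scale="log2"`` instead averages log2(TPM + pseudocount) per group and
    reports 2**(difference), matching tools that work on log-transformed TPM.
    Zero-pseudocount folds with a zero reference mean are reported as +inf
    and flagged non-finite (excluded from downstream ranking).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if summary not in ("mean", "median"):
        raise ValueError(f"unknown summary {summary!r}")
    if scale not in ("linear", "log2"):
        raise ValueError(f"unknown scale {scale!r}")
    avg = lambda df: df.mean(axis=1) if summary == "mean" else df.median(axis=1)
    tumor_cols = expr.sample_group.index[expr.sample_group == "tumor"]
    ref_cols = expr.sample_group.index[expr.sample_group == "reference"]
    mean_tumor = avg(expr.tpm[tumor_cols])
    mean_ref = avg(expr.tpm[ref_cols])
    if scale == "linear":
        with np.errstate(divide="ignore"):
            fold = (mean_tumor + pseudocount).to_numpy() / (
                mean_ref + pseudocount
            ).to_numpy()
    else:
        lt = avg(np.log2(expr.tpm[tumor_cols] + pseudocount))
        lr = avg(np.log2(expr.tpm[ref_cols] + pseudocount))
        fold = np.power(2.0, (lt - lr).to_numpy())
    out = pd.DataFrame(
        {
            "mean_tumor_tpm": mean_tumor,
            "mean_reference_tpm": mean_ref,
            "fold_change": fold,
        },
        index=expr.tpm.index,
    )
    out["finite_fold"] = np.isfinite(out["fold_change"])
    return out


def select_overexpressed(
    enrichment: pd.DataFrame,
    min_fold: float = 3.0,
    min_tumor_tpm: float = 10.0,
) -> tuple[set[str], pd.DataFrame]:
    """Overexpression filter: fold > min_fold and tumor average > min_tumor_tpm.

    Both inequalities are strict. Returns the passing gene-id set and the
    table with a ``selected`` flag. Non-finite folds never pass.
    """
    if min_fold <= 0 or min_tumor_tpm <= 0:
        raise ValueError("thresholds must be positive")
    flagged = enrichment.copy()
    flagged["selected"] = (
        flagged["finite_fold"]
        & (flagged["fold_change"] > min_fold)
        & (flagged["mean_tumor_tpm"] > min_tumor_tpm)
    )
    return set(flagged.index[flagged["selected"]]), flagged
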
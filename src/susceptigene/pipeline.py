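"""End-to-end orchestration of the susceptibility-gene screen.

``run_screen`` chains the three stages as a strictly nested funnel —
dependency selection, then the overexpression filter on the stage-1 passers,
then the survival hazard ranking on the stage-2 passers — and writes a
single per-gene results table plus a JSON run manifest (thresholds, seed,
input checksums, package version) for reproducibility. ``run_integrative``
couples the promoter-signal gene ranking to the knockout expression changes
through preranked GSEA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sgio
from .essentiality import (
    DependencyMatrix,
    mean_scores_by_group,
    select_susceptibility_candidates,
)
from .expression import ExpressionMatrix, expression_enrichment, select_overexpressed
from .survival import SurvivalTable, hazard_screen
from .enrichment import EnrichmentResult, GeneSet, RankedList, gsea_preranked
from .regulatory import promoter_signal_rank

__all__ = ["ScreenThresholds", "ScreenConfig", "screen", "run_screen", "run_integrative"]

logger = logging.getLogger("susceptigene")


@dataclass(frozen=True)
class ScreenThresholds:
    """Stage thresholds of the screen funnel.

    Defaults are the canonical selection rules: dependency below -0.5 in the
    target lines with background above -0.2; overexpression above 3-fold
    with average tumor TPM above 10; survival split at the 25% expression
    quantiles, with final candidates requiring HR > 1 at log-rank p < 0.05.
    """

    thr_target: float = -0.5
    thr_other: float = -0.2
    min_fold: float = 3.0
    min_tpm: float = 10.0
    quantile: float = 0.25
    min_hr: float = 1.0
    max_logrank_p: float = 0.05


@dataclass
class ScreenConfig:
    """File-based configuration for a full screen run."""

    dependency_scores: str
    dependency_groups: str
    expression_tpm: str
    expression_groups: str
    survival_table: str
    output_dir: str
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    seed: int = 0
    nested: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = ScreenThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


def screen(
    dep: DependencyMatrix,
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    thresholds: ScreenThresholds = ScreenThresholds(),
    nested: bool = True,
) -> pd.DataFrame:
    """Run the three-stage screen on in-memory inputs.

    Returns one row per gene of the dependency matrix. In nested mode
    (default, mirroring the funnel design) stage-2 statistics are computed
    only for stage-1 passers and stage-3 only for stage-2 passers; the
    non-nested mode scores every stage on the full universe. The final
    ``candidate`` flag requires stage-1 and stage-2 passes plus
    HR > min_hr at log-rank p < max_logrank_p.
    """
    t = thresholds
    means = mean_scores_by_group(dep)
    stage1, stage1_table = select_susceptibility_candidates(
        means, thr_target=t.thr_target, thr_other=t.thr_other
    )
    result = stage1_table[["mean_target", "mean_other"]].copy()
    result["stage1_pass"] = stage1_table["selected"]
    logger.info("stage 1 (dependency): %d / %d genes", len(stage1), len(result))

    enr = expression_enrichment(expr)
    stage2_universe = sorted(stage1) if nested else list(result.index)
    enr_sub = enr.loc[[g for g in stage2_universe if g in enr.index]]
    stage2, stage2_table = select_overexpressed(
        enr_sub, min_fold=t.min_fold, min_tumor_tpm=t.min_tpm
    )
    for col in ("fold_change", "mean_tumor_tpm"):
        result[col] = stage2_table[col].reindex(result.index)
    result["stage2_pass"] = (
        stage2_table["selected"].astype(bool).reindex(result.index, fill_value=False)
    )
    logger.info("stage 2 (expression): %d / %d genes", len(stage2), len(enr_sub))

    stage3_universe = sorted(stage2) if nested else list(result.index)
    stage3_universe = [g for g in stage3_universe if g in surv.covariates.columns]
    if stage3_universe:
        hz = hazard_screen(surv, stage3_universe, q=t.quantile)
        for col in ("hr", "ci_low", "ci_high", "logrank_p"):
            result[col] = hz[col].reindex(result.index)
        scored = hz[hz["ok"]]
        ranks = scored["hr"].rank(ascending=False, method="first")
        result["stage3_rank"] = ranks.reindex(result.index)
        passed = (
            hz["ok"] & (hz["hr"] > t.min_hr) & (hz["logrank_p"] < t.max_logrank_p)
        )
    else:
        for col in ("hr", "ci_low", "ci_high", "logrank_p", "stage3_rank"):
            result[col] = np.nan
        passed = pd.Series(False, index=result.index)
    result["candidate"] = (
        result["stage1_pass"]
        & result["stage2_pass"]
        & passed.astype(bool).reindex(result.index, fill_value=False)
    )
    n_final = int(result["candidate"].sum())
    logger.info("stage 3 (survival): %d final candidates", n_final)
    # funnel sanity: candidates are always a subset of the stage-2 passers
    assert bool((result["candidate"] <= result["stage2_pass"]).all())
    if nested:
        assert bool((result["stage2_pass"] <= result["stage1_pass"]).all())
    return result


def run_screen(cfg: ScreenConfig) -> pd.DataFrame:
    """File-based screen run: read inputs, screen, write results + manifest."""
    dep = DependencyMatrix(
        scores=sgio.read_matrix_tsv(cfg.dependency_scores),
        group=sgio.read_groups_tsv(cfg.dependency_groups),
    )
    expr = ExpressionMatrix(
        tpm=sgio.read_matrix_tsv(cfg.expression_tpm),
        sample_group=sgio.read_groups_tsv(cfg.expression_groups),
    )
    surv_df = sgio.read_survival_tsv(cfg.survival_table)
    surv = SurvivalTable(
        time=surv_df["time"],
        event=surv_df["event"].astype(int),
        covariates=surv_df.drop(columns=["time", "event"]),
    )
    result = screen(dep, expr, surv, thresholds=cfg.thresholds, nested=cfg.nested)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    out_tsv = outdir / "screen_result.tsv"
    sgio.write_matrix_tsv(result, out_tsv)
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": asdict(cfg.thresholds),
        "nested": cfg.nested,
        "inputs": {
            name: {"path": str(path), "sha256": sgio.sha256_file(path)}
            for name, path in (
                ("dependency_scores", cfg.dependency_scores),
                ("dependency_groups", cfg.dependency_groups),
                ("expression_tpm", cfg.expression_tpm),
                ("expression_groups", cfg.expression_groups),
                ("survival_table", cfg.survival_table),
            )
        },
        "n_candidates": int(result["candidate"].sum()),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result


def run_integrative(
    peaks: pd.DataFrame,
    promoters: pd.DataFrame,
    de_results: pd.DataFrame,
    top_n: int = 200,
    n_perm: int = 1000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Promoter-binding / expression-change coupling analysis.

    Takes the ``top_n`` genes with the highest promoter peak signal as a
    gene set and asks, by preranked GSEA over the knockout log2 fold
    changes, whether that set concentrates among down- (negative ES) or
    up-regulated genes.
    """
    _, top_genes = promoter_signal_rank(peaks, promoters, top_n=top_n)
    ranked = RankedList.from_metric(de_results["log2_fold_change"])
    gene_set = GeneSet(name=f"top{top_n}_promoter_signal", genes=frozenset(top_genes))
    (res,) = gsea_preranked(ranked, [gene_set], n_perm=n_perm, seed=seed)
    return res
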
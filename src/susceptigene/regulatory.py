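"""Peak-centric regulatory analyses for ChIP-seq-style interval data.

All coordinates are 0-based half-open BED intervals; two intervals overlap
when they share at least one base on the same chromosome (strand-agnostic).
Provides promoter/non-promoter peak classification, peak-level Venn overlap
between two peak sets, genomic-feature distribution of peaks versus the
genome background, and the per-gene promoter-signal ranking that feeds the
enrichment analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeakClassification",
    "OverlapSummary",
    "validate_intervals",
    "classify_peaks",
    "overlap_peaksets",
    "genomic_distribution",
    "promoter_signal_rank",
    "promoters_from_tss",
]


@dataclass
class PeakClassification:
    promoter_peaks: pd.DataFrame
    nonpromoter_peaks: pd.DataFrame


@dataclass
class OverlapSummary:
    """Peak-level Venn counts, reported from both perspectives because
    interval overlap is many-to-many."""

    only_a: int
    only_b: int
    shared_a: int  # peaks of A overlapping >= 1 peak of B
    shared_b: int  # peaks of B overlapping >= 1 peak of A


def validate_intervals(df: pd.DataFrame, what: str = "interval") -> None:
    bad = df[(df["start"] >= df["end"]) | (df["start"] < 0)]
    if len(bad):
        rec = bad.iloc[0]
        raise ValueError(
            f"malformed {what}: {rec['chrom']}:{rec['start']}-{rec['end']}"
            + (f" ({rec['name']})" if "name" in bad.columns else "")
        )


def _overlaps_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: overlaps >= 1 bp with any target interval."""
    result = np.zeros(len(query), dtype=bool)
    tgt_by_chrom = {c: g for c, g in targets.groupby("chrom")}
    for chrom, qgrp in query.groupby("chrom"):
        tgt = tgt_by_chrom.get(chrom)
        if tgt is None:
            continue
        starts = tgt["start"].to_numpy()
        ends = tgt["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts = starts[order]
        ends_cummax = np.maximum.accumulate(ends[order])
        # target overlaps query iff target.start < q.end and target.end > q.start
        idx = np.searchsorted(starts, qgrp["end"].to_numpy(), side="left") - 1
        hit = np.zeros(len(qgrp), dtype=bool)
        valid = idx >= 0
        hit[valid] = ends_cummax[idx[valid]] > qgrp["start"].to_numpy()[valid]
        result[query.index.get_indexer(qgrp.index)] = hit
    return result


def classify_peaks(
    peaks: pd.DataFrame, promoters: pd.DataFrame
) -> PeakClassification:
    """Partition peaks into promoter peaks (>= 1 bp overlap with any
    promoter) and non-promoter peaks. The two sets exactly partition the
    input."""
    validate_intervals(peaks, "peak")
    validate_intervals(promoters, "promoter")
    peaks = peaks.reset_index(drop=True)
    is_prom = _overlaps_any(peaks, promoters)
    return PeakClassification(
        promoter_peaks=peaks[is_prom].reset_index(drop=True),
        nonpromoter_peaks=peaks[~is_prom].reset_index(drop=True),
    )


def overlap_peaksets(a: pd.DataFrame, b: pd.DataFrame) -> OverlapSummary:
    """Peak-level Venn overlap of two peak sets (counts from both sides)."""
    validate_intervals(a, "peak (set A)")
    validate_intervals(b, "peak (set B)")
    a = a.reset_index(drop=True)
    b = b.reset_index(drop=True)
    shared_a = int(_overlaps_any(a, b).sum())
    shared_b = int(_overlaps_any(b, a).sum())
    return OverlapSummary(
        only_a=len(a) - shared_a,
        only_b=len(b) - shared_b,
        shared_a=shared_a,
        shared_b=shared_b,
    )


def _merged_length(df: pd.DataFrame) -> int:
    total = 0
    for _, grp in df.groupby("chrom"):
        ivs = grp[["start", "end"]].sort_values("start").to_numpy()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return int(total)


def genomic_distribution(
    peaks: pd.DataFrame,
    annotation: dict[str, pd.DataFrame],
    precedence: tuple[str, ...] = ("promoter", "exon", "intron", "intergenic"),
) -> pd.DataFrame:
    """Fraction of peaks per genomic category versus the genome background.

    Each peak is assigned to the highest-precedence category it overlaps;
    peaks overlapping no annotated interval fall into the lowest-precedence
    category. The background is each category's share of annotated base
    pairs (merged intervals), the expected distribution for random placement.
    """
    if not annotation:
        raise ValueError("empty annotation")
    missing = [c for c in precedence if c not in annotation]
    if set(annotation) - set(precedence):
        raise ValueError(f"categories without precedence: {set(annotation) - set(precedence)}")
    cats = [c for c in precedence if c in annotation]
    validate_intervals(peaks, "peak")
    for c in cats:
        validate_intervals(annotation[c], f"annotation ({c})")
    peaks = peaks.reset_index(drop=True)
    assigned = np.full(len(peaks), cats[-1], dtype=object)
    unassigned = np.ones(len(peaks), dtype=bool)
    for cat in cats:
        if not unassigned.any():
            break
        hit = _overlaps_any(peaks, annotation[cat])
        take = unassigned & hit
        assigned[take] = cat
        unassigned &= ~hit
    n = len(peaks)
    peak_frac = {c: float(np.sum(assigned == c)) / n for c in cats}
    bp = {c: _merged_length(annotation[c]) for c in cats}
    total_bp = sum(bp.values())
    return pd.DataFrame(
        {
            "peak_fraction": [peak_frac[c] for c in cats],
            "genome_fraction": [bp[c] / total_bp for c in cats],
        },
        index=pd.Index(cats, name="category"),
    )


def promoter_signal_rank(
    peaks: pd.DataFrame,
    promoters: pd.DataFrame,
    top_n: int = 200,
    agg: str = "max",
) -> tuple[pd.DataFrame, list[str]]:
    """Rank genes by the signal of peaks overlapping their promoters.

    ``promoters`` must carry the gene id in the ``name`` column. Per gene,
    the signal of all peaks overlapping any of its promoters is aggregated
    (``max`` by default, ``sum`` optional), genes are sorted by descending
    signal with ties broken by gene id, and the top ``top_n`` are returned
    as a gene list alongside the full ranking. Genes whose promoters catch
    no peak are omitted (zero signal).
    """
    if agg not in ("max", "sum"):
        raise ValueError(f"unknown aggregation {agg!r}")
    validate_intervals(peaks, "peak")
    validate_intervals(promoters, "promoter")
    signal: dict[str, float] = {}
    peaks_by_chrom = {c: g for c, g in peaks.groupby("chrom")}
    for _, prom in promoters.iterrows():
        grp = peaks_by_chrom.get(prom["chrom"])
        if grp is None:
            continue
        hit = grp[(grp["start"] < prom["end"]) & (grp["end"] > prom["start"])]
        if hit.empty:
            continue
        val = float(hit["score"].max() if agg == "max" else hit["score"].sum())
        gene = prom["name"]
        if gene in signal:
            signal[gene] = max(signal[gene], val) if agg == "max" else signal[gene] + val
        else:
            signal[gene] = val
    ranking = (
        pd.DataFrame(
            {"gene_id": list(signal), "promoter_signal": list(signal.values())}
        )
        .sort_values(
            ["promoter_signal", "gene_id"], ascending=[False, True], kind="stable"
        )
        .reset_index(drop=True)
    )
    if top_n > len(ranking):
        warnings.warn(
            f"requested top {top_n} genes but only {len(ranking)} carry promoter "
            "signal; returning all",
            stacklevel=2,
        )
    top = ranking["gene_id"].head(top_n).tolist()
    return ranking, top


def promoters_from_tss(
    genes: pd.DataFrame, flank: int = 2000, chrom_sizes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Fallback promoter definition: TSS +/- ``flank`` bp from a gene table
    (BED-style with strand; TSS = start on '+', end on '-')."""
    validate_intervals(genes, "gene")
    tss = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])
    out = genes.copy()
    out["start"] = np.maximum(0, tss - flank)
    out["end"] = tss + flank + 1
    if chrom_sizes:
        caps = out["chrom"].map(chrom_sizes)
        out["end"] = np.minimum(out["end"], caps.fillna(out["end"]).astype(int))
    return out.reset_index(drop=True)
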
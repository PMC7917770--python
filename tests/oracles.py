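"""Independent brute-force oracles used by the test suite.

Every function here is a deliberately naive re-derivation (plain loops,
all-pairs scans, hand-unrolled running sums) of an operation in the package,
kept free of any shared code path with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def group_means_loop(scores: pd.DataFrame, group: pd.Series) -> pd.DataFrame:
    rows = {}
    for gene in scores.index:
        rec = {}
        for label in ("target", "other"):
            vals = [
                scores.at[gene, line]
                for line in scores.columns
                if group[line] == label and not pd.isna(scores.at[gene, line])
            ]
            rec[f"mean_{label}"] = sum(vals) / len(vals) if vals else math.nan
            rec[f"n_{label}"] = len(vals)
        rows[gene] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


def fold_change_loop(
    tpm: pd.DataFrame, sample_group: pd.Series, pseudocount: float
) -> pd.DataFrame:
    rows = {}
    for gene in tpm.index:
        t = [tpm.at[gene, s] for s in tpm.columns if sample_group[s] == "tumor"]
        r = [tpm.at[gene, s] for s in tpm.columns if sample_group[s] == "reference"]
        mt, mr = sum(t) / len(t), sum(r) / len(r)
        denom = mr + pseudocount
        fold = (mt + pseudocount) / denom if denom > 0 else math.inf
        rows[gene] = {
            "mean_tumor_tpm": mt,
            "mean_reference_tpm": mr,
            "fold_change": fold,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def overlaps(a_chrom, a_start, a_end, b_chrom, b_start, b_end) -> bool:
    return a_chrom == b_chrom and a_start < b_end and b_start < a_end


def classify_loop(peaks: pd.DataFrame, promoters: pd.DataFrame):
    """All-pairs promoter/non-promoter partition; returns a boolean list."""
    flags = []
    for _, pk in peaks.iterrows():
        hit = any(
            overlaps(
                pk["chrom"], pk["start"], pk["end"], pr["chrom"], pr["start"], pr["end"]
            )
            for _, pr in promoters.iterrows()
        )
        flags.append(hit)
    return flags


def venn_loop(a: pd.DataFrame, b: pd.DataFrame):
    shared_a = sum(
        any(
            overlaps(x["chrom"], x["start"], x["end"], y["chrom"], y["start"], y["end"])
            for _, y in b.iterrows()
        )
        for _, x in a.iterrows()
    )
    shared_b = sum(
        any(
            overlaps(y["chrom"], y["start"], y["end"], x["chrom"], x["start"], x["end"])
            for _, x in a.iterrows()
        )
        for _, y in b.iterrows()
    )
    return len(a) - shared_a, len(b) - shared_b, shared_a, shared_b


def promoter_rank_loop(peaks: pd.DataFrame, promoters: pd.DataFrame, agg: str = "max"):
    """Aggregate-then-sort oracle: gene -> aggregated promoter peak signal."""
    per_gene: dict[str, float] = {}
    for _, pr in promoters.iterrows():
        vals = [
            pk["score"]
            for _, pk in peaks.iterrows()
            if overlaps(
                pk["chrom"], pk["start"], pk["end"], pr["chrom"], pr["start"], pr["end"]
            )
        ]
        if not vals:
            continue
        v = max(vals) if agg == "max" else sum(vals)
        g = pr["name"]
        if g in per_gene:
            per_gene[g] = max(per_gene[g], v) if agg == "max" else per_gene[g] + v
        else:
            per_gene[g] = v
    return sorted(per_gene.items(), key=lambda kv: (-kv[1], kv[0]))


def size_factors_loop(counts: pd.DataFrame) -> list[float]:
    usable = [
        g for g in counts.index if all(counts.at[g, s] > 0 for s in counts.columns)
    ]
    factors = []
    for s in counts.columns:
        ratios = []
        for g in usable:
            logs = [math.log(counts.at[g, c]) for c in counts.columns]
            geomean = math.exp(sum(logs) / len(logs))
            ratios.append(counts.at[g, s] / geomean)
        ratios.sort()
        m = len(ratios)
        med = ratios[m // 2] if m % 2 else 0.5 * (ratios[m // 2 - 1] + ratios[m // 2])
        factors.append(med)
    return factors


def enrichment_score_loop(genes, metric, members, weight_p: float):
    """Hand-unrolled weighted running sum; returns the signed extremum."""
    hits = [g in members for g in genes]
    n = len(genes)
    n_hit = sum(hits)
    if weight_p == 0:
        w = [1.0] * n
    else:
        w = [abs(m) ** weight_p for m in metric]
    total = sum(wi for wi, h in zip(w, hits) if h)
    running = 0.0
    best = 0.0
    for i in range(n):
        if hits[i]:
            running += w[i] / total
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def km_by_hand(times, events):
    """Product-limit values after each distinct event time."""
    pairs = sorted(zip(times, events))
    distinct = sorted({t for t, e in pairs if e == 1})
    s = 1.0
    out = []
    for et in distinct:
        n_risk = sum(1 for t, _ in pairs if t >= et)
        d = sum(1 for t, e in pairs if t == et and e == 1)
        s *= 1.0 - d / n_risk
        out.append((et, s))
    return out


def logrank_by_hand(times_a, events_a, times_b, events_b):
    all_pairs = [(t, e, "a") for t, e in zip(times_a, events_a)] + [
        (t, e, "b") for t, e in zip(times_b, events_b)
    ]
    distinct = sorted({t for t, e, _ in all_pairs if e == 1})
    u = 0.0
    var = 0.0
    for et in distinct:
        n = sum(1 for t, _, _ in all_pairs if t >= et)
        n_a = sum(1 for t, _, g in all_pairs if t >= et and g == "a")
        d = sum(1 for t, e, _ in all_pairs if t == et and e == 1)
        d_a = sum(1 for t, e, g in all_pairs if t == et and e == 1 and g == "a")
        u += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1)
    return u * u / var if var > 0 else 0.0


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                     size: int = 10_000, max_len: int = 400) -> pd.DataFrame:
    start = rng.integers(0, size - max_len, n)
    length = rng.integers(1, max_len, n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, n),
            "start": start,
            "end": start + length,
            "name": [f"iv{i}" for i in range(n)],
            "score": rng.lognormal(1.0, 1.0, n),
            "strand": ".",
        }
    )
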
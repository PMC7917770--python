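"""Preranked gene-set enrichment from first principles.

The statistic is the classic weighted Kolmogorov-Smirnov-like running sum:
walking down a list of genes ranked by a real-valued metric, gene-set hits
push the sum up by |metric|^p (normalized over the set's hits) and misses
pull it down by 1/(N - N_hits); the enrichment score (ES) is the running-sum
value of maximal absolute deviation from zero. Significance comes from a
gene-label permutation null (random sets of the same size), with the
normalized enrichment score (NES) defined against same-sign null magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RankedList",
    "GeneSet",
    "EnrichmentResult",
    "enrichment_score",
    "gsea_preranked",
]


@dataclass
class RankedList:
    """Genes ordered by a descending ranking metric.

    Construct with :meth:`from_metric` to sort; ties keep the input order
    (stable sort), so the ranking is deterministic.
    """

    genes: list[str]
    metric: np.ndarray

    @classmethod
    def from_metric(cls, metric: pd.Series) -> "RankedList":
        if metric.index.duplicated().any():
            raise ValueError("duplicate genes in ranking metric")
        if not np.all(np.isfinite(metric.to_numpy(dtype=float))):
            raise ValueError("ranking metric must be finite")
        order = np.argsort(-metric.to_numpy(dtype=float), kind="stable")
        return cls(
            genes=[metric.index[i] for i in order],
            metric=metric.to_numpy(dtype=float)[order],
        )

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate genes in ranked list")
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.size:
            raise ValueError("genes and metric differ in length")


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    nominal_p: float
    n_permutations: int
    set_size: int  # members found in the ranked list
    leading_edge: list[str] = field(default_factory=list)
    p_is_bound: bool = False  # True when no same-sign null ES existed


def _running_sum(hit_mask: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Running sum for a 0/1 hit mask over the ranked list."""
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    hit_w = np.abs(weights) * hit_mask
    total = hit_w.sum()
    if total == 0:  # all-zero metric at the hits: fall back to unweighted
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit_mask.astype(bool)).astype(float) / (n - n_hits)
    return np.cumsum(steps)


def _es_from_mask(hit_mask: np.ndarray, weights: np.ndarray) -> float:
    rs = _running_sum(hit_mask, weights)
    i = int(np.argmax(np.abs(rs)))
    return float(rs[i])


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted running-sum enrichment score of one gene set.

    Returns (es, running_sum, leading_edge). The leading edge contains the
    set members up to the ES extremum: the prefix hits for a positive ES,
    the suffix hits for a negative ES. Set members absent from the ranked
    list are dropped with a warning; a set covering the whole list is an
    error (the miss decrement is undefined).
    """
    present = gene_set.genes & set(ranked.genes)
    dropped = len(gene_set.genes) - len(present)
    if dropped:
        warnings.warn(
            f"{gene_set.name}: {dropped} member(s) absent from the ranked list",
            stacklevel=2,
        )
    if not present:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the list")
    if len(present) == len(ranked.genes):
        raise ValueError(
            f"gene set {gene_set.name!r} covers the entire ranked list"
        )
    hit_mask = np.array([g in present for g in ranked.genes])
    weights = np.abs(ranked.metric) ** weight_p if weight_p != 0 else np.ones(
        len(ranked.genes)
    )
    rs = _running_sum(hit_mask, weights)
    peak = int(np.argmax(np.abs(rs)))
    es = float(rs[peak])
    if es >= 0:
        leading = [g for i, g in enumerate(ranked.genes) if i <= peak and hit_mask[i]]
    else:
        leading = [g for i, g in enumerate(ranked.genes) if i >= peak and hit_mask[i]]
    return es, rs, leading


def gsea_preranked(
    ranked: RankedList,
    sets,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[EnrichmentResult]:
    """Permutation-based preranked GSEA over a collection of gene sets.

    The null randomizes set membership (gene-label permutation, sizes
    preserved). For each set: nominal_p = (1 + #{same-sign null with |ES| >=
    |observed|}) / (1 + #{same-sign null}) and NES = ES / mean(|same-sign
    null ES|). When no null ES shares the observed sign, p is reported at
    its resolution bound 1/(n_perm + 1) and flagged.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(ranked.genes)
    weights = np.abs(ranked.metric) ** weight_p if weight_p != 0 else np.ones(n)
    results = []
    null_cache: dict[int, np.ndarray] = {}
    for gene_set in sets:
        es, _, leading = enrichment_score(ranked, gene_set, weight_p=weight_p)
        k = len(gene_set.genes & set(ranked.genes))
        if k not in null_cache:
            null = np.empty(n_perm)
            mask = np.zeros(n, dtype=bool)
            for j in range(n_perm):
                mask[:] = False
                mask[rng.choice(n, size=k, replace=False)] = True
                null[j] = _es_from_mask(mask, weights)
            null_cache[k] = null
        null = null_cache[k]
        same_sign = null >= 0 if es >= 0 else null < 0
        m = int(same_sign.sum())
        if m == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.sign(es) * np.inf if es != 0 else 0.0
            bound = True
        else:
            extreme = int(np.sum(np.abs(null[same_sign]) >= abs(es)))
            p = (1 + extreme) / (1 + m)
            denom = float(np.mean(np.abs(null[same_sign])))
            nes = es / denom if denom > 0 else 0.0
            bound = False
        results.append(
            EnrichmentResult(
                name=gene_set.name,
                es=es,
                nes=float(nes),
                nominal_p=float(p),
                n_permutations=n_perm,
                set_size=k,
                leading_edge=leading,
                p_is_bound=bound,
            )
        )
    return results
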
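"""Seeded generators for every input class of the screen, with planted truth.

The generators emulate the study design of a cancer-type-specific
susceptibility screen: a CRISPR dependency matrix with a small panel of
target-type cell lines against a large background panel, tumor/reference TPM
expression, proportional-hazards survival times driven by an expression risk
group, negative-binomial RNA-seq counts for a knockout-vs-control comparison,
and a toy genome with gene-labelled promoters and signal-bearing peaks.

Every dataset is accompanied by its planted truth so downstream modules can
be scored for sensitivity and false discovery against known ground truth.
Determinism contract: identical :class:`SimConfig` -> bit-identical outputs.
Each generator draws from its own substream of the global seed, so adding a
generator never perturbs the fixtures of another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .essentiality import DependencyMatrix
from .expression import ExpressionMatrix
from .diffexpr import CountMatrix
from .survival import SurvivalTable

__all__ = [
    "SimConfig",
    "planted_screen_config",
    "gene_universe",
    "gen_dependency",
    "gen_expression",
    "gen_survival",
    "gen_counts",
    "gen_genome",
    "tile_annotation",
    "simulate_survival_times",
    "write_truth",
]

# Fixed substream ids: appending new streams never perturbs existing ones.
_STREAMS = {
    "dependency": 0,
    "expression": 1,
    "survival": 2,
    "counts": 3,
    "genome": 4,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design constants and planted truth for all generators.

    The cell-line panel sizes default to the 13-target-line / 345-background
    design of a genome-wide dependency screen; survival defaults give a
    cohort large enough that a planted hazard ratio of ~2.5 is detectable at
    a quartile split.
    """

    seed: int
    n_genes: int = 2000

    # dependency screen
    n_target_lines: int = 13
    n_other_lines: int = 345
    planted_essential: frozenset[str] = frozenset()
    essential_effect: float = -1.0  # mean score shift in target lines
    noise_sd: float = 0.15  # per-observation dependency-score noise

    # expression (TPM)
    n_tumor: int = 300
    n_reference: int = 100
    planted_overexpressed: frozenset[str] = frozenset()
    overexpression_fold: float = 8.0
    expr_log_sd: float = 0.5  # natural-log sd of per-sample TPM noise
    base_tpm_median: float = 5.0  # median baseline TPM across null genes
    base_tpm_log_sd: float = 1.0  # spread of baseline medians (natural log)
    planted_base_tpm: float = 20.0  # reference-group median of planted genes

    # survival
    planted_prognostic: frozenset[str] = frozenset()
    log_hr: float = math.log(2.5)  # true log hazard ratio of the risk group
    # Loading of planted prognostic genes on the latent risk factor. At the
    # default 1.0 the planted genes are perfectly co-ranked with the factor,
    # so each one realizes the configured log-HR exactly between its own
    # expression quartiles; loadings < 1 attenuate the per-gene hazard ratio
    # and are meant for sensitivity analyses.
    prognostic_coexpression: float = 1.0
    n_samples_survival: int = 300
    censoring_rate: float = 0.2
    baseline_hazard: float = 0.005  # events per time unit (day-like scale)

    # counts (knockout vs control)
    planted_de: Mapping[str, float] = field(default_factory=dict)  # gene -> fold
    n_replicates: int = 4
    nb_dispersion: float = 0.1
    base_count_median: float = 100.0
    base_count_log_sd: float = 1.0

    # toy genome
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_200_000, "chr2": 800_000}
    )
    n_promoters: int = 200
    promoter_width: int = 2000
    n_peaks: int = 1000
    peak_width: int = 200
    promoter_overlap_fraction: float = 0.3

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_target_lines": self.n_target_lines,
            "n_other_lines": self.n_other_lines,
            "n_tumor": self.n_tumor,
            "n_reference": self.n_reference,
            "n_samples_survival": self.n_samples_survival,
            "n_replicates": self.n_replicates,
            "n_promoters": self.n_promoters,
            "n_peaks": self.n_peaks,
            "promoter_width": self.promoter_width,
            "peak_width": self.peak_width,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must lie in [0, 1]")
        if not 0.0 <= self.promoter_overlap_fraction <= 1.0:
            raise ValueError("promoter_overlap_fraction must lie in [0, 1]")
        if not 0.0 <= self.prognostic_coexpression <= 1.0:
            raise ValueError("prognostic_coexpression must lie in [0, 1]")
        if self.noise_sd < 0 or self.expr_log_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        universe = set(gene_universe(self))
        for label, planted in (
            ("planted_essential", self.planted_essential),
            ("planted_overexpressed", self.planted_overexpressed),
            ("planted_prognostic", self.planted_prognostic),
            ("planted_de", set(self.planted_de)),
        ):
            extra = set(planted) - universe
            if extra:
                raise ValueError(f"{label} not in gene universe: {sorted(extra)[:5]}")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible substream for one generator."""
        key = _STREAMS[stream]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )


def gene_universe(cfg: SimConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(cfg.n_genes)]


def planted_screen_config(seed: int, n_genes: int = 2000, n_planted: int = 30, **kw) -> SimConfig:
    """Config in which the same genes are planted at every screen stage.

    These genes carry the full signature a true susceptibility gene would:
    target-specific essentiality, tumor overexpression, and prognostic value.
    """
    planted = frozenset(f"G{i:05d}" for i in range(n_planted))
    return SimConfig(
        seed=seed,
        n_genes=n_genes,
        planted_essential=planted,
        planted_overexpressed=planted,
        planted_prognostic=planted,
        **kw,
    )


# Dependency matrix ---------------------------------------------------------


def gen_dependency(cfg: SimConfig) -> DependencyMatrix:
    """Gene x cell-line dependency scores with planted target-specific hits.

    Background scores are Normal(0, noise_sd) for every line; planted
    essential genes have their target-line scores shifted by
    ``essential_effect`` (negative = knockout depletes the target lines).
    """
    rng = cfg.rng("dependency")
    genes = gene_universe(cfg)
    lines = [f"TL{i:03d}" for i in range(cfg.n_target_lines)] + [
        f"OL{i:03d}" for i in range(cfg.n_other_lines)
    ]
    scores = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(lines)))
    planted_idx = [i for i, g in enumerate(genes) if g in cfg.planted_essential]
    scores[planted_idx, : cfg.n_target_lines] += cfg.essential_effect
    group = pd.Series(
        ["target"] * cfg.n_target_lines + ["other"] * cfg.n_other_lines,
        index=lines,
        name="label",
    )
    return DependencyMatrix(
        scores=pd.DataFrame(scores, index=genes, columns=lines), group=group
    )


# Expression ----------------------------------------------------------------


def gen_expression(cfg: SimConfig) -> ExpressionMatrix:
    """Log-normal TPM matrix with planted tumor overexpression.

    Null genes share one baseline between tumor and reference samples;
    planted overexpressed genes have every tumor-sample value multiplied by
    ``overexpression_fold``. Planted prognostic genes additionally load on a
    per-sample latent risk factor (loading ``prognostic_coexpression``),
    emulating a co-regulated prognostic signature; the latent factor is kept
    on the returned matrix so the survival generator can tie hazard to it.
    """
    rng = cfg.rng("expression")
    genes = gene_universe(cfg)
    tumor = [f"T{i:04d}" for i in range(cfg.n_tumor)]
    reference = [f"R{i:04d}" for i in range(cfg.n_reference)]
    samples = tumor + reference
    n_samples = len(samples)

    base = np.exp(
        rng.normal(math.log(cfg.base_tpm_median), cfg.base_tpm_log_sd, size=cfg.n_genes)
    )
    is_planted = np.array([g in cfg.planted_overexpressed for g in genes])
    # planted genes sit in the well-expressed range, with mild spread so no
    # two planted genes share the exact same baseline
    base[is_planted] = cfg.planted_base_tpm * np.exp(
        rng.normal(0.0, 0.25, size=int(is_planted.sum()))
    )

    latent = rng.normal(0.0, 1.0, size=n_samples)
    eps = rng.normal(0.0, 1.0, size=(cfg.n_genes, n_samples))
    lam = cfg.prognostic_coexpression
    is_prog = np.array([g in cfg.planted_prognostic for g in genes])
    z = eps.copy()
    if is_prog.any():
        z[is_prog] = lam * latent[None, :] + math.sqrt(1.0 - lam * lam) * eps[is_prog]

    tpm = base[:, None] * np.exp(cfg.expr_log_sd * z)
    if is_planted.any():
        tpm[np.ix_(is_planted, np.arange(cfg.n_tumor))] *= cfg.overexpression_fold

    group = pd.Series(
        ["tumor"] * cfg.n_tumor + ["reference"] * cfg.n_reference,
        index=samples,
        name="label",
    )
    return ExpressionMatrix(
        tpm=pd.DataFrame(tpm, index=genes, columns=samples),
        sample_group=group,
        sample_factor=pd.Series(latent, index=samples, name="risk_factor"),
    )


# Survival ------------------------------------------------------------------


def simulate_survival_times(
    risk_group: np.ndarray,
    log_hr: float,
    baseline_hazard: float,
    censoring_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with hazard ``baseline * exp(log_hr)`` in the
    risk group, under independent Uniform(0, tau) censoring calibrated so the
    expected censored fraction approximates ``censoring_rate``.

    Returns (observed time, event indicator).
    """
    risk_group = np.asarray(risk_group, dtype=bool)
    n = risk_group.size
    rate = baseline_hazard * np.where(risk_group, math.exp(log_hr), 1.0)
    event_time = rng.exponential(1.0 / rate)
    if censoring_rate <= 0.0:
        return event_time, np.ones(n, dtype=int)
    if censoring_rate >= 1.0:
        raise ValueError("censoring_rate must be < 1 for observable events")
    # P(C < T) for T ~ Exp(lam), C ~ U(0, tau) is (1 - exp(-lam*tau)) / (lam*tau);
    # solve for tau at the cohort's mean hazard.
    lam = float(np.mean(rate))
    f = lambda x: (1.0 - math.exp(-x)) / x - censoring_rate
    x = brentq(f, 1e-9, 1e9)
    tau = x / lam
    censor_time = rng.uniform(0.0, tau, size=n)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return observed, event


def gen_survival(cfg: SimConfig, expression: ExpressionMatrix) -> SurvivalTable:
    """Survival cohort over the tumor samples of ``expression``.

    The hazard is multiplied by ``exp(log_hr)`` for samples in the top
    quartile of the latent risk factor that the planted prognostic genes load
    on, so every planted gene carries (up to its coexpression loading) the
    configured hazard ratio between its own expression quartiles. With no
    planted prognostic genes the cohort is homogeneous.
    """
    tumor = expression.sample_group.index[expression.sample_group == "tumor"]
    if len(tumor) < cfg.n_samples_survival:
        raise ValueError(
            f"expression has {len(tumor)} tumor samples, "
            f"need {cfg.n_samples_survival}"
        )
    missing = set(cfg.planted_prognostic) - set(expression.tpm.index)
    if missing:
        raise ValueError(f"planted prognostic genes absent: {sorted(missing)[:5]}")
    samples = list(tumor[: cfg.n_samples_survival])
    rng = cfg.rng("survival")
    if cfg.planted_prognostic and expression.sample_factor is not None:
        factor = expression.sample_factor.loc[samples].to_numpy()
        risk = factor >= np.quantile(factor, 0.75)
    else:
        risk = np.zeros(len(samples), dtype=bool)
    time, event = simulate_survival_times(
        risk, cfg.log_hr, cfg.baseline_hazard, cfg.censoring_rate, rng
    )
    covariates = expression.tpm[samples].T
    return SurvivalTable(
        time=pd.Series(time, index=samples, name="time"),
        event=pd.Series(event, index=samples, name="event"),
        covariates=covariates,
    )


# Counts --------------------------------------------------------------------


def gen_counts(cfg: SimConfig, noiseless: bool = False) -> CountMatrix:
    """Negative-binomial count matrix for a knockout-vs-control design.

    Per-gene baseline means are log-normal; planted DE genes have their
    knockout-condition mean multiplied by the configured fold (folds < 1
    plant downregulation). ``nb_dispersion`` is the NB dispersion alpha in
    Var = mu + alpha * mu^2; alpha = 0 gives Poisson counts. ``noiseless``
    returns the rounded means themselves (degenerate limit used in tests).
    """
    rng = cfg.rng("counts")
    genes = gene_universe(cfg)
    samples = [f"ctrl_{i + 1}" for i in range(cfg.n_replicates)] + [
        f"ko_{i + 1}" for i in range(cfg.n_replicates)
    ]
    base = np.exp(
        rng.normal(
            math.log(cfg.base_count_median), cfg.base_count_log_sd, size=cfg.n_genes
        )
    )
    if noiseless:
        base = np.round(base)
    fold = np.ones(cfg.n_genes)
    for i, g in enumerate(genes):
        if g in cfg.planted_de:
            fold[i] = cfg.planted_de[g]
            if fold[i] <= 0:
                raise ValueError(f"planted fold for {g} must be positive")
    mu = np.empty((cfg.n_genes, 2 * cfg.n_replicates))
    mu[:, : cfg.n_replicates] = base[:, None]
    mu[:, cfg.n_replicates :] = (base * fold)[:, None]

    if noiseless:
        counts = np.round(mu).astype(int)
    elif cfg.nb_dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / cfg.nb_dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    condition = pd.Series(
        ["control"] * cfg.n_replicates + ["knockout"] * cfg.n_replicates,
        index=samples,
        name="condition",
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples), condition=condition
    )


# Toy genome ----------------------------------------------------------------


def gen_genome(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy genome: non-overlapping gene-labelled promoters and signal peaks.

    Each peak is, with probability ``promoter_overlap_fraction``, placed to
    overlap a random promoter by at least 1 bp; otherwise it is placed so it
    overlaps no promoter. Returns (promoters, peaks) as BED-style frames.
    """
    rng = cfg.rng("genome")
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms])
    slot = 3 * cfg.promoter_width
    slots_per_chrom = sizes // slot
    total_slots = int(slots_per_chrom.sum())
    if total_slots < cfg.n_promoters:
        raise ValueError(
            f"genome too small: {total_slots} promoter slots "
            f"< {cfg.n_promoters} requested"
        )
    chosen = np.sort(rng.choice(total_slots, size=cfg.n_promoters, replace=False))
    bounds = np.cumsum(slots_per_chrom)
    genes = gene_universe(cfg)
    if cfg.n_promoters > cfg.n_genes:
        raise ValueError("more promoters requested than genes in the universe")
    # promoters belong to a random subset of the universe, so promoter
    # ownership is independent of any planted gene set
    owners = sorted(rng.choice(cfg.n_genes, size=cfg.n_promoters, replace=False))
    prom_rows = []
    for k, s in enumerate(chosen):
        ci = int(np.searchsorted(bounds, s, side="right"))
        local = s - (bounds[ci - 1] if ci else 0)
        jitter = int(rng.integers(0, slot - cfg.promoter_width))
        start = int(local * slot + jitter)
        prom_rows.append(
            (chroms[ci], start, start + cfg.promoter_width, genes[owners[k]], 0.0, "+")
        )
    promoters = pd.DataFrame(
        prom_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    by_chrom = {c: g[["start", "end"]].to_numpy() for c, g in promoters.groupby("chrom")}
    in_promoter = rng.random(cfg.n_peaks) < cfg.promoter_overlap_fraction
    signal = np.exp(rng.normal(math.log(5.0), 1.0, size=cfg.n_peaks))
    peak_rows = []
    for j in range(cfg.n_peaks):
        if in_promoter[j]:
            p = promoters.iloc[int(rng.integers(0, cfg.n_promoters))]
            lo = max(0, p["start"] - cfg.peak_width + 1)
            hi = min(cfg.chrom_sizes[p["chrom"]] - cfg.peak_width, p["end"] - 1)
            start = int(rng.integers(lo, hi + 1))
            chrom = p["chrom"]
        else:
            for _ in range(1000):
                ci = int(rng.integers(0, len(chroms)))
                chrom = chroms[ci]
                start = int(rng.integers(0, cfg.chrom_sizes[chrom] - cfg.peak_width))
                ivs = by_chrom.get(chrom)
                if ivs is None or not np.any(
                    (ivs[:, 0] < start + cfg.peak_width) & (ivs[:, 1] > start)
                ):
                    break
            else:
                raise ValueError("genome too dense to place a non-promoter peak")
        peak_rows.append(
            (chrom, start, start + cfg.peak_width, f"peak_{j:05d}", signal[j], ".")
        )
    peaks = pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    order = np.lexsort((peaks["start"].to_numpy(), peaks["chrom"].to_numpy()))
    return promoters.sort_values(["chrom", "start"], ignore_index=True), peaks.iloc[
        order
    ].reset_index(drop=True)


def tile_annotation(
    chrom_sizes: Mapping[str, int],
    fractions: Mapping[str, float],
    tile: int = 1000,
) -> dict[str, pd.DataFrame]:
    """Deterministic disjoint annotation covering the genome.

    Tiles each chromosome and assigns tiles to categories cyclically in
    proportion to ``fractions`` (which must sum to 1). Useful as the
    annotation input of the genomic-distribution analysis.
    """
    cats = list(fractions)
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    cuts = np.cumsum([fractions[c] for c in cats])
    rows: dict[str, list] = {c: [] for c in cats}
    for chrom, size in chrom_sizes.items():
        n_tiles = size // tile
        for t in range(n_tiles):
            u = (t % 100 + 0.5) / 100.0  # deterministic cycle through categories
            cat = cats[int(np.searchsorted(cuts, u))]
            rows[cat].append((chrom, t * tile, (t + 1) * tile, ".", 0.0, "."))
    return {
        c: pd.DataFrame(r, columns=["chrom", "start", "end", "name", "score", "strand"])
        for c, r in rows.items()
    }


# Truth sidecar -------------------------------------------------------------


def write_truth(cfg: SimConfig, path: str | Path) -> None:
    truth = {
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "planted_essential": sorted(cfg.planted_essential),
        "essential_effect": cfg.essential_effect,
        "planted_overexpressed": sorted(cfg.planted_overexpressed),
        "overexpression_fold": cfg.overexpression_fold,
        "planted_prognostic": sorted(cfg.planted_prognostic),
        "log_hr": cfg.log_hr,
        "planted_de": dict(sorted(cfg.planted_de.items())),
    }
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Same study design, different random seed."""
    return replace(cfg, seed=seed)
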
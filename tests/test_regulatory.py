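"""Interval analyses: classification, Venn overlap, distribution, ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from susceptigene import synthdata as sd
from susceptigene.regulatory import (
    classify_peaks,
    genomic_distribution,
    overlap_peaksets,
    promoter_signal_rank,
    promoters_from_tss,
)
from oracles import classify_loop, promoter_rank_loop, random_intervals, venn_loop


def iv(chrom, start, end, name="x", score=1.0):
    return pd.DataFrame(
        [(chrom, start, end, name, score, ".")],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


def test_overlap_conventions():
    peak = iv("chr1", 100, 200)
    assert len(classify_peaks(peak, iv("chr1", 150, 250)).promoter_peaks) == 1
    # half-open abutment is not overlap
    assert len(classify_peaks(peak, iv("chr1", 200, 300)).promoter_peaks) == 0
    # same coordinates, different chromosome
    assert len(classify_peaks(peak, iv("chr2", 100, 200)).promoter_peaks) == 0


def test_malformed_interval_names_the_record():
    with pytest.raises(ValueError, match="bad_peak"):
        classify_peaks(iv("chr1", 200, 100, name="bad_peak"), iv("chr1", 0, 10))


def test_classification_is_exact_partition_and_matches_bruteforce(rng):
    for _ in range(5):
        peaks = random_intervals(rng, 300)
        promoters = random_intervals(rng, 60)
        cls = classify_peaks(peaks, promoters)
        assert len(cls.promoter_peaks) + len(cls.nonpromoter_peaks) == len(peaks)
        got = set(cls.promoter_peaks["name"])
        expected = {
            n for n, f in zip(peaks["name"], classify_loop(peaks, promoters)) if f
        }
        assert got == expected


def test_classification_invariant_under_input_order(rng):
    peaks = random_intervals(rng, 100)
    promoters = random_intervals(rng, 30)
    a = classify_peaks(peaks, promoters)
    b = classify_peaks(peaks.sample(frac=1, random_state=1), promoters)
    assert set(a.promoter_peaks["name"]) == set(b.promoter_peaks["name"])


def test_venn_identity_and_disjoint():
    peaks = random_intervals(np.random.default_rng(0), 50)
    s = overlap_peaksets(peaks, peaks)
    assert s.shared_a == len(peaks) and s.only_a == 0
    moved = peaks.assign(chrom="chrX")
    s2 = overlap_peaksets(peaks, moved)
    assert s2.shared_a == 0 and s2.only_b == len(moved)


def test_venn_matches_bruteforce_and_is_symmetric(rng):
    for _ in range(5):
        a = random_intervals(rng, 120)
        b = random_intervals(rng, 80)
        mine = overlap_peaksets(a, b)
        only_a, only_b, shared_a, shared_b = venn_loop(a, b)
        assert (mine.only_a, mine.only_b, mine.shared_a, mine.shared_b) == (
            only_a, only_b, shared_a, shared_b,
        )
        flipped = overlap_peaksets(b, a)
        assert flipped.shared_a == mine.shared_b and flipped.shared_b == mine.shared_a


def test_distribution_all_promoter_peaks():
    ann = {
        "promoter": iv("chr1", 0, 1000),
        "intergenic": iv("chr1", 1000, 10_000),
    }
    peaks = pd.concat([iv("chr1", 10, 60), iv("chr1", 500, 700)], ignore_index=True)
    dist = genomic_distribution(peaks, ann, precedence=("promoter", "intergenic"))
    assert dist.at["promoter", "peak_fraction"] == 1.0
    assert dist["peak_fraction"].sum() == pytest.approx(1.0, abs=1e-12)
    assert dist["genome_fraction"].sum() == pytest.approx(1.0, abs=1e-12)


def test_distribution_random_placement_matches_background(rng):
    sizes = {"chr1": 200_000}
    ann = sd.tile_annotation(
        sizes, {"promoter": 0.1, "exon": 0.2, "intron": 0.3, "intergenic": 0.4}
    )
    n = 2000
    starts = rng.integers(0, sizes["chr1"] - 1, n)
    peaks = pd.DataFrame(
        {
            "chrom": "chr1", "start": starts, "end": starts + 1,
            "name": [f"p{i}" for i in range(n)], "score": 1.0, "strand": ".",
        }
    )
    dist = genomic_distribution(peaks, ann)
    for cat in dist.index:
        bg = dist.at[cat, "genome_fraction"]
        lo, hi = stats.binom.interval(0.999, n, bg)
        assert lo / n <= dist.at[cat, "peak_fraction"] <= hi / n


def test_promoter_rank_top_gene_and_full_return(rng):
    promoters = pd.concat(
        [iv("chr1", 0, 100, "gA"), iv("chr1", 1000, 1100, "gB")], ignore_index=True
    )
    peaks = pd.concat(
        [iv("chr1", 50, 80, "p1", score=9.0), iv("chr1", 1050, 1080, "p2", score=2.0)],
        ignore_index=True,
    )
    ranking, top = promoter_signal_rank(peaks, promoters, top_n=1)
    assert top == ["gA"] and ranking.iloc[0]["promoter_signal"] == 9.0
    with pytest.warns(UserWarning, match="only"):
        _, everything = promoter_signal_rank(peaks, promoters, top_n=10)
    assert set(everything) == {"gA", "gB"}


def test_promoter_rank_matches_bruteforce(rng):
    for agg in ("max", "sum"):
        for _ in range(5):
            peaks = random_intervals(rng, 150)
            promoters = random_intervals(rng, 40)
            promoters["name"] = [f"gene{i % 25}" for i in range(40)]
            ranking, _ = promoter_signal_rank(peaks, promoters, top_n=5, agg=agg)
            oracle = promoter_rank_loop(peaks, promoters, agg=agg)
            assert list(ranking["gene_id"]) == [g for g, _ in oracle]
            assert np.allclose(ranking["promoter_signal"], [v for _, v in oracle])


def test_promoters_from_tss_respects_strand():
    genes = pd.concat(
        [iv("chr1", 5000, 9000, "plus"), iv("chr1", 20_000, 24_000, "minus")],
        ignore_index=True,
    )
    genes.loc[1, "strand"] = "-"
    prom = promoters_from_tss(genes, flank=2000)
    plus = prom[prom["name"] == "plus"].iloc[0]
    minus = prom[prom["name"] == "minus"].iloc[0]
    assert (plus["start"], plus["end"]) == (3000, 7001)
    assert (minus["start"], minus["end"]) == (21_999, 26_000)
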
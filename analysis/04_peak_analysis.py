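#!/usr/bin/env python
"""Peak-centric regulatory analyses on the toy genome.

Classifies binding peaks into promoter and non-promoter peaks, compares two
independent peak sets (a second simulated "replicate cell line") as a
peak-level Venn, and tabulates the genomic distribution of peaks against the
genome background.
"""

import argparse
import json
from dataclasses import replace
from pathlib import Path

from susceptigene import io as sgio
from susceptigene import synthdata as sd
from susceptigene.regulatory import (
    classify_peaks,
    genomic_distribution,
    overlap_peaksets,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/peaks"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    promoters = sgio.read_bed(args.datadir / "promoters.bed")
    peaks = sgio.read_bed(args.datadir / "peaks.bed")

    cls = classify_peaks(peaks, promoters)
    sgio.write_bed(cls.promoter_peaks, args.outdir / "promoter_peaks.bed")
    sgio.write_bed(cls.nonpromoter_peaks, args.outdir / "nonpromoter_peaks.bed")
    print(f"{len(cls.promoter_peaks)} promoter / {len(cls.nonpromoter_peaks)} "
          f"non-promoter peaks (of {len(peaks)})")

    # a second, independent peak set standing in for another cell line
    cfg2 = replace(
        sd.planted_screen_config(args.seed + 500, n_genes=2000, n_planted=30),
        n_peaks=1000, promoter_overlap_fraction=0.3,
    )
    _, peaks2 = sd.gen_genome(cfg2)
    venn = overlap_peaksets(peaks, peaks2)
    print(f"Venn vs replicate set: only_a={venn.only_a}, shared_a={venn.shared_a}, "
          f"only_b={venn.only_b}, shared_b={venn.shared_b}")

    sizes = dict(sd.SimConfig(seed=args.seed, n_genes=10).chrom_sizes)
    ann = sd.tile_annotation(
        sizes, {"promoter": 0.1, "exon": 0.25, "intron": 0.35, "intergenic": 0.3}
    )
    dist = genomic_distribution(peaks, ann)
    dist.to_csv(args.outdir / "genomic_distribution.tsv", sep="\t",
                float_format="%.6g")
    print("genomic distribution (peak vs genome fraction):")
    print(dist.to_string())

    (args.outdir / "venn.json").write_text(json.dumps(vars(venn), indent=2) + "\n")


if __name__ == "__main__":
    main()
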
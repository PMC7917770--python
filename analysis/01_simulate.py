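#!/usr/bin/env python
"""Generate the synthetic study datasets for the downstream analyses.

Emulates the full study design: a dependency screen over 2,000 genes
(13 target-type vs 345 background cell lines), tumor/reference TPM
expression, a 300-sample survival cohort, knockout-vs-control RNA-seq
counts, and a toy genome with promoters and binding peaks. Thirty genes
carry the full susceptibility signature (essentiality effect -1.0, 8-fold
overexpression, hazard ratio 2.5); sixty genes are planted as knockout-
responsive (half up, half down, 8-fold). All planted truth goes to a JSON
sidecar so later steps can score themselves.
"""

import argparse
from pathlib import Path

import pandas as pd

from susceptigene import io as sgio
from susceptigene import synthdata as sd


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    de_truth = {f"G{i:05d}": (8.0 if i % 2 else 0.125) for i in range(100, 160)}
    cfg = sd.planted_screen_config(
        args.seed, n_genes=2000, n_planted=30, planted_de=de_truth,
        n_peaks=1000, promoter_overlap_fraction=0.3,
    )

    dep = sd.gen_dependency(cfg)
    sgio.write_matrix_tsv(dep.scores, args.outdir / "dependency_scores.tsv")
    sgio.write_groups_tsv(dep.group, args.outdir / "dependency_groups.tsv",
                          id_name="cell_line_id")

    expr = sd.gen_expression(cfg)
    sgio.write_matrix_tsv(expr.tpm, args.outdir / "expression_tpm.tsv")
    sgio.write_groups_tsv(expr.sample_group, args.outdir / "expression_groups.tsv")

    surv = sd.gen_survival(cfg, expr)
    surv_df = pd.concat([surv.time, surv.event, surv.covariates], axis=1)
    sgio.write_survival_tsv(surv_df, args.outdir / "survival.tsv")

    counts = sd.gen_counts(cfg)
    sgio.write_matrix_tsv(counts.counts, args.outdir / "ko_counts.tsv")
    sgio.write_groups_tsv(counts.condition, args.outdir / "ko_conditions.tsv")

    promoters, peaks = sd.gen_genome(cfg)
    sgio.write_bed(promoters, args.outdir / "promoters.bed")
    sgio.write_bed(peaks, args.outdir / "peaks.bed")

    sd.write_truth(cfg, args.outdir / "truth.json")
    print(f"wrote dependency ({dep.scores.shape}), expression ({expr.tpm.shape}), "
          f"survival (n={len(surv.time)}), counts ({counts.counts.shape}), "
          f"{len(promoters)} promoters, {len(peaks)} peaks -> {args.outdir}")


if __name__ == "__main__":
    main()
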
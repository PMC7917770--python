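#!/usr/bin/env python
"""Kaplan-Meier stratification of the top screen candidate.

Splits the cohort at the candidate's expression quartiles (and, for
comparison, at the median), estimates both survival curves, and reports the
log-rank separation and Cox hazard ratio. Writes the curve coordinates as
TSV and, when matplotlib is available, a two-curve KM plot.
"""

import argparse
from pathlib import Path

import pandas as pd

from susceptigene import io as sgio
from susceptigene.survival import (
    SurvivalTable,
    cox_hr,
    km_estimate,
    logrank_test,
    stratify_by_quantile,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--screendir", type=Path, default=Path("results/screen"))
    ap.add_argument("--outdir", type=Path, default=Path("results/survival"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    screen = pd.read_csv(args.screendir / "screen_result.tsv", sep="\t").set_index("gene_id")
    gene = screen[screen["candidate"]].sort_values("hr", ascending=False).index[0]

    df = sgio.read_survival_tsv(args.datadir / "survival.tsv")
    surv = SurvivalTable(time=df["time"], event=df["event"].astype(int),
                        covariates=df.drop(columns=["time", "event"]))

    for label, q in (("quartile", 0.25), ("median", 0.5)):
        groups = stratify_by_quantile(surv.covariates[gene], q=q)
        high, low = surv.subset(groups.high), surv.subset(groups.low)
        chi2, p = logrank_test(high, low)
        members = groups.high + groups.low
        indicator = pd.Series([1] * len(groups.high) + [0] * len(groups.low),
                              index=members)
        hr = cox_hr(surv.subset(members), indicator, gene_id=gene)
        print(f"{gene} ({label} split): HR={hr.hr:.2f}, "
              f"log-rank chi2={chi2:.1f}, p={p:.2e}, "
              f"n_high={len(groups.high)}, n_low={len(groups.low)}")

        rows = []
        for grp_label, grp in (("high", high), ("low", low)):
            km = km_estimate(grp.time, grp.event)
            for t, s, n in zip(km.event_times, km.survival, km.at_risk):
                rows.append((grp_label, t, s, n))
        pd.DataFrame(rows, columns=["group", "time", "survival", "at_risk"]).to_csv(
            args.outdir / f"km_{gene}_{label}.tsv", sep="\t", index=False,
            float_format="%.6g",
        )

        try:
            from susceptigene.survival import plot_km

            ax = plot_km(
                {"high expression": (high.time, high.event),
                 "low expression": (low.time, low.event)},
                title=f"{gene}: {label} split (log-rank p={p:.1e})",
            )
            ax.figure.savefig(args.outdir / f"km_{gene}_{label}.png", dpi=120)
        except ImportError:
            pass
    print(f"curves written to {args.outdir}")


if __name__ == "__main__":
    main()
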
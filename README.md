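# susceptigene

A tested, reusable implementation of a multi-stage *in silico* screen for
cancer-type-specific susceptibility genes, together with the downstream
regulatory analyses such a screen feeds into. The motivating use case is
acute myeloid leukemia (AML): find genes whose knockout selectively impairs
AML cell lines, which are overexpressed in AML patients, and whose high
expression predicts poor survival — then characterize how such a gene
(e.g. a transcription factor like IRF8) acts on chromatin and transcription.

## The screen

Given a gene × cell-line CRISPR dependency matrix with a small target-type
panel (default 13 lines) and a large background panel (default 345), a gene
× sample TPM matrix, and a survival cohort, the funnel is:

1. **Dependency stage** — per gene, compare mean dependency scores
   $\bar{s}_{\text{target}}$ vs $\bar{s}_{\text{other}}$; keep genes with
   $\bar{s}_{\text{target}} < -0.5$ and $\bar{s}_{\text{other}} > -0.2$
   (knockout depletes the target lines but not the background).
2. **Expression stage** — keep genes with tumor/reference fold change
   $(\bar{x}_T + 1)/(\bar{x}_R + 1) > 3$ and mean tumor TPM $> 10$.
3. **Survival stage** — split the cohort at the 25% highest vs lowest
   expressing samples, fit a univariate Cox proportional-hazards model
   (Breslow ties, Newton–Raphson on the partial likelihood) for the
   high-vs-low indicator, and test the separation with the two-group
   log-rank statistic. Final candidates have HR $> 1$ at log-rank
   $p < 0.05$.

The downstream layers implement, from first principles where the statistic
is the point: Kaplan–Meier estimation, promoter/non-promoter peak
classification (≥ 1 bp overlap, 0-based half-open BED), peak-level Venn
overlap of two peak sets, genomic-feature distribution of peaks versus the
genome background, per-gene promoter-signal ranking, median-of-ratios count
normalization with a Welch-t differential-expression stand-in and the
"≥ 2-fold, p < 0.01" DE rule, and preranked GSEA (weighted running-sum ES,
gene-label permutation null, sign-stratified NES and nominal p).

A seeded synthetic-data module (`susceptigene.synthdata`) generates every
input class with planted, known-truth structure — target-specific essential
genes, overexpressed genes, a prognostic signature driving hazard, planted
negative-binomial fold changes, and a toy genome — so the entire pipeline is
testable without any external download.

## Worked example

The `analysis/` scripts run the whole study on simulated data:

```
python analysis/01_simulate.py --seed 1     # writes results/data/
python analysis/02_screen.py                # three-stage screen
python analysis/03_survival_curves.py       # KM curves for the top candidate
python analysis/04_peak_analysis.py         # peak classification / Venn / distribution
python analysis/05_differential_expression.py
python analysis/06_integrative_enrichment.py
```

With seed 1, `02_screen.py` prints:

```
funnel: 2000 genes -> 30 dependency-specific -> 30 overexpressed -> 30 final candidates
planted recovery: 30/30 found, 0 false positives
```

i.e. the 30 genes planted with the full susceptibility signature
(dependency effect −1.0, 8-fold overexpression, true hazard ratio 2.5) are
recovered exactly, with no false positives among the 1,970 null genes, and
`03_survival_curves.py` reports the quartile-split hazard for the
top-ranked candidate (`HR=2.83, log-rank p=7.5e-08` at this seed — the
estimate for a *single* gene scatters around the planted 2.5).
`05_differential_expression.py` recovers 56/60 planted knockout-responsive
genes at the 2-fold / p < 0.01 rule with a balanced up/down split, and
`04_peak_analysis.py` classifies 313/1000 peaks as promoter peaks against a
planted promoter-overlap fraction of 0.3.

The same machinery is importable directly:

```python
import susceptigene as sg
from susceptigene import synthdata as sd

cfg = sd.planted_screen_config(seed=1, n_genes=2000, n_planted=30)
expr = sd.gen_expression(cfg)
result = sg.screen(sd.gen_dependency(cfg), expr, sd.gen_survival(cfg, expr))
print(result[result["candidate"]].head())
```

A thin CLI mirrors the stages (`susceptigene essentiality|expression|
survival|peaks|de|gsea|run`); see `--help` on each subcommand.

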
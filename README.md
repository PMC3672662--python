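# parityomics

Quantitative toolkit for studying how an early pregnancy (parity) changes
mammary stem/progenitor cell populations in the mouse. Parity is the
strongest known modifiable protective factor against breast cancer; one
proposed mechanism is that it depletes the proliferation potential and
rewires the Wnt/Notch signaling balance of basal stem/progenitor cells.
This package implements the statistical machinery needed to quantify that
claim from the standard experimental readouts:

* **Limiting-dilution transplantation** — maximum-likelihood inference of
  the mammary repopulating unit (MRU) frequency `f` under the single-hit
  Poisson model, `P(negative | dose d) = exp(-f d)`, with Wald confidence
  intervals on `log f`, likelihood-ratio tests between donor groups, and a
  single-hit adequacy (deviance) check.
* **Moderated differential expression** — empirical-Bayes shrinkage of
  gene-wise variances (`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)`) with
  moderated t statistics, Benjamini–Hochberg adjustment, and the
  fold-change / adjusted-p / average-expression filter cascade used for
  sorted-cell microarray data.
* **Motif activity response analysis (MARA)** — ridge-regularised
  inference of per-sample transcription-factor motif activities from
  `E ≈ N·A` (expression explained by promoter binding-site counts), with
  per-motif condition-change z-scores.
* **Permutation GSEA** — weighted Kolmogorov–Smirnov enrichment scores
  with a gene-set permutation null, reporting ES/NES/nominal p/FDR/FWER.
* **IHC color quantification** — Mahalanobis-distance segmentation of
  stained pixels in RGB micrographs against a fitted reference color
  distribution, thresholded at a chi-square(3) quantile.
* **Synthetic data** — seeded generators that draw from exactly the
  models the analyses assume, with planted-truth records, so every stage
  is testable end to end without any external download.

Core computations are exposed as scikit-learn-style estimators
(`SingleHitModel`, `ModeratedTTest`, `MotifActivityModel`,
`GeneSetEnrichment`, `MahalanobisSegmenter`) with plain functions
(`fit_single_hit`, `moderated_t`, `fit_activities`, `permute_and_score`,
`segment_by_mahalanobis`) as thin wrappers.

## Worked example

Fit the packaged basal stem/progenitor transplantation tables (outgrowths
scored at the ≥10%-of-fat-pad stringency) and compare virgin against
parous donors:

```python
from parityomics.datasets import load_transplant_tables
from parityomics import fit_single_hit, compare_frequencies, goodness_of_fit

tables = load_transplant_tables()
for label in ("virgin_d", "parous_d"):
    est = fit_single_hit(tables[label])
    gof = goodness_of_fit(tables[label], est)
    print(f"{label}: 1/{est.denominator} "
          f"(95% CI 1/{round(1/est.ci_low)} - 1/{round(1/est.ci_high)}), "
          f"single-hit GoF p = {gof.p_value:.2f}")
cmp = compare_frequencies(tables["virgin_d"], tables["parous_d"])
print(f"virgin vs parous (>=10% outgrowths): chi2 = {cmp.chi2:.2f}, p = {cmp.p_value:.2g}")
```

prints

```
virgin_d: 1/472 (95% CI 1/766 - 1/290), single-hit GoF p = 0.75
parous_d: 1/2094 (95% CI 1/4441 - 1/987), single-hit GoF p = 0.57
virgin vs parous (>=10% outgrowths): chi2 = 12.31, p = 0.00045
```

i.e. roughly one repopulating cell per 472 injected basal
stem/progenitor cells from virgin donors versus one per ~2100 from
parous donors — a ~4.4-fold drop in repopulating frequency after parity
(p ≈ 4×10⁻⁴), with the single-hit model fitting both tables well.

The same analyses run from the shell:

```bash
parityomics lda fit transplants.csv
parityomics de run expr.tsv samples.csv --fc 1.5 --padj 0.05 --ave 4
parityomics mara fit expr.tsv samples.csv sites.tsv --ridge-lambda cv
parityomics gsea run expr.tsv samples.csv sets.gmt --perms 1000 --seed 17
parityomics ihc quantify image.png brown_pixels.csv --quantile 0.99
parityomics pipeline run config.yaml --out runs/
```

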
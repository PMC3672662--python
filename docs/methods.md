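# Methods

This note documents the statistical models implemented in `parityomics`,
the choices made where the methodology was genuinely open, what the
synthetic-data generators do and do not emulate, and the numerical
conventions.

## Limiting-dilution frequency inference

**Model.** A transplant of `d` cells into a cleared fat pad is scored
positive when an epithelial outgrowth forms. Under the single-hit
Poisson model the graft fails only if it received zero repopulating
cells, so `P(negative | d) = exp(-f d)` with `f` the repopulating-unit
frequency per injected cell. The log-likelihood over dose groups
`(d_i, n_i, r_i)` is

    l(f) = Σ_i [ r_i log(1 - e^{-f d_i}) - (n_i - r_i) f d_i ].

`f̂` is found by bounded scalar maximisation over `log f` (Brent,
`xatol 1e-12`); this is equivalent to an intercept-only binomial
regression with complementary log-log link and offset `log d`, and the
implementation is cross-checked against that GLM formulation in the
tests.

**Confidence intervals.** The default 95% interval is Wald on the
natural-log scale, `exp(log f̂ ± 1.96·SE)`, with the SE from the
*expected* (IRLS) Fisher information `I(log f) = f² Σ_i n_i d_i² q_i/p_i`
(`p_i = 1 - e^{-f d_i}`, `q_i = 1 - p_i`). Expected rather than observed
information was chosen because it is what limiting-dilution software
conventionally reports (the GLM route) and it reproduces published
interval bounds for this assay design; a profile-likelihood interval is
available via `ci_method="profile"`. Simulated coverage at the packaged
dose ladder (doses 1000/500/250/100/50, n = 9/11/6/6/7, f = 1/500) is
~95% over 1000 replicates.

**Group comparison.** Equality of frequencies between two donor groups
is tested by the likelihood ratio: `χ² = 2(l_a + l_b - l_pooled)` on
1 df, where the pooled fit constrains one `f` to the concatenated
table. A Wald test would be asymptotically equivalent; the LRT is
preferred for its symmetry and behaviour at small counts.

**Boundary tables.** A table with zero positives overall has its MLE at
`f = 0`; we report `boundary_flag="zero"` with the exact one-sided upper
bound `f ≤ log(1/α)/Σ n_i d_i` instead of a Wald interval (analogously
for all-positive tables). Individual all-negative *rows* inside an
otherwise informative table are ordinary data, not a boundary.

**Goodness of fit.** Residual deviance of the fitted binomial model
against the saturated model, referred to chi-square with
(dose groups − 1) df. Under data generated from the single-hit model the
resulting p-values are close to uniform; dose-response shapes steeper
than single-hit (cooperative, "two-hit-like") are flagged with small p.

**Outgrowth scoring.** `classify_outgrowths` thresholds
fraction-of-fat-pad-filled values so a dose-response table can be built
at a chosen stringency (3% rudimentary, 10% or 25% large outgrowths);
the packaged tables ship all three scoring variants.

## Moderated differential expression

Two-group comparison on log2 expression with `n` of order 3 per group.
Per gene, the pooled residual variance `s²_g` (df `d_g = n_a + n_b - 2`)
is shrunk toward a prior `(d₀, s₀²)` estimated by the method of moments
on `log s²_g` (digamma/trigamma matching; the trigamma inverse is solved
by Newton iteration). The moderated statistic

    t_g = (mean_b - mean_a) / sqrt(s̃²_g (1/n_a + 1/n_b)),
    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)

is referred to a t distribution with `d₀ + d_g` df. When the observed
spread of log-variances is no larger than sampling noise the prior df is
infinite and variances pool completely (flagged). `prior_df=0` disables
shrinkage and reduces exactly to the ordinary pooled t. The
implementation is verified in the tests against an independent
R implementation of the same empirical-Bayes model.

**Filters.** The retention cascade is conjunctive: linear fold change
`2^{|log2FC|}` above a threshold (default 1.5; 2.0 for shortlists),
BH-adjusted p below a threshold (0.05; 0.001 for shortlists), and
average linear expression above 4. "Average linear expression" is
computed as the mean of the two condition means of `2^{log2 value}` —
the wording "linear" is taken literally even though the input matrix is
log2; this is configurable via `FilterCriteria`. Multiple-testing
adjustment is Benjamini–Hochberg ("adjusted p" is not otherwise
specified by convention in this assay, and BH is the field default).
Probe-level tables can be collapsed to genes keeping the probe with the
largest |log2FC|.

**Display normalisation.** `zscore_rows` standardises each gene row to
mean 0 and sample SD 1 (`Z = (x-μ)/sd`), mapping constant rows to zero
with a warning; this is a visualisation aid, not an inference step.

## Motif activity response analysis

Expression is modeled as `E ≈ N·A`: `N` (genes × motifs) counts
predicted transcription-factor binding sites in proximal promoters, `A`
(motifs × samples) are the unknown motif activities. The expression
matrix is double-centered (per gene, then per sample) and the site
counts column-centered, so activities are defined up to and invariant
under additive gene/sample offsets. Per sample,

    Â_·s = argmin_A ‖E_·s - N A‖² + λ‖A‖²  =  (NᵀN + λI)⁻¹ Nᵀ E_·s,

with standard errors `sqrt(σ̂²_s · diag((NᵀN + λI)⁻¹))` where `σ̂²_s` is
the per-sample residual variance with the ridge's effective model df
(trace of the hat matrix). The penalty is needed because site-count
columns of related motifs are nearly collinear; `λ` may be fixed or
chosen by gene-wise k-fold cross-validation. `λ = 0` on a singular
system raises an error instructing a positive penalty rather than
silently pseudo-inverting.

**Condition changes.** Per motif, `Δ = mean(parous) - mean(virgin)`.
The SE of `Δ` uses the between-sample spread of fitted activities
(which already carries the fitting noise), moderated across motifs by
the same empirical-Bayes variance shrinkage as the DE module — at three
replicates per condition a raw 4-df variance estimate is noisy enough
for null motifs to fluke extreme z-scores — and floored by the
propagated per-sample fitting error so degenerate motifs keep a
positive SE. `z = Δ/SE` with a two-sided normal p; motifs are ranked by
|z|. The normal reference is an approximation whose quality grows with
replication; null calibration is demonstrated in the tests at 10
samples per condition.

## Permutation gene-set enrichment

Genes are ranked by the parous-minus-virgin mean expression difference
(descending; ties broken lexicographically for determinism). For a set
of size `k` in a universe of `N`, the running sum increments by
`|score|^p / Σ_set |score|^p` at members and decrements by `1/(N-k)`
otherwise; ES is the signed maximum deviation. `p = 1` by default
(standard weighting), `p = 0` gives the unweighted KS form used for the
analytic test cases. The permutation null draws random same-size gene
sets (gene-set permutation, appropriate when arrays per group are too
few for phenotype permutation):

* nominal p — fraction of same-sign null ES at least as extreme;
* NES — ES divided by the mean |ES| of same-sign nulls of that size;
* FDR q — tail-ratio on the pooled normalised null (fraction of null
  NES at least as extreme divided by fraction of observed NES at least
  as extreme, clipped to [0,1]);
* FWER — fraction of permutations whose most extreme same-sign null
  NES across all sets exceeds the observed NES.

Null draws are shared across same-size sets (the null law depends only
on set size), and the extrema of the piecewise-linear running sum are
evaluated only at hit-adjacent positions, making the permutation loop
`O(n_perm · k log k)` instead of `O(n_perm · N)`. Sets outside the
5–500-member band are flagged but still scored.

## IHC color segmentation

A reference stain color is summarised by the sample mean and covariance
of ≥10 hand-picked training pixels (near-singular covariances are
diagonally inflated and flagged). A pixel is called positive when its
squared Mahalanobis distance to the reference is within the
chi-square(3 df) quantile `q` (default 0.99) — under a Gaussian color
model the expected positive rate on reference-distribution pixels is
exactly `q`, which makes the threshold calibration-testable. The
positive fraction can be restricted to a tissue mask. Distances are
computed on floats after promoting 8-bit RGB; the mask is invariant to
invertible linear color transforms applied consistently to image and
reference.

## Synthetic-data generators

One global seed is expanded into fixed per-generator substreams, so
adding a generator or changing another stage's parameters never
perturbs existing draws; identical config + seed gives byte-identical
outputs.

* **Transplants** — each injection positive with `1 - e^{-f d}`,
  matching the fitted model exactly.
* **Expression** — gene baselines `N(7, 2²)` log2 units (typical RMA
  output range); gene variances from the scaled inverse-chi-square
  prior `d₀ = 4, s₀² = 0.05` (residual sd ≈ 0.22, typical for replicate
  arrays), so the moderated-t prior is exactly the generative family
  and shrinkage recovery is a sharp test; 5% of genes shifted by
  ±1 log2 unit in the parous condition by default; three samples per
  condition, matching the replicate structure of the sorted-cell
  experiments.
* **Motif data** — site counts Poisson(0.5), sparse like real
  promoter-site matrices (this also stresses the ridge's conditioning);
  activities per sample around condition means with replicate sd 0.25
  (replicate arrays vary less than typical condition effects of order
  1); expression = `N·A` + Gaussian noise (sd 0.5) + baseline. All-zero
  site columns are generated as drawn and flagged.
* **Images** — exactly `floor(fraction · H · W)` pixels from the
  positive color Gaussian (default DAB-brown-like mean) and the rest
  from a light background, with the truth mask returned.

**What the generators do not emulate:** probe-level array artifacts,
normalisation residue, batch effects, correlated genes, motif libraries
derived from real position-weight matrices, tissue morphology or
staining gradients in images. Passing tests therefore demonstrate
correctness and calibration of the estimators under their assumed
models, not robustness to real-data violations of those assumptions.

## Numerical conventions and limitations

* Frequencies are displayed in the conventional `1/round(1/f̂)` form.
* Optimisation bounds for `log f` span `[-30, log(20/min dose)]`;
  likelihood terms use `log1p`/`expm1` for stability near saturation.
* BH adjustment and tail probabilities come from statsmodels/scipy.
* Problem sizes in the test suite (10⁴ genes for calibration checks,
  5000 genes × 50 motifs for recovery, 1000 simulated assays for
  coverage, 128×128 images) were chosen as the smallest sizes at which
  Monte-Carlo error is comfortably below the tolerances being asserted.
* The pipeline runner hashes its config (SHA-256 over canonical JSON)
  into every report and excludes timestamps and absolute paths, so a
  rerun with identical config and seed reproduces the report
  byte-identically.
* Known limitations: no multi-hit or heterogeneity transplant models;
  no multi-factor expression designs or batch correction; no sequence
  scanning or promoter annotation (site counts are an input); no stain
  deconvolution or cell-level segmentation; GSEA reports no
  leading-edge genes.
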
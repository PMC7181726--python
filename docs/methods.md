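# Methods

This note documents the statistical model behind `fibroprot`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Data model and pre-filtering

LFQ intensities are analyzed on the log2 scale; zero or empty cells in the
`proteinGroups` table are treated as missing (MaxQuant writes 0 for
non-quantified proteins), and the matrix carries an explicit missing mask —
a cell is either finite or missing, never both. Nothing in the pipeline
imputes: missingness propagates into valid-value counts and the missingness
gate instead. Decoy/contaminant/only-by-site flags follow the "any non-empty
cell means flagged" convention so both the `+` and `TRUE` dialects parse.
The ≥ 6-valid-values detection filter counts across all samples of the
table, not per group, because it belongs to the pre-processing step that
precedes any group comparison; a per-group variant can be had by subsetting
columns first.

## Robust quantile normalization

Per-sample systematic shifts are removed by a quantile-based transform that
deliberately does *not* force full distributional equality. For sample *s*
with empirical quantile function `Q_s`:

* a probability grid of `grid_size` points (default 1001) spans the central
  range `[α, 1−α]` (default α = 0.05);
* the reference `R(p)` is the per-probability **median** of the samples'
  quantiles — the median rather than the mean so that a single outlying
  sample cannot drag the reference;
* within the central span, values are mapped by monotone linear
  interpolation through the knots `(Q_s(p), R(p))`;
* outside the span, values receive only the additive offset that makes the
  transform continuous at the span boundary.

Consequences, all covered by tests: the transform is monotone within each
sample (ranks preserved); per-sample medians align exactly on complete data
with an odd number of rows (and to interpolation error otherwise); the
within-tail *spread* of every sample is preserved exactly, because the tail
branch is a pure shift; and a pure between-sample shift is corrected
completely. Ordinary quantile normalization (also provided, and used as the
contrast in tests) instead maps every sample onto the mean order statistics,
equalizing tail variability. Duplicate quantile knots (ties) are collapsed
by averaging their reference values, which keeps the interpolant monotone.

The original study's normalization is described only as a robust variant of
quantile normalization that conserves variability of high- and low-abundant
proteins; the construction above is the simplest transform with exactly
those two properties. The central span α and grid size are configurable
(`normalization:` block in the pipeline YAML).

## Noise model and moderated test

For each protein and a pair of groups A, B the pooled residual standard
deviation is

    SD² = (Σ_A (x−x̄_A)² + Σ_B (x−x̄_B)²) / (nA + nB − 2)

over valid cells, undefined when the residual degrees of freedom d =
nA + nB − 2 < 1. The intensity-dependent prior `SD_prior` is a LOWESS fit
(tricube weights, locally linear, zero robustness iterations — the
statsmodels implementation) of SD against the protein's mean log2 intensity.
The smoothing span of 1000 is a nearest-neighbour window in *points*,
clipped to the number of proteins with a defined SD; a span of 1000 read as
a fraction would be meaningless. Predictions are floored at zero.

The moderated spread is the equally weighted average

    SD_mod = (SD + SD_prior) / 2,

falling back to `SD_prior` alone when SD is undefined (the average cannot be
formed; the affected proteins are logged). The test statistic is

    t = (x̄_A − x̄_B) / (SD_mod · sqrt(1/nA + 1/nB)).

**Degrees of freedom.** `SD_mod` is half protein-specific estimate, half
smooth function of thousands of proteins, so it is far less variable than
SD itself: with `Var(SD) ≈ σ²/(2d)` (delta method) and the prior treated as
known, `Var(SD_mod) ≈ σ²/(8d)` — the moderated SD carries the information
of an SD estimate with ≈ 4d degrees of freedom. Referring t to `t_{4d}`
(the default, `df_scale = 4`) gives a calibrated test: on null simulations
(2000 proteins, 6 vs 6) the empirical type-I error at P < 0.01 lands in
[0.0075, 0.015] across seeds and the P-value distribution is uniform
(KS < 0.05). Referring it to `t_d` (`df_scale = 1`) is markedly
conservative (empirical α ≈ 0.002–0.005 at the 0.01 threshold) because it
ignores the variance reduction the moderation buys. Setting `df_scale = 1`
restores the plain residual-df convention when direct comparability with a
classic pooled test's P values matters; the *statistic* itself reduces
exactly to the classic pooled two-sample t whenever `SD_prior = SD`,
regardless of the df choice.

**Significance.** A protein is called significantly changed when P < 0.01
and fewer than 50% of its cells among the compared samples are missing.
Both thresholds are configurable — note that published analyses of this
kind sometimes quote P < 0.05 in results text while the processing methods
state P < 0.01; the package defaults to the stricter 0.01 and leaves the
choice to `test.alpha_sig`. The missingness fraction is computed over the
samples of the current comparison, matching the two-condition framing of
the test; no multiple-testing correction gates the call (the raw-P
threshold is the convention this workflow reproduces) but a BH-FDR column
is always written. Multi-group designs are handled as the union of
significant sets over the listed pairwise contrasts, each run through the
full two-group pipeline including its own prior fit.

## Annotation, overlap, clustering, PCA

Cross-species matching is by trimmed, upper-cased gene symbol; protein
groups with several gene names contribute every symbol. This matches mouse
and human hits without an ortholog database but will over- or under-count
where orthology is not 1:1 by symbol — an explicit ortholog table can be
substituted upstream. The packaged matrisome table
(`src/fibroprot/data/matrisome_mini.tsv`) is a small hand-curated subset of
the public matrisome catalogue (division and category per symbol) meant for
tests and demonstrations; real analyses should point `matrisome:` at the
full published list.

Heatmap row ordering uses agglomerative clustering with distance
`d = 1 − r` where r is the Pearson correlation over pairwise-complete
cells (≥ 3 shared finite cells required; constant rows are rejected by
name). Average linkage is the default — the similarity measure is the
choice that matters for this workflow, the linkage is exposed
(`complete`/`single` available) — and the implementation is verified
against a naive O(n³) agglomeration oracle. PCA standardizes each protein
(row) across samples, drops proteins with any missing cell (logged), and
projects samples onto the first two components; scores are checked against
a covariance eigendecomposition up to sign.

## PRM quantification

Per (sample, peptide, isotope label) the cumulative area over the 6–7
fragment transitions is summed; the peptide ratio is light/heavy —
endogenous over the heavy-labelled standard spiked at a fixed amount — so
larger values mean more endogenous protein. The standard peptide
SLSSPTVTLSAPLEGAK is excluded by default (unreliable heavy quantification);
ratios of the remaining (expected two) peptides are averaged arithmetically
per sample, with a warning when the count deviates and a geometric-mean
option for ratio purists. Levels are reported relative to the arithmetic
mean of the control group, which therefore averages to exactly 1. Ratios
are invariant to rescaling all areas of a sample (tested), so differences
in injection amount or spray efficiency cancel.

## Synthetic-data generator

`generate_lfq` emulates the structure this analysis assumes, with defaults
chosen to mirror a realistic two-group LFQ tissue experiment:

| parameter | default | meaning |
|---|---|---|
| n_proteins | 2000 | detected proteome size after filtering |
| groups | control/case, 6 + 6 | biological units per arm |
| base intensity | 0.85·N(27, 1.8²) + 0.15·N(24, 1.2²) (log2) | heavy-tailed abundance mixture on the MaxQuant LFQ scale |
| t-location-scale option | t₄, loc 26.5, scale 1.8 | heavier-tailed alternative |
| sample_shift_sd | 0.3 log2 units | per-sample systematic shift |
| noise SD | 0.2 + 6·exp(−0.18·I) | intensity-dependent biological noise, ≈ 0.25 at the mode, rising toward low abundance |
| de_fraction / effects | 0.1, ±1 log2 | planted truly changed proteins |
| MNAR dropout | logistic, midpoint 23.5, slope 1.2 | ≈ 50% dropout at the low-abundance edge, the mechanism that motivates the < 50%-missing gate |
| MCAR rate | 0.02 | label-free stochastic losses |

Overall realized missingness under the defaults is ≈ 12%, concentrated at
low intensity (the observed fraction is monotone in intensity decile —
tested). Written output is a parseable `proteinGroups`-dialect file with
raw-scale intensities, zeros for missing cells and planted
contaminant/decoy/by-site rows, so the ingest layer and the pre-filters are
exercised by the same fixtures. Generation is bit-reproducible from the
seed.

What the generator does **not** emulate: peptide-to-protein roll-up and
shared-peptide effects, correlated proteins (co-regulation), batch
structure beyond a scalar shift, intensity-dependent *technical* CV,
interference/chimeric spectra, or real decoy/contaminant abundance
profiles. Passing tests therefore demonstrate the statistical machinery is
correct under the stated model, not that the model captures every pathology
of real LFQ data.

`generate_prm` plants a known case/control ratio with lognormal
peptide-level noise of a given CV and an erratic heavy signal for the
excluded standard peptide; with noise 0 the pipeline recovers the ratio
exactly, and at CV 0.1 with 11 samples per arm (the cohort size of a
typical biopsy comparison) within ±0.05.

## Numerical choices and degenerate inputs

* Quantiles use numpy's default linear interpolation; quantile-knot ties
  collapse by averaging (monotonicity preserved).
* Samples need ≥ 10 valid values for robust normalization, ≥ 2 for
  ordinary; violations raise with the sample named.
* Proteins with zero residual df get `SD_mod = SD_prior`; df < 1 or
  `SD_mod = 0` marks a record untestable, and untestable records are never
  significant.
* The LOWESS prior needs ≥ 10 proteins with defined SD.
* Outputs are sorted by ascending P with protein-id tie-break, and the run
  manifest checksums every artifact, so reruns are byte-identical.

## Problem sizes

The test suite and `scripts/acceptance.py` run at the sizes the statistics
are stated for — 2000-protein, 6 vs 6 simulations for calibration and
recovery, 2001 × 4 deterministic inverse-CDF fixtures for normalization
properties, 11 + 11 PRM cohorts — and complete in a few seconds in total.

## Known limitations

* The significance call is a raw-P threshold by design; use the `fdr_bh`
  column when error-rate control across the proteome is needed.
* Symbol-level cross-species matching is approximate (see above).
* The robust normalization assumes samples share a common distribution
  shape in the central span; gross global differences (e.g. failed runs)
  should be excluded beforehand.
* No imputation, by design: strongly MNAR proteins are handled by the
  missingness gate, not modelled.
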
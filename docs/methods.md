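# Methods

## Problem and model

`tegene` estimates, gene by gene, how the expression of transposable-element
(TE) subfamilies located upstream of a gene associates with that gene's
expression across RNA-seq samples.  The response and predictors are
TMM-normalized log₂-CPM values and the model is ordinary least squares:

    y_i = β₀ + Σ_k β_k · TE_ki + Σ_m γ_m · C_mi + ε_i,   ε_i ~ N(0, σ²)

One model is fitted per gene that has at least one linked TE term surviving
the count filter.  Reported per model: coefficient estimates with standard
errors and two-sided t tests on n−p−1 degrees of freedom, R² about the mean,
adjusted R² = 1 − (1−R²)(n−1)/(n−p−1), the overall F = (R²/p)/((1−R²)/(n−p−1))
with upper-tail p from F(p, n−p−1), and σ̂² = RSS/(n−p−1).  `p` counts
predictor columns excluding the intercept.  No observation weights are used:
the transformation applied is the log₂-CPM step only, because the downstream
fit is plain OLS and the reference arithmetic (adjusted R² and F at n = 44,
p = 3 for single-TE models with two covariates) is consistent only with
unweighted fits.

Associations are correlational: a significant TE term may reflect the TE
driving the gene, the gene's locus activating the TE, or a shared upstream
cause.  The model makes no causal claim.

## Coordinate conventions and linking

All internal coordinates are 0-based half-open; conversion from RepeatMasker
(1-based inclusive, `C` = minus strand) and GTF (1-based inclusive) happens
only in the parsers.  The gene anchor is the strand-aware TSS; the TE anchor
is its annotated lower coordinate — repeat annotations do not reliably carry
a transcriptional orientation for every copy, so the annotated start is the
only universally defined anchor.  The signed upstream distance is
d = tss − start on `+` genes and start − tss on `−` genes; a positive window
keeps 0 < d ≤ distance (inclusive at the far edge, exclusive at the TSS: a
TE at or downstream of the TSS is not "upstream"), a negative window keeps
−|distance| ≤ d < 0.  Defaults: distance = 5000 (the 5 kb promoter-proximal
window commonly used for TE–gene studies) and no strand matching, since
upstream regulatory TEs act from either strand; both are exposed.  The
search uses per-chromosome sorted start arrays with binary search; its
correctness is defined by, and tested against, an exhaustive scan over all
(gene, TE) pairs.

## Read counting

A read is credited to a TE instance only when its aligned *reference* span
is fully contained in the instance interval: soft-clipped bases fall outside
the span; deletions and introns extend it (CIGAR reference length).  Mates
of a pair are counted independently, and a read contained in several
overlapping instances counts toward each — there is no disambiguation rule,
so overlapping annotations share reads (loud caveat: sums over overlapping
instances double-count).  Flags excluded always: unmapped, secondary,
supplementary, duplicate.  `min_mapq` defaults to 0 so BAMs already filtered
to unique alignments are not filtered twice; pass 60 to restrict to uniquely
mapped reads when counting raw alignments, which is the recommended setting
because multi-mapping reads are inherently ambiguous among repeat copies.

## Normalization

Genes and TEs are merged into one matrix *before* filtering and
normalization, so scaling factors reflect the library composition the models
actually see.  Filtering keeps rows with a total (across samples) of at
least `min_total` = 10 reads, boundary inclusive; row totals were chosen
over per-sample thresholds as the simpler rule with the same intent.  TMM
factors follow the published trimmed-mean-of-M-values estimator: reference =
sample whose 75th-percentile count fraction is closest to the mean of those
quantiles; per sample, M and A values over features positive in both, double
trimming (30 % of M per tail, 5 % of A), weights = inverse delta-method
binomial variances, factor = 2^(weighted mean M); factors are rescaled to
geometric mean 1.  A sample sharing no positive feature with the reference
gets factor 1 with a warning.  The transform is
log₂((count + 0.5) / (lib·factor + 1) × 10⁶) with library sizes recomputed
on the filtered matrix.  The implementation is tested against an
independent plain transcription of the formulas (≤ 1e−6) and against
Bioconductor edgeR.

## Design matrices and covariates

The default covariate encoding is `numeric`: one column per covariate, with
categorical levels coded 0, 1, … in first-appearance order.  This mirrors
the reference arithmetic — single-TE models over 44 samples with tissue and
patient covariates report adjusted R² consistent with p = 3, i.e. one column
per covariate — and is therefore the default for comparability.  It treats
a many-level factor like `patient` as a linear trend, which is statistically
dubious; `onehot` (reference level dropped) is available and recommended for
new analyses.  Rank-deficient designs are handled by greedily dropping
aliased columns (reported with NA coefficients and a warning).  Genes with
n ≤ p+1 or a zero-variance response are skipped with reasons, not errors.
Model p-values are reported raw (the reference output is raw); a
Benjamini–Hochberg `model_q` column is added, clearly labelled, for
convenience.  Significance for diagnostics/plots is strict: model_p < α.

## Synthetic data generator

The generator emulates a paired bulk RNA-seq design: 44 samples = 22
patients × (normal, tumour), ~2×10⁶ counted reads per sample, TE baseline
expression uniform on log₂-CPM (3, 7), gene baselines uniform (4, 8), a
per-gene tissue effect ~ N(0, 0.5), residual noise σ = 0.5 on the log scale,
and negative-binomial counts with variance μ + μ²·φ at φ = 0.05 — values in
the range typically estimated for bulk tissue.  Genomic layout: genes in
non-overlapping slots on alternating strands with TE instances planted at
upstream offsets {−100, 1000, 4000, 5000, 6000}, so a 5 kb window must link
exactly the 1000/4000/5000 offsets (boundary inclusive) per gene.  BAM
fixtures add, per instance, decoy reads that must not be counted at
MAPQ ≥ 60 (partial overlap, MAPQ 0, duplicate flag) and one soft-clipped
read whose reference span is contained (must be counted).  The per-instance
truth tables account for reads contained in more than one instance.

`make_full_fixture` chains the generators self-consistently: per-instance
read counts are drawn from the latent TE expression, BAMs carry exactly
those reads, and gene counts are generated from the planted model using the
*aggregated truth counts* as predictors — the same quantity the pipeline's
counter recomputes — so an end-to-end run recovers both the truth counts
exactly and the planted coefficients.  Within `simulate_expression` the
planted linear combination likewise uses the realized (count-derived) TE
log₂-CPM, not the latent draw; conditioning on the realized predictor is
what makes the planted β the estimand of the fitted model, rather than an
errors-in-variables-attenuated version of it.

What the generator does **not** emulate: realistic read sequences or base
qualities, splicing, fragment-level duplicate structure, mappability
variation, batch effects, or correlated TE–gene baselines.  Passing tests
therefore demonstrate correctness of the arithmetic and the estimator under
the stated model, not robustness to alignment artefacts in real data.

Determinism: every generator is a pure function of (config, seed); repeated
runs produce byte-identical data files.  The JSON run manifest carries a
wall-clock timestamp and is the one file excluded from byte-identity.

## Numerical and procedural choices

- OLS is delegated to statsmodels; tests pin it to the closed-form normal
  equations (≤ 1e−8) and the adjusted-R² identity (≤ 1e−10).
- TMM trim fractions are fixed at the standard 0.30 / 0.05; the A cutoff
  default (−1e10) effectively disables the abundance floor.
- Null calibration of the TE-term test uses responses generated at the
  log-CPM level with Gaussian noise and a true TE coefficient of zero —
  the setting in which the p-value is exactly uniform; count-level noise
  makes it only approximately so.
- Problem sizes in the test suite and acceptance script (e.g. 2 000 null
  genes, 200 replicate planted genes, 50 random layouts, 20-gene
  file-level fixtures at 44 samples) were chosen as the smallest sizes at
  which the sampling error of each checked quantity is well inside its
  tolerance.
- Exit codes of the CLI: 0 success, 1 usage error, 2 data error.

## Known limitations

- Duplicate gene symbols mapping to several loci resolve to the longest
  span (logged); there is no transcript-model collapsing beyond that.
- No multi-mapper rescue: reads below the MAPQ threshold are simply
  dropped, so young, highly similar TE subfamilies are under-counted.
- `numeric` covariate encoding is kept as the default for comparability
  with the reference arithmetic despite its linear-trend assumption.
- CPM values are compositional: a handful of features dominating a library
  couples every feature to the per-sample totals.  TMM mitigates but does
  not remove this.
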
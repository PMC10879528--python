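# Methods

This note documents the models and procedures implemented in `sccmgan`, the
parameter choices that matter, and what the synthetic benchmark does and
does not show.

## Preprocessing

The reference-preparation pipeline runs, in order:

1. **Basic gene filter.** Genes with zero total count or identical values in
   every cell are removed (a constant gene carries no information and breaks
   downstream standardization).
2. **Cell QC.** For each cell we compute library size, mitochondrial count
   fraction and ribosomal count fraction; gene families are recognized by
   identifier prefix (`MT-`; `RPS`/`RPL`), configurable for other
   nomenclatures.  A cell is discarded if any metric lies further than
   `n_mads` (default 3) scaled median absolute deviations from the median;
   the MAD is scaled by 1.4826 so it estimates a normal σ, library size is
   tested on log scale, and the inequality is strict (a cell exactly at the
   fence survives, and an all-identical metric flags nobody).  An unscaled
   MAD is available as a config switch.
3. **Prevalence filter.** A gene is kept if its count exceeds the detection
   threshold (default 1, strict) in at least `prevalence_fraction` (default
   5%, with ceiling) of all cells, regardless of cell type.  We read the
   two published conditions ("present in ≥ 5% of cells", "count greater
   than one") as one joint condition, since they bind the same gene.
4. **TMM normalization**, each cell treated as one sample.  The reference
   cell is the one whose 75th-percentile CPM is closest to the mean; per
   pair, genes zero in either sample are excluded, log-ratios are trimmed
   30% from each tail and mean log-abundances 5% from each tail, and the
   factor is 2 to the precision-weighted mean of the surviving log-ratios
   (inverse asymptotic binomial variances as weights).  Factors are
   rescaled to geometric mean 1, and columns are divided by their effective
   library size relative to the mean, which keeps values on the count
   scale.  TMM is computed after the gene filters, and per cell rather than
   per subject (the literal reading of "each sample is one column").

One caveat documented by a test: a re-applied MAD filter is not exactly
idempotent.  Removing the tail shrinks the re-computed fence, so a second
pass can flag a few boundary cells (~0.2% on the default fixture).  QC is
therefore a one-pass operation, as in standard single-cell practice.

Raw (filtered) counts are used for pseudo-bulk summation; normalized
expression is used for marker ranking, median imputation and signatures.

## Pseudo-bulk mixtures

Each mixture draws a composition from a symmetric Dirichlet (default
concentration 1, uniform on the simplex), allocates the per-mixture cell
budget (default 100 cells) multinomially, samples cells with replacement
within each type and sums their raw counts.  Ground truth is the *realized*
fraction of drawn cells, not the Dirichlet draw, because that is the
quantity a deconvolver could at best recover.  Cells are drawn with
replacement so the number of mixtures is not limited by the test-half size.

## Generative backends

All backends share one contract: fit on a labelled reference, then emit a
requested number of cells per training cell type, over exactly the training
genes, non-negative, labelled with a synthetic subject.

**Gaussian copula** (per cell type): empirical per-gene marginals inverted
by linear interpolation between order statistics at midpoint ranks, coupled
through the correlation matrix of van der Waerden normal scores.
Non-positive-definite matrices are repaired by clipping eigenvalues at 1e-6
and renormalizing the diagonal.  Samples always stay inside the training
range; constant genes stay constant.

**Conditional GAN / VAE**: compact dense networks (default one hidden layer
of 128 units, latent dimension 16, batch size 32, Adam at 2e-3) on
expression transformed by `log1p` followed by per-gene min–max scaling to
[−1, 1]; the output activation is tanh and the inverse transform clamps at
zero.  The GAN uses the standard non-saturating loss with a one-hot
cell-type condition on both networks.  The VAE is a conditional encoder /
decoder with a diagonal Gaussian latent and a unit-variance Gaussian
likelihood (ELBO objective).  Defaults were chosen so that per-type sample
means track training means on held fixtures at ~50 training epochs.

Three design measures keep the GAN on-distribution in short training runs,
where a bare MLP GAN on this transform is badly biased:

* a condition→output skip connection initialized at the per-type mean
  profile in transform space, so early samples are cell-type prototypes;
* per-type per-gene multiplicative mean recalibration in count space,
  estimated once after training from training data only (the desk-scale
  analogue of the per-column normalization used by published tabular GANs;
  without it sample means land near the geometric rather than arithmetic
  mean, a Jensen-gap artifact of the log transform);
* an exponential moving average (decay 0.99) of generator weights, sampled
  from instead of the last iterate.

Generated values stay continuous; downstream deconvolution treats the
reference as expression levels.  Models are deterministic given the config
seed and cheap to refit; they are not serialized to disk.

## sc-CMGAN

*Feature selection.* Gene importance is the maximum over cell types of the
absolute coefficient of a ridge regression (penalty `ridge_alpha`, default
1.0) of the type's 0/1 indicator on log1p, per-gene-standardized
expression.  One-vs-rest is the minimal multi-class reading; a multinomial
model is a possible alternative.  Importance is computed once, before
stepping.

*Schedule.* Step *k* of *n* selects the top `t0 − (k−1)·t_step` percent of
genes (defaults 2 steps, 40% then 20%; sizes are rounded half-up; ties
break by input gene order).  Because the ranking is fixed, step sets are
nested.  A schedule reaching 0% (e.g. 3 steps from 40 by 20) is rejected at
config time.  The percentage notation could also be read as a single final
fraction; the schedule function is isolated so that alternative is a
one-line change.

*Generation.* Each step trains the GAN backend on its marker submatrix
(re-trained per step — the input dimensionality differs) and samples its
share of cells; the requested cells per type are split as evenly as
possible across steps, remainder to the earliest steps.  Non-marker genes
are filled with the per-cell-type median of the training expression,
computed directly on the expression scale, which makes the imputation
exactly reproducible (for odd cell counts it coincides with a median taken
on any monotone transform scale).

*Why it stabilizes.* Most coordinates of a generated cell are
epoch-independent medians, and the adversarial model only covers the marker
block, so the augmented reference depends far less on GAN training length
than whole-transcriptome generation.

## Deconvolution and evaluation

The baseline deconvolver builds the signature as the per-cell-type mean of
per-cell CPM profiles pooled over all subjects (real and generated), solves
non-negative least squares per CPM-scaled mixture and renormalizes to the
simplex.  Genes are matched by inner join; there is no marker pre-filtering
at deconvolution time.  Published subject-aware methods (SCDC, MuSiC,
BisqueRNA) are *not* re-implemented; `read_external_proportions` accepts a
cell-type × mixture CSV from any external tool so they can be plugged into
the same evaluation.

Metrics: RMSE per mixture (across types) and overall; Pearson correlation
per cell type (across mixtures) and over all entries.  An undefined
correlation (constant vector) is reported as missing with a warning, never
coerced to 0.  Augmented and control runs are compared by a two-sided
paired t-test; the pairing unit is per-mixture RMSE (1000 pairs at the
default mixture count) and is recorded in the report.  Identical inputs
return t = 0, p = 1; constant non-zero differences are a degenerate-pairing
error rather than a spurious p-value.  The grid search sweeps training
epochs (50–300 by 50) × generated cells per type (100–1000 by 100) and
preserves partial results if a grid point fails.

## Synthetic data

`make_synthetic` draws, per gene, a base mean log-uniform in
`nb_mean_range` (default 0.5–50); planted marker genes (default 20% of
genes, split evenly across types) get a `marker_fold` (default 4×) up-shift
in their type; each subject multiplies every gene by a log-normal effect
with log-sd `subject_sigma`; counts are negative binomial with a shared
dispersion (default 0.3, variance μ + 0.3 μ²).  The first genes carry
mitochondrial/ribosomal prefixes (2% / 5%) for QC testing, and library-size
outlier cells can be planted.  All parameters are recorded in a
`GroundTruth` that also yields exact expected-CPM signatures per subject.

Defaults (500 genes, 5 types × 120 cells, 4 subjects, σ = 0.3–0.6)
emulate a small multi-donor study: big enough that every pipeline stage has
signal, small enough that the full benchmark suite runs in minutes on one
CPU.  The generator deliberately omits platform-specific noise, zero
inflation beyond the NB, doublets and cell-size differences, so passing
benchmarks demonstrate correctness of the pipeline and the direction of the
subject-heterogeneity effect — not real-data performance parity.

## What the benchmark shows, and limits

With subject heterogeneity at σ = 0.6 and 2 reference vs 2 target subjects,
control deconvolution degrades markedly (RMSE ≈ 0.12–0.18 vs ≈ 0.02 with no
heterogeneity), and sc-CMGAN augmentation lowers mean per-mixture RMSE on
most fixture seeds.  The effect is a regularization trade-off: augmented
cells pull the signature toward marker-emphasized per-type prototypes,
which helps precisely when the reference is far from the target subjects
and can slightly hurt when it is already close.  Under the NNLS baseline
the mean effect is small (|ΔRMSE| of order 0.005), so the per-seed win
fraction fluctuates between seed families (≈ 0.4–0.8 over 10-seed
batches); a subject-aware deconvolver is expected to benefit more, since
it can exploit the generated cells as an additional reference case rather
than only through the pooled signature mean.

Epoch sensitivity is measured at the 300-cells-per-type comparison point.
The stepwise method shows no systematic epoch drift (its across-epoch
spread equals its across-seed sampling noise), whereas the plain GAN's
spread exceeds its sampling noise.  However, the mean-calibrated, EMA-
averaged GAN used here is itself far more epoch-stable than published
tabular GANs, so the *total*-spread comparison between the two arms is
often within sampling noise rather than a clear ordering — an honest
limitation of testing an epoch-stability claim against an already-stable
baseline.

Other known limitations: the NNLS baseline has no subject-level modeling,
so improvements reported by subject-aware deconvolvers on real data are not
directly comparable; preprocessing QC is one-pass (see above); generator
models are not serialized.
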
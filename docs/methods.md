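# Methods

`methewas` implements an epigenome-wide association study (EWAS) of a
binary prenatal exposure on Illumina 450K-style DNA-methylation data,
together with a synthetic cohort generator so the whole chain can be
exercised, tested and benchmarked entirely offline.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic data do and do not establish about behaviour on real arrays.

## Measurement model

A probe's methylation state is summarized as the beta-value

    beta = M / (M + U + 100)

where M and U are the methylated- and unmethylated-allele intensities and
the offset of 100 regularizes low-intensity probes.  Beta is interpretable
as the fraction of methylated copies (0 = unmethylated, 1 = methylated).
Regression is run on M-values,

    m = log2(beta / (1 - beta)),

which are closer to homoscedastic across the beta range; beta is clipped
to [1e-6, 1 - 1e-6] before the logit so the transform is total, and the
round trip beta -> m -> beta is identity to 1e-12 inside that interval.

## Quality control and normalization

The preprocessing chain runs in a fixed order: detection/bead filtering,
colour-bias correction, background subtraction, beta computation, BMIQ,
cross-reactive probe removal, M-value transform.

**Detection p-values.** Per sample, the summed red+green signal of the
negative-control probes defines a background distribution with mean mu and
SD sigma; a probe's detection p is `1 - Phi((M + U - mu) / sigma)`.  The
platform literature does not fix a single convention; the z-test on summed
signal is the common default and is what is implemented.  Degenerate
controls (sigma = 0) are an error.

**Filters.** Measurement cells with fewer than 3 functional beads or
detection p > 0.01 are masked; samples with fewer than 80% unmasked cells
are dropped; probes masked in more than 5% of retained samples are then
dropped outright.  The 3-bead, 0.01 and 80% values are the conventional
choices; the 5% probe-drop rule is this package's own addition so that
per-CpG regressions keep close to the full sample size while systematically
failing probes disappear.  All counts are logged.  Probes on X and Y and
probes near SNPs are deliberately *not* filtered anywhere in the chain.

**Colour-bias correction.** Per sample, the pooled red-channel and
green-channel probe signals (type I probes contribute both alleles to
their design channel; type II probes contribute the unmethylated signal to
red and the methylated to green) define two empirical quantile functions.
Each channel is mapped onto the pointwise mean of the two by monotone
linear interpolation on a 1000-point grid — the interpolation provides the
smoothing.  Only type I probe signals are remapped (a type I beta uses two
signals from the *same* channel, so between-channel bias would otherwise
distort type I and type II probes differently); type II signals enter the
pools but are left untouched, and negative controls are passed through the
same per-channel map so background subtraction stays consistent.

**Background subtraction.** The per-sample, per-channel *median*
negative-control signal (median for robustness) is subtracted, flooring at
1.0 to keep later ratios positive.

**BMIQ.** Type II probes are systematically compressed toward 0.5
relative to type I.  Beta-mixture quantile normalization fits, per sample
and per design class, a three-component beta mixture with states U
(unmethylated), H (hemimethylated), M (methylated).  Type II probes are
assigned to their maximum-responsibility state; U-state values are mapped
through the fitted type II U-component CDF and the inverse type I
U-component CDF, M-state values analogously, and H-state values by a
linear dilation that carries the interval between the maximal transformed
U value and the minimal transformed M value onto the corresponding type I
span.  Outputs are clipped to [0, 1]; rank order is preserved within each
state.

EM details: initialization assigns beta < 0.25 to U, beta > 0.75 to M,
the rest to H.  The M-step moment-matches each component from the
responsibility-weighted mean and variance and then refines (a, b) by a
truncated Newton step on the weighted beta log-likelihood (digamma
equations).  Pure moment matching is not an ascent step and in practice
either stalls the likelihood or oscillates; the Newton refinement makes
the loop a generalized EM whose log-likelihood trace is non-decreasing (a
safety check stops the fit, keeping the previous parameters, if an update
would ever lower it).  Convergence is declared when the log-likelihood
changes by less than max(1e-5 relative, 5e-5 per observation); max 100
iterations.  For speed each mixture is fit on at most 2000 evenly spaced
order statistics of the class — a deterministic, distribution-preserving
subsample — and then applied to all probes.  A sample whose fit fails to
converge, or whose U or M state is empty, falls back to the identity
transform with a warning; at default simulation scale this does not occur.

## Cell-type deconvolution

Blood is a mixture of leukocyte types with distinct methylomes, and
exposure-associated shifts in composition masquerade as methylation
differences, so the six major white-cell fractions (CD4+ T, CD8+ T, B,
NK, monocytes, granulocytes) are estimated and adjusted for.  Given a
reference profile F (sites x 6 mean betas from purified cells) and a
sample's observed betas y at those sites, the fractions solve

    w = argmin ||y - F w||^2   subject to  w >= 0,

by nonnegative least squares — constrained projection with *no* sum-to-one
constraint, so totals are free and in practice land near 1.  Sites missing
for a sample are dropped row-wise for that sample; fewer than 50% of
reference sites available is an error.  Site selection keeps the k = 500
sites with the largest between-cell-type variance of the profile means
over a nominal residual variance of 0.01 (the reference table carries
means only, so this deterministic surrogate stands in for a replicate-based
F statistic); ties break toward the lower probe id.

## Batch adjustment and the regression model

Technical variation is absorbed by principal components of the built-in
control probes: control signals are log2-transformed (raw, not
normalized — the PCs should capture exactly the technical variation that
normalization may or may not remove), each control-probe row is centred,
and the first k = 30 sample-score vectors from an SVD enter the design.
Requesting more components than the matrix rank returns the rank with a
warning.

Per CpG, ordinary least squares regresses the M-value on: intercept;
exposure (0/1, the predictor of interest); sex; age in months; study
centre (DE/IT/ES indicators against reference BE); maternal education
(middle/high against low); postnatal maternal and paternal smoking; the
six cell fractions; and the 30 control-probe PCs — 47 columns in the full
design.  Samples with missing exposure (exposed only before gestational
week 12 — a group deliberately coded missing rather than assigned to
either arm) are excluded; remaining covariate missingness is handled
complete-case, as is per-probe outcome missingness.  Constant or collinear
design columns are pruned with a warning (protecting intercept and
exposure) so degenerate small cohorts still run.  The exposure
coefficient's two-sided p comes from the t distribution with df = (probe's
complete cases) - (columns); probes with fewer than columns + 5 complete
cases are skipped and logged.

A companion OLS of the *beta*-values on the identical design yields the
adjusted beta-scale difference (and SE) reported in top tables — the
simplest construction of an "adjusted mean difference in percent
methylation"; back-transforming the M coefficient is deliberately not used
because its value depends on the probe's baseline.

Implementation note: the per-probe normal equations are obtained by
downdating the full-design Gram matrix by each probe's few missing rows,
so 20000 probes x 47 columns fit in roughly a second on one core.

Multiple testing uses Benjamini–Hochberg step-up q-values (q_(i) =
min over j >= i of m p_(j) / j, capped at 1); epigenome-wide significance
is q < 0.05.  Calibration is summarized by the genomic-inflation factor

    lambda = median(Q_chi2_1(1 - p)) / 0.4549364,

the median association chi-square over its null median.  The pipeline
reports lambda for a cell-mixture-only model, a cell+PC model and the full
model; on confounded synthetic cohorts the full model orders strictly
below the cell-only model, reproducing the qualitative ladder a real
analysis shows.  Volcano (effect vs -log10 p) and QQ series are emitted as
tables, with optional matplotlib rendering.

## The synthetic cohort generator

The generator emulates the structure of a multicentre European child
cohort: 308 unexposed and 58 exposed children plus 18 early-only
exposures (coded missing and excluded from analysis), laid out on 33
slides x 12 arrays at random.  Categorical covariates (sex, centre,
maternal education, postnatal smoking, feeding mode) are assigned by
exact largest-remainder counts from the published per-group marginals
rather than iid draws — generated tables then match the target marginals
by construction, which removes an irrelevant source of Monte-Carlo noise
from every downstream test; continuous covariates (age ~ N(66.4, 0.8)
months, birthweight by sex and group) are Normal draws.

True methylation: 500 designated reference sites take their betas from a
Dirichlet cell mixture (alpha = (6.0, 3.6, 2.4, 1.5, 2.1, 14.4), i.e.
granulocyte-dominated child blood) times a generated purified-cell
profile; all other probes draw a baseline from a symmetric
low/mid/high mixture (42.5% Beta(2,18), 15% Beta(5,5), 42.5% Beta(18,2) —
symmetric so the red and green signal pools share a distribution and
colour correction removes bias only).  On the M scale each probe receives
per-covariate random effects (SDs 0.01–0.12 per design column, giving the
covariate confounding the lambda ladder needs), a per-slide batch effect
(loading SD 0.08), and residual noise (SD 0.5).  The five planted
exposure effects (+0.09, -0.02, +0.05, +0.04, +0.04 on the beta scale, in
that rank order) are added *after* the noise, on the beta scale, to
exposed samples only, at five designated type I probes — type I because
BMIQ maps type II onto the type I scale, so planting on type I keeps the
recovered beta-scale difference directly comparable to the planted value.
Unexposed baselines at those probes are 0.35, 0.045, 0.13, 0.10, 0.10:
the smaller effects sit near the unmethylated boundary where residual
variance is low, so that all five effects are detectable at n = 366 with
association z-scores around 6–8, matching a study in which all five
survive FDR correction (and mirroring the published pattern of a tiny SE
for the hypomethylated probe).

Signals: total intensity T ~ LogNormal(log 1e4, 0.3); meth = T*beta + B,
unmeth = T*(1-beta) + B with background B ~ N(200 + slide shift, 40) and
per-slide shift ~ N(0, 25) shared with the negative controls (600 of
them, per channel), so control-probe PCA can see the batch; per-sample
channel bias ~ LogNormal(0, 0.05) multiplies everything read in that
channel; type II probes are compressed toward 0.5 by a factor 0.12 before
signal mapping so BMIQ has real work.  0.5% of probe x sample cells fail
(background-only in both channels) and 0.2% get < 3 beads.  A
`noise_free_variant()` keeps the background distribution on the controls
but makes probe signals exact — used by chain-identity and QC-exactness
tests.  Everything is deterministic under the config seed, with separate
derived streams for sheet, manifest, reference and intensities.

What the generator does *not* emulate: genome-wide correlation between
neighbouring CpGs, SNP-affected probes, sex-chromosome dosage, dye-swap
chemistry detail, or realistic per-probe variance heterogeneity beyond
the beta-binomial-like mean-variance link induced by the logit noise.
Passing tests therefore establish internal consistency of the pipeline
(each stage inverts the artifact the generator planted for it, effects
are recovered without bias, error rates calibrate) — not performance on
any real cohort.

## Default problem sizes

Simulations default to 20000 probes x 384 arrays rather than full array
scale; all operators are dimension-agnostic and probes are processed as
matrices, so full-scale input is a memory/time multiple, not a code path
change.  The replication study behind the headline numbers
(`planted_effect_replicates`) runs 20 such pipelines; unit and property
tests use cohorts of 84–384 samples and 500–5000 probes.

## Known limitations

- The beta-scale effect is a linear-model difference; for probes near 0
  or 1 a fraction-scale OLS can in principle predict outside [0, 1].
- BMIQ's H-state dilation is linear; heavily distorted type II
  distributions whose hemimethylated mass dominates are corrected only
  partially (the realistic ~15% H fraction is handled well).
- The detection-p and probe-drop conventions are reasonable defaults, not
  the only ones in use; both are parameters.
- Cell-fraction estimates inherit any mismatch between the reference
  profile and the cohort's true cell methylomes; the generator shares one
  profile between truth and estimation, which is optimistic relative to
  real data.
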
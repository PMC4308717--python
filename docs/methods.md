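# Methods

This note documents the statistical models implemented in `xconstraint`,
the synthetic panels they are validated on, the numerical choices, and what
the validation does and does not establish about real data.

## Dynamic range and the constrained-gene call

For an orthologue pair, all npIDR-filtered biosample RPKM values of both
species are pooled; DNR = log10(max) − log10(min) over the non-zero values,
defined only with ≥ 2 detections per species (a single detection carries no
range information). Zeros are *not* replaced before the DNR — they mean
"reproducibly undetected" and are excluded — whereas the ANOVA and
ratio-type statistics replace zeros by an effective floor of 1e-3 RPKM
before taking logs. Averages are taken on the linear RPKM scale first and
log-transformed afterwards (`average_log_expression`), so a gene's level is
log10 of its mean expression, not the mean of its log levels.

The DNR distribution is decomposed into two Gaussians by EM
(scikit-learn, k-means++ initialization, 10 restarts, fixed seed, variance
floor `reg_covar` = 1e-4 to keep the narrow constrained component from
collapsing). The classification threshold is the root of
w1·N(x; μ1, σ1²) = w2·N(x; μ2, σ2²) between the two means, obtained
analytically from the quadratic in x and refined by Brent's method to 1e-6.
With equal weights and variances this is exactly the midpoint of the means.
A caller may override the fitted threshold with a fixed cutoff (e.g. 2.0).
When no root lies between the means (extreme weight imbalance) the fit
raises, reporting both analytic roots, rather than inventing a cutoff.

**Expression matching.** The constrained/unconstrained comparison sets are
built on a bins×bins (default 10×10) grid of per-species expression
quantiles; each cell contributes min(#constrained, #unconstrained) genes
sampled without replacement (seeded). This equalizes the joint expression
distribution at cell resolution — a deliberate, simple stand-in for finer
matching procedures; the tests verify the result by a two-sample KS
statistic ≤ 0.05 per species.

## npIDR

The estimator: elements detected (signal > 0) in at least one replicate are
assigned to 20 log-spaced bins of max(rep1, rep2) (binning by the mean is a
config option); bins with fewer than 25 elements merge upward into their
higher-signal neighbour; a bin's discordance is the fraction of its
elements with exactly one zero replicate; monotonicity (reproducibility
cannot worsen with signal) is enforced by a cumulative minimum from the
low-signal end upward; elements absent from both replicates score 1. Ties
at bin edges fall to the lower bin; everything is deterministic and
seedless. Under independent per-replicate detection with probability p at
fixed signal, the discordance among *detectable* elements is
2(1−p)/(2−p) — e.g. 2/3 at p = 0.5 — because elements missing from both
replicates never enter a signal bin; the property tests assert this
conditional value. Filtering follows the consortium rule: per biosample the
replicate mean is kept where npIDR ≤ 0.1, otherwise the value is set to 0.

## Intron-centric splicing metrics

ψ5, ψ3, pooled ψ and θ are computed exactly as defined in the README, with
`min_count` = 10 on the relevant denominator: estimates from fewer reads
are reported NA, not 0 (a proportion from a handful of reads is noise).
For the pooled ψ both side denominators must individually reach
`min_count`; otherwise a junction unique at both sites would pass the gate
merely because its two identical denominators are summed. The sample
variance of ψ uses the unbiased (n−1) estimator, and the Bernoulli bound
uses the pooled mean m. The constitutive calls require every usable sample
of both species (≥ 2 per species) to clear the 0.85 / 0.15 cutoffs; the
constrained-inclusion flag applies only to variable junctions with
m ∈ (0.15, 0.85) and var(ψ) ≤ 0.2·m(1−m); both interval and fraction are
configurable (a wider (0.1, 0.9) interval is sometimes quoted — the
narrower interval is the default here). Concordance between species
correlates logit-transformed mean ψ (clipped to [1e-3, 1−1e-3]) over
orthologous junctions, excluding junctions at constant complete inclusion
or exclusion.

## Vls/Vt

Transcript abundances of a gene are square-root rescaled (tempering extreme
major isoforms) and each sample becomes a point Y_s ∈ R^T. "Constant
splicing" means fixed isoform proportions at varying total expression,
which is a ray through the origin; its direction u is the normalized mean
of the per-sample unit vectors Y_s/‖Y_s‖ (all-zero samples excluded from u,
retained in the variances). Vls is the variance of the scalar projections
Y_s·u about their mean, Vt the total variance of Y_s about the centroid;
the ratio is clipped to [0, 1] against floating-point underflow.
Single-transcript genes and degenerate zero-variance data are 1 by
convention (no splicing dimension to explain anything). Outlier samples
are mitigated by a bootstrap over samples (default B = 100, seeded;
resamples with < 3 distinct samples or zero total variance are redrawn, at
most 10·B attempts) summarized by the median and IQR. Anchoring the ray at
the origin rather than the centroid is a design choice: the centroid of
log-scale-heterogeneous samples is not a constant-splicing state, the
origin is.

## Genome signal

"Read density" is mean per-nucleotide coverage (length-free,
bedGraph-native), computed by interval arithmetic, not per-base expansion.
Cross-species bin correlations are Pearson on log10(density + pseudo) with
pseudo = 1e-2 (configurable); strata with < 3 pairs report NA. Metagene
profiles extract strand-oriented ±500 nt windows around the TSS (or TTS);
for a − strand gene the window is (tss−500, tss+500] reversed, so genomic
tss−o maps to transcriptional offset +o on both strands. Per mark, windows
are normalized to the maximum signal across *all* genes, then averaged over
the gene group and across samples — doubling all coverage leaves the
profile unchanged and its maximum never exceeds 1. Mark divergence per
orthologue is |log10(s1+1) − log10(s2+1)| of mean window signal (pseudo 1
for read-count-scale signals).

## The synthetic panels

Defaults are a deliberate scale-down of a two-species consortium panel:
2 species × 20 biosamples × 5,000 orthologues, two replicates each; 2,000
junctions × 30 samples per species at Poisson depth 50; 200 isoform genes
× 10 samples; 10,000 orthologous 100-nt bins; 200 TSS mark profiles. The
full pipeline runs in well under a minute at these sizes, and every
generator is a pure function of (config, seed).

**Expression.** Orthologues share a per-gene log10 baseline across species.
Constrained genes (45% of the panel, matching the roughly balanced
constrained share of range-defined orthologues in such data) draw baselines
from N(1.5, 0.75²) and per-sample deviations from U(−r/2, r/2) with
r = 1.0, bounding their true range below 2 by construction. Unconstrained
genes draw baselines from N(1.2, 0.9²) and Gaussian tissue effects with
s.d. 1.0, whose range across 40 samples is ≈ 4.3 in expectation. Replicates
multiply truth by lognormal noise (0.1 in log10) and drop out with a
logistic probability, 50% at 10^-1.5 RPKM with slope 2. The dropout
midpoint and the unconstrained baseline were chosen together so that the
detection floor does not censor the unconstrained minima into the
constrained mode: with npIDR ≤ 0.1, values below roughly
midpoint + ln(19)/slope ≈ 0 log10 RPKM are zeroed, so an unconstrained
gene's measured range stays well above the threshold unless its baseline
is ≈ 2.5 s.d. below the mean. The induced measured-DNR distribution is
strongly bimodal (Ashman's D > 2) and mixture classification recovers truth
for ≈ 98% of defined genes.

**Junctions.** Each panel junction has one alternative-acceptor and one
alternative-donor partner carrying the complementary counts, so its pooled
ψ estimates the true inclusion directly. Classes: constitutive high
(ψ* ∈ (0.92, 0.995), constant, shared across species), constitutive low
(ψ* ∈ (0.005, 0.08)), constrained intermediate (constant
ψ* ∈ (0.2, 0.8) shared across species), variable (per-sample
Beta(0.5, 0.5), variance 0.125 — far above the 20% Bernoulli bound).
Boundary reads are Poisson with mean split·(1−θ*)/θ*, θ* ~ U(0.7, 0.99).
At depth 50 the strict all-samples constitutive rules are only ~70%
sensitive — an honest property of thresholding 60 binomial proportions,
not a defect; the constrained-inclusion flag reaches ≥ 99% detection with
no false flags among variable junctions.

**Isoforms.** Expression-driven genes keep one Dirichlet(0.8) proportion
vector across samples; splicing-driven genes redraw it per sample. Totals
are 10^N(1, 0.2) in both regimes — a modest (~2.5-fold) total-expression
spread, chosen so that, in the splicing-driven regime, proportion
resampling rather than total variation dominates the variance (at larger
total spreads the ray direction absorbs most variance for *any* regime and
the two regimes blur). Measurement noise is lognormal, 0.02 in log10.

**Bins and marks.** Bin-pair log densities are bivariate normal
(mean 1, s.d. 0.5 in log10) with correlation
ρ = ρ_class · exp(−distance/20 kb), ρ_class = 0.85/0.70/0.55 for
exonic/intronic/intergenic, genic bins at distance 0; a flat-kernel
configuration exists for calibration checks. Mark tracks place 200 genes of
alternating strand on a toy chromosome at 3 kb spacing; each gene's signal
is an amplitude 10^N(1, 0.5) times a Gaussian kernel (s.d. 150 nt) at the
TSS; half the genes share the amplitude across species, half draw
independently.

**What the generator does not emulate.** Read-level sampling (fragment
biases, mappability), annotation errors, correlated dropout between
replicates, inter-gene correlation, isoform-count variation beyond T ≤ 5,
matched biological conditions between species, and any real genome
sequence. Passing tests therefore certify the estimators and the pipeline
logic under the stated stochastic models, not performance on any particular
real dataset; headline quantities that depend on the expression scale
composition of a panel (e.g. the output fraction captured by constrained
genes) are generator-specific.

## Numerical choices and degenerate inputs

Coordinates are 0-based half-open internally (GTF converted at the
boundary); exonic > intronic > intergenic precedence in the genome
partition; strand-agnostic partition labels (antisense analyses use
stranded inputs separately). Matrix TSVs print with %.6g and NA for
missing, which makes write∘read∘write byte-stable — the end-to-end
determinism guarantee relies on it. Empty annotation files, all-zero
replicate panels, samples without expression, genes absent from one matrix,
and junctions with too few usable samples all have defined behaviour
(empty result, error, NA, warning + skip, "unclassified" respectively)
exercised by the unit tests.
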
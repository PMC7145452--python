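# Methods

This note records the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic data do and do not
emulate, and the numerical decisions that matter for reproducing the
results.

## Synthetic study design

The generators emulate a mouse amyloid time-course crossed with a human
GWAS, with every planted signal recorded in a truth sidecar.

**Design.** Three genotypes (wild type, hemizygous, homozygous
transgenic) x five ages (2, 4, 8, 12, 18 months) x four replicates = 60
samples.  Plaque load follows a saturating curve
`plateau * (1 - exp(-rate * (age - onset)))` per genotype: homozygotes
start at 4 months (rate 0.25/month, plateau 1.0), hemizygotes at 6
months (rate 0.18, plateau 0.7), wild type identically zero.  A
microglial cell-number factor rises with plaque to 3.7x at full load —
the magnitude reported for hippocampal microglia at 18 months in
homozygous amyloid mice.

**Expression.** A planted module of 150 genes (of 5000) has expected
abundance `baseline * cell_number_factor * (1 + beta(age) * plaque)`.
Ten *direct responders* carry `beta ~ 1.8`, which compounds with the
cell-number factor to ~10x fold change at 18 months; ten
*early-transient* genes carry a Gaussian-in-age amplitude peaking at 8
months (~4x, amyloid-gated so it vanishes wherever plaque is zero); the
remaining 130 track cell number only.  A per-sample log-normal
fluctuation (sd 0.1) shared by all module genes models animal-to-animal
variation in microglial number; residual noise is log-normal with sd
0.15, a typical biological coefficient of variation for
well-expressed genes.  Background genes load on 150 latent factors
with Zipf-weighted sizes, heterogeneous strengths (U(0.2, 0.8)) and 35%
unloaded genes — chosen so the connectivity spectrum is heavy-tailed
and the scale-free fit index behaves as it does on real transcriptomes
(R^2 ~ 0.9 at soft powers 7–8 on the default bundle).  One factor
drives the tau_load covariate, giving the tau-trait analysis a genuine
(non-amyloid) module to find.

**Genetics.** Human orthologues arise by name transformation with 8%
unmapped and 4% many-to-one entries.  Gene spans are laid on 20
chromosomes with most neighbours 0.8–2 Mb apart and ~15% forming
sub-0.5 Mb clusters (so proximity collapsing has real work).  Each gene
carries one LD block of 4–12 SNPs; haplotypes are exchangeable within a
block (each SNP copies a block ancestral allele with probability
sqrt(r), target r = 0.6) over 500 haplotypes.  GWAS z-scores are drawn
from MVN(mu, R_hat) where R_hat is the *realized* LD of the generated
panel and mu is non-zero (+-6) only at planted causal SNPs — two per
causal gene, the causal genes being 10 of the 150 module orthologues by
default.  Effect sizes and standard errors are emitted on the
case-control scale for a notional 60 000-sample study.  eQTL tables
place their causal variant at a designated SNP, shared or not with the
disease signal.

**What the generator does not emulate:** read-level counts and library
normalization (noise is log-normal multiplicative, preserving the
fold-change semantics the analysis consumes), realistic human LD maps
(blocks are exchangeable and independent), population stratification,
and case/control genotype sampling (association is simulated at the
z-score level, which is what the downstream statistics consume).
Passing tests therefore validate the statistical machinery and its
calibration under block LD, not robustness to, e.g., long-range LD or
count-model misspecification.

## Network stage

Unsigned adjacency `|cor|^beta` (signed-hybrid available), Pearson
correlation, zero-variance genes a hard error.  The soft threshold is
the smallest candidate (1–20) whose signed scale-free fit R^2 reaches
0.85, falling back to the best-fitting power with a warning.  Modules
come from average-linkage clustering of `1 - TOM` with a *static* cut
(default height 0.995), minimum size 30, and iterative merging of
modules whose eigengenes correlate above 0.75 — a deterministic
simplification of dynamic tree cutting that is sufficient for planted
block structure; ties in the all-equal-TOM degenerate case yield a
single module.  The amyloid module is the one whose eigengene best
correlates with plaque load.  Default pre-filtering keeps genes with
mean abundance >= 1 and the top 2000 by log-expression variance.

## Gene-based association

SNP p-values are genomic-control corrected genome-wide first
(chi-squares divided by lambda only when lambda > 1), then assigned to
gene spans (closed intervals; default flank 0 bp — flanking made little
difference in the source analyses — with a flank option).  Per gene,
the LD correlation matrix of allele dosages comes from the reference
panel; SNPs absent from the panel are dropped with a logged count, and
all-monomorphic genes are skipped.

The combined statistic is Fisher's `X = -2 sum(log p_i)`.  Its null
under LD is computed by conditional convolution: SNPs in near-perfect
LD (|r| > 0.999) are merged (their terms add deterministically, which
makes the perfect-LD collapse exact: two identical SNPs give back the
SNP p-value); near-independent components (|r| < 0.05) are convolved
independently; within a component a low-rank factor model
`R ~ L L' + diag(psi)` (one factor, two when the residual exceeds 0.12)
renders the z-scores conditionally independent, so the conditional
distribution of X is an FFT convolution of exactly computed bin masses,
integrated over Gauss–Hermite factor nodes (48–256 nodes, growing with
factor strength).  Two further corrections matter at the 1e-3 level:
the lattice is centred so the distribution's first moment equals the
exact `2k`, and the final distribution is rescaled around that mean by
the ratio of analytic variances under the true versus the factor-model
LD (using a quadrature-fitted polynomial for
`cov(-2 log p_i, -2 log p_j)` as a function of r), which absorbs the
correlation a single factor cannot represent.  The grid spans X in
[0, 655] at spacing 0.08; reported p-values are clamped to
[1e-15, 1].

Measured calibration: on realized block LD (k <= 12, r in [0.1, 0.9]),
empirical type-I error is within Monte-Carlo noise of nominal at alpha
= 0.05 and 0.01 (residual bias ~ +0.0002 at alpha = 0.05, measured with
1.6M draws); the independence case reproduces Fisher's closed form to
four decimals.

The classical Brown approximation — X referred to `c * chi2_f` with
moments from the Kost–McDermott covariance polynomial — is available
as `method="kost"` with the rho transform (|r| or r^2) switchable.  Two
caveats, verified numerically: the polynomial was derived for
one-sided tests, and with two-sided p-values the |r| transform
overstates the covariance several-fold at low LD (conservative test),
while r^2 understates it slightly (anti-conservative); and no
two-moment fit calibrates to three decimals in the weak-LD regime.
Hence the convolution default.

The best SNP per gene is reported for completeness and never feeds the
gene p-value.

## Enrichment

Mouse module genes are mapped to human symbols (unmapped dropped and
counted, many-to-one deduplicated).  Genes whose span midpoints lie
within 0.5 Mb are chained transitively per chromosome into one group
(midpoint distance rather than span-edge distance; the representative
carries the group's minimum p, the conservative direction).  The
Z-test compares the observed count of groups significant at alpha with
expectation `N*alpha` and variance `N*alpha*(1-alpha)`, one-sided; an
exact binomial p is reported alongside.  The two agree within an order
of magnitude while the observed count is within ~3 SD of expectation;
in the deep tail the normal approximation is badly anti-conservative
(e.g. N = 200, alpha = 0.01, k = 8: Z-p = 1.0e-5 versus exact 1.1e-3),
which is why both numbers are emitted.  A related discreteness effect
sets the smallest meaningful set size for *calibration* experiments:
at N = 150 the rejection rule "k >= 12" has exact null probability
0.074 at nominal 0.05 regardless of how well the gene p-values are
calibrated, so the calibration experiment uses N = 300 (exact 0.0486);
the power experiment keeps N = 150.

Established-locus exclusion removes genes overlapping +-0.5 Mb windows
around supplied top SNPs plus the fixed APOE (chr19:44.5–46.5 Mb) and
HLA (chr6:32.2–32.8 Mb) windows.  Candidates at alpha = 0.01 are split
into established (listed or inside an exclusion window) versus novel.

## Trajectories

Fold change is the linear-scale ratio of group means versus age-matched
wild type, with percentile-bootstrap intervals over animal resampling
(default 2000 seeded resamples; percentile levels expanded by the
t-correction for the small group sizes, which restores ~95% coverage
that plain percentiles lose at 4 animals).  The network-average fold
change is the geometric mean over module genes (fold changes are
ratio-scale; arithmetic mean by flag).

The gene-versus-network comparison does *not* use per-gene bootstrap
intervals: with 4 animals a per-gene sd estimate has ~40% sampling
error and the resample space is too coarse for 1–2% tails.  Instead
the replicate variance is pooled across all module genes after removing
gene and sample effects (two-way centering, so fluctuations shared by
all genes of an animal — e.g. its microglial content — cancel exactly
as they do in the ratio), giving the test ~450 degrees of freedom.  A
gene is "above the network" at an age when its log fold-change,
relative to the network average, exceeds a one-sided z-test bound at
the 2% level; the test is evaluated only at ages with non-zero plaque
(there is nothing to respond to before onset, and testing flat ages
only adds multiplicity).  Labels: *direct amyloid* = above the network
at the final age and fold change exceeding the 3.7x cell-number
reference; *early transient* = above at the heavy-plaque onset age
(default 8 months) but not at the final age; *proliferation tracking* =
never above and consistent with the network average at the final age
(a deliberately weak 99.9% consistency band — its only job is to
separate tracking genes from clearly divergent ones); otherwise
*unclassified*.  On the default bundle this labels >= 96% of planted
genes correctly across seeds (direct responders essentially always;
early-transient genes are the power-limited class at ~4x versus a ~3x
network average with 4 animals per group).

## Colocalization

Per-SNP evidence is the Wakefield log approximate Bayes factor
`0.5*log(1-r) + 0.5*z^2*r` with `r = W/(V+W)`; prior effect sds default
to 0.15 (case-control) and 0.20 (quantitative eQTL), and priors
p1 = p2 = 1e-4, p12 = 1e-5 — the conventional single-causal-variant
settings, configurable.  The five-hypothesis enumeration runs in log
space with log-sum-exp (safe to |z| = 40); with one SNP the
two-distinct-variants hypothesis is exactly impossible and gets mass
zero.  When a table lacks standard errors they are back-derived from
the effect and p-value and flagged.  The gene-list overlap test is the
one-sided hypergeometric tail with Bonferroni correction.

## Problem sizes used by the validation suite

Chosen to exercise each method at the scale its approximations must
hold: combined-test calibration uses 20 realized LD structures x 1e5
null draws (binomial 99% CI half-widths 0.0018 / 0.0008; with 40 CI
checks ~0.4 boundary misses are expected by chance, so up to 2 are
tolerated while the worst absolute deviation stays bounded);
oracle agreement uses 20 non-null cases x 1e5 draws (+-3 SE);
enrichment calibration 1000 replicates on a 600-gene genome (300-gene
network), power 100 replicates with 10 of 150 network orthologues
causal; collapsing 1000 random layouts against a union-find oracle;
module recovery on the full default bundle (5000 x 60); colocalization
200 shared- and 200 distinct-causal simulations on a 50-SNP region of
five LD blocks; trajectory classification on the full default bundle;
determinism on a 600-gene end-to-end double run.  The whole suite
completes in a few minutes on one CPU.

## Known limitations

The convolution null's residual error is ~2e-4 in tail probability and
up to ~3e-3 in the middle of the distribution for strongly multi-factor
LD (it is exact for rank-1 LD); p-values below 1e-15 are clamped.  The
static tree cut can split very weakly separated modules that dynamic
cutting would keep together.  The enrichment Z-test inherits the
normal approximation's deep-tail anti-conservatism (use the reported
binomial p there).  Early-transient trajectory detection has ~80–90%
per-gene power at the default effect size and replicate count — a
property of the design's signal-to-noise, not of the estimator.  The
colocalization model assumes at most one causal variant per trait in
the region.
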
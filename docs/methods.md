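# Methods

`cushaw` re-implements, as a tested and reusable pipeline, the
post-variant-calling population-genomic analyses of a crop-domestication
study system: a wild squash taxon with two sub-lineages, a domesticated
taxon derived from one of them, secondary-contact gene flow between them,
a sister crop species used to polarize alleles and probe introgression,
and a deeper outgroup for ancestral-state calls.  Everything upstream of
the genotype matrix (read mapping, variant calling, genome assembly) is
out of scope; a coalescent synthetic-data generator stands in for the
study's raw data so that every stage is testable end to end.

## The synthetic-data generator

The generator is a structured coalescent implemented from scratch
(`cushaw._kernels`, numba-compiled).  Time runs backward in generations
(one generation = one calendar year for this annual species); haploid
lineages in a diploid deme of size N_e coalesce pairwise at rate
1/(2 N_e); backward per-lineage migration rates m[i][j] move lineages
between demes; population events are (time, source, destination,
fraction) tuples — fraction 1 is a clean split (the source deme is
retired), fraction < 1 an admixture pulse.  Gene-flow modes: `none`,
`continuous` (migration active until lineages merge into the common
ancestor), and `secondary_contact` (migration active only at times more
recent than `secondary_contact_end`).  Waiting times are exponential
(continuous-time approximation of discrete generations).

Mutations are infinite-sites, mapped to integer positions inside a locus
window with collisions resolved by rejection.  Two modes:

- `fixed_s`: one mutation per independent genealogy — unlinked SNPs,
  convenient for statistics that assume exchangeable sites;
- `rate`: Poisson(mu x locus_len x tree length) mutations per genealogy —
  linked SNPs within a reduced-representation "tag", which is what the
  study's tGBS libraries produce and what carries absolute-rate
  information (defaults mu = 1e-8 per bp per generation, plant-typical;
  500 bp tags).

Calibration: pairwise TMRCA matches the closed form 2 N_e, segregating
sites match Watterson's expectation, the two-deme island model matches
the closed form 4N + 1/(2m), and means agree with msprime (the
independent implementation used only as a test oracle) within Monte-Carlo
error on fixed two-deme models.

Default demography of the domestication preset (`domestication_model`):
wild sizes 15,000, domesticate 8,000, ancestor 20,000 diploids; wild
lineages split 15,000 generations ago (late-Pleistocene, when the
megafaunal dispersers vanished), the domesticate 8,700 generations ago
(the earliest archaeological record); secondary contact over the last
2,000 generations with backward migration 2e-4 per lineage per generation
between the domesticate and its source deme (about a third of lineages
trace to a recent migrant — strong ongoing crop-wild gene flow) and 5e-5
to the far wild deme.  The sister species splits 1e6 generations ago, the
deeper outgroup 3e6.  These values were fixed a priori as the generator's
study conditions and are config-overridable; they are not fitted
quantities.

What the generator does **not** emulate: recombination within tags (sites
within a tag share one genealogy; tags are unlinked), sequencing and
genotyping error, allele dropout, reference bias, and selection dynamics
(spiked selected loci are a post-hoc frequency manipulation, not a
forward sweep).  Passing tests therefore demonstrate correctness of the
statistics under the stated coalescent model, not robustness to
real-data artifacts.

## Filters

The cascade order is fixed (the upstream tools leave it ambiguous): site
missingness (> 50% dropped), then sample missingness (> 50% dropped),
then minor-allele frequency (< 1% dropped, recomputed on the remaining
samples); each step's removals are reported.  The Hardy-Weinberg exact
test is the two-sided conditional test (sum of all heterozygote
configurations with probability not exceeding the observed one; no mid-p
variant), computed with log-gamma arithmetic and verified against exact
rational enumeration for every table with up to 30 genotypes.  LD
pruning is a greedy left-to-right scan: within a 100 kbp look-back
window the later-positioned member of any pair with r^2 > 0.25 is
removed; r^2 is the squared Pearson correlation of dosages
(genotype-based, as in plink) with pairwise-complete handling of missing
genotypes.  The step parameter is accepted for interface parity; a full
look-back is equivalent for any step no larger than the window.

## Diversity and structure

Per-SNP nucleotide diversity is the unbiased expected heterozygosity
n/(n-1) 2p(1-p), averaged over sites with at least two non-missing
alleles; this is the per-SNP convention (magnitudes ~0.1 on SNP panels),
not per-bp diversity.  F_ST is Weir & Cockerham (1984): variance
components a, b, c from genotype counts (observed heterozygosity enters
b and c), multilocus estimate as the ratio of sums, loci with zero total
variance skipped; confidence intervals are percentile bootstraps over
loci (100 replicates, 95%).  PCA uses Patterson scaling (centre 2p,
scale sqrt(2p(1-p))) with per-site mean imputation of missing dosages.

## Demographic inference

The observed statistic is the unfolded joint site-frequency spectrum
over (Jalisco-wild, Southern-wild, domesticated), polarized by the
sister-species outgroup: the ancestral allele is the one carried by a
monomorphic outgroup; sites with a polymorphic or missing outgroup are
dropped and counted; in-group complete cases only; the two monomorphic
corner cells are masked.

Expected spectra are estimated by simulation: the expected cell
proportions are pooled observable branch-length shares over many
independent genealogies (the Rao-Blackwellized version of dropping
mutations), with the simulation budget expressed as an equivalent SNP
count.  Crucially, the expectation is computed **with the outgroup
simulated and the same polarization rule applied** (drop
outgroup-polymorphic cells, flip outgroup-fixed-derived cells), so the
conditioning of observed and expected spectra matches exactly —
including the small mis-polarization rate.

The composite likelihood is multinomial over unmasked cells with
observed count >= 1 (the "minimum SFS count of 1" rule), natural log,
zero-expectation cells floored at 0.1/n_sim.  SFS *proportions* are
invariant to jointly rescaling all sizes, times, and inverse migration
rates, so absolute parameters need an anchor: when the data carry
mutation-rate information (rate-mode tags with known mu and surveyed
length), a Poisson term on the polarized-SNP yield,
S ln(lambda) - lambda with lambda = n_loci * u * E[observable tree
length], is added — the standard monomorphic-cell anchor.  Without it,
only parameter ratios are identified (`fixed_params` lets the user pin a
reference size instead).

Six scenarios are compared: {Jalisco origin, Southern origin} x {no
flow, continuous flow, secondary contact}, each with independent
directional migration rates between the domesticate and each wild deme
(wild-wild migration is not modelled).  Free parameters: four sizes, two
split times, plus four migration rates (flow models) and the contact
time (secondary contact); log-uniform priors T in [1e3, 2e5]
generations, N_e in [1e2, 6e4], m in [1e-4, 0.5]; the domesticated split
is constrained to be the most recent and the contact epoch to precede
it.

Fitting is a seeded multi-start plus local refinement: initial
log-uniform draws are augmented with method-of-moments starting points
(per-deme diversity -> N-hat through the anchor; between-deme divergence
-> T-hat), bracketed for the two biases that gene flow induces (the
domestication split estimate is biased recent, the domesticate's size
estimate biased large).  Each refinement cycle re-estimates the expected
SFS under a fresh common-random-number seed and runs a Nelder-Mead pass
in log-parameter space with an initial simplex that shrinks over cycles
(simultaneous moves are needed because the domestication split time and
the contact migration rates form a correlated ridge that single-
parameter steps cannot traverse); the two leading, mutually distant
starting points are refined and the better kept under one final common
seed; iteration stops early when a cycle improves the composite
log-likelihood by less than 0.001.  Defaults follow the study (40
cycles, up to 200,000 simulated SNPs per evaluation); the acceptance
experiments use the scaled-down setting of 5 cycles and 20,000 simulated
SNPs per evaluation with 800 tags (~2,000 polarized SNPs), 10 diploids
per in-group deme and 5 outgroup diploids, which this package's
recovery experiments show is sufficient to rank the generating scenario
first by AIC and recover sizes and split times within +-50% (median over
seeds).  Because each optimizer run reports its likelihood under its own
final Monte-Carlo draw, all best-fit parameter sets are re-scored under
one common seed and a denser tree budget before AIC comparison.
Replicate fits (`fit_model_replicates`) retain the runs above the 95%
point of the likelihood distribution and report the best.

## Selection scans

Three complementary tests with the domestication status (wild 0,
domesticated 1) as the environmental variable, and a consensus rule that
flags SNPs significant in at least two tests.

**F-model MCMC** (`bayescenv_scan`).  Hierarchical beta-binomial model:
population allele frequencies are beta-distributed around an ancestral
frequency pi_i with locus-by-population precision on the logit scale,
eta_ij = beta_j (neutral), beta_j + alpha_i (locus effect) or beta_j +
g_i E_j (environmental effect); F_ij = sigmoid(eta_ij) is the
locus-population differentiation parameter.  Per-locus model indicators
move through a product-space (Carlin-Chib) step with priors as
pseudo-priors, plus a locus<->env mode swap that exchanges alpha and g
(an involution with unit Jacobian) — without the swap the indicator
mixes poorly because a fitted locus effect cannot carry over to the
environmental model.  Priors: alpha, g ~ N(0, 3^2); beta_j ~ N(-1,
1.8^2); model prior odds 10:1 in favour of neutrality.  Pilot runs tune
proposal widths to 25-45% acceptance; two independent chains run, with
Gelman-Rubin diagnostics on the population effects and the
log-likelihood (threshold 1.1; non-convergence flags the result, it does
not silently pass).  q-values are running means of the sorted posterior
error probabilities of the environmental model; q < 0.05 flags a locus.
The environmental and locus models are only weakly distinguishable with
two populations (both add one parameter per locus); the test develops
its power in multi-population designs like the study's, which is how the
power experiments are configured.  Study-scale MCMC defaults (20 pilots
x 10,000; burn-in 100,000; 100,000 sampled, thinned by 20) are kept as
defaults; tests run shorter chains (6 x 250 pilots, 1,500 burn-in, 4,000
sampled, thin 10), at which the flagged sets are stable.

**PCA-Mahalanobis scan** (`pcadapt_scan`).  Scaled dosages are regressed
on the first K = 2 principal-component scores; the per-SNP t-statistics
are mapped through the t CDF to normal quantiles (at tens of samples the
raw t tails break the chi-squared calibration), combined into a robust
Mahalanobis distance (minimum covariance determinant when enough SNPs
are available, median/MAD otherwise), rescaled by the genomic inflation
factor (median D^2 over the chi-squared_K median), and converted to
Bonferroni-adjusted chi-squared_K p-values (cutoff 0.05).  Sites with
minor-allele frequency below 0.05 are excluded from the test — their
z-scores are too heavy-tailed for the calibration — and reported with
NaN p-values, mirroring the reference tool's default MAF screen.

**Latent-factor ridge scan** (`lfmm_scan`).  The covariate is projected
out of the centred genotype matrix; the top-K SVD factors of the
residual are the latent confounders (K = 6 in the study, chosen
externally; synthetic tests use the design's true dimension); effect
sizes come from a ridge regression (lambda = 1e-5) of the residualized
genotypes on the covariate; z-scores are recalibrated with the median
chi-squared_1 inflation factor and converted to Benjamini-Hochberg
q-values (cutoff 0.05).  With K = 0 and lambda -> 0 the statistic
reduces exactly to the per-SNP OLS z-score.  When the covariate is
perfectly collinear with the only axis of structure (a plain two-deme
design) the inflation factor absorbs real signal; the power experiments
therefore use a crossed design where geography and domestication status
are separate axes.

## Introgression

Frequency-weighted ABBA-BABA over the fixed (((P1 wild, P2 domesticate),
P3 sister), P4 outgroup) arrangement: D = sum(abba - baba) / sum(abba +
baba) with abba = (1-p1) p2 p3 (1-p4) and baba = p1 (1-p2) p3 (1-p4);
single genomes enter as frequencies in {0, 1/2, 1}.  Significance comes
from a weighted delete-one-block jackknife (contiguous equal-SNP blocks
by default; blocks weighted by their share of the denominator), with a
two-sided normal p on Z = D/SE.  f_G splits the P3 sample into random
halves per site (seeded hypergeometric) and divides the observed
ABBA-BABA excess by the excess expected if P2 were replaced by one P3
half.  Local D uses 500-SNP windows with step 250; a trailing partial
window is reported with its size.

Candidate classification polarizes each consensus SNP with the available
outgroups (each must be monomorphic; all must agree, otherwise
"unknown") and labels it from the derived frequencies in wild,
domesticate, and sister taxa with thresholds hi = 0.8 / lo = 0.2 (config
parameters — the underlying study states no numeric rule):
ABBA/BABA (sister shares the high-frequency derived allele) take
precedence over sel_domesticated/sel_wild; everything else is unknown.
Labels always partition the candidate set exactly.

## Structural variants

Two call sets (a whole-genome-alignment caller and a long-read caller)
are intersected per chromosome and type with the +-100 bp endpoint rule;
matching is one-to-one and greedy by smallest total endpoint offset
(ties by leftmost record); translocations must satisfy the rule at both
loci (a stricter choice than the rule's literal reading, documented
here); unaligned-region records bypass matching on a separate channel,
as only the alignment-based caller reports them.  Gene assignment uses
any overlap for inversions and translocations but full containment for
CNVs and unaligned regions.  Term enrichment is a classic per-term
one-sided Fisher exact test (p < 0.05) on the (foreground x term) 2x2
table; no decorrelation across the term hierarchy is attempted.

## Numerical choices and degenerate inputs

Monomorphic sites give HWE p = 1 and pi = 0; zero-variance loci are
skipped in F_ST sums; a zero ABBA+BABA denominator yields NaN D with a
warning; identical jackknife blocks yield SE = 0, reported with a
degenerate-variance warning and p = 0; constant SNP columns are excluded
from the PCA scan with NaN p-values; an empty filter result warns rather
than raises.  All seeds derive from user-visible integers through
`numpy.random.SeedSequence`; the pipeline's single global seed fans out
to per-stage seeds so any stage can be reproduced alone.

## Problem sizes used by the test suite

Module tests use hundreds of SNPs and a handful of diploids; the
acceptance experiments use the scaled-down study designs stated above
(2,000-SNP spectra, 1,000-SNP scan panels with 20 diploids per deme or 8
demes x 10 diploids, 5,000-SNP ABBA-BABA panels with 20 jackknife
blocks, 10-seed replication).  These sizes are the package's chosen
desk-scale study conditions; headline numbers from the original study
(12,813 SNPs from 192 individuals, 443 consensus SVs, 110 consensus
candidates, D jackknife p = 0.0014, f_G = 0.01) are not reproducible
without its raw sequencing data and are not targeted by any test.

## Known limitations

- The coalescent kernel is event-by-event; very high migration rates
  over long epochs are slow (they are also near-panmictic, so the priors
  rarely make this matter in practice).
- Composite-likelihood AIC ignores linkage between sites within a tag;
  model ranking is supported by the recovery experiments, not by
  asymptotic theory.
- The F-model's environmental/locus decomposition is weakly identified
  with few populations; results on two-population designs should be read
  as conservative.
- LD decay is all-pairs within a chromosome and quadratic in sites per
  chromosome; it is meant for reduced-representation panels, not
  whole-genome density.
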
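# Methods

## Site filtering

A site enters the analysis as a pair of allele read depths (a, b) with total
N = a + b and ratio x = b/N.  Three filters apply in a fixed order — depth,
error, truncation — and each removed site is attributed to the first filter
that rejects it, so per-filter removal counts plus the retained count always
equal the input count.

* **Depth**: N ≥ `min_depth` (default 10 reads).  Shallow sites make the
  heterozygote classes statistically indistinguishable.
* **Error**: a site is dropped when its minor-allele count m is plausibly
  pure sequencing error, i.e. when P(X ≥ m | X ~ Binomial(N, ε)) > 0.05 with
  per-read error rate ε = 0.01.  The exact binomial tail is used (no normal
  approximation); both ε and the tail threshold are configurable and
  recorded in the filter report.  This rule is this package's concrete
  interpretation of "filter at an assumed error rate": it removes sites
  whose minor allele is not significantly in excess of error expectation.
* **Truncation**: 0.15 ≤ x ≤ 0.85 (defaults).  Ratios outside the band are
  dominated by homozygous sites with residual error reads.

Ratios are never folded about 0.5, because the tetraploid classes at 0.25
and 0.75 must remain distinguishable from each other.

## The mixture family

For one sample the retained sites are modelled as i.i.d. draws from a
K-component mixture plus an optional uniform noise component.  Component
means are fixed at the heterozygote-class expectations — (0.5) for the
diploid layout, (1/3, 2/3) triploid, (0.25, 0.50, 0.75) tetraploid — and are
never free parameters.  Three component families are supported:

* **normal** on the ratio scale, component c ~ N(m_c, s_c²);
* **beta** on the ratio scale, parameterised by mean and scale through
  moment matching: ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν.  Requests with
  s² ≥ m(1−m) are clamped to 95% of the maximum variance with a logged
  warning;
* **beta-binomial** on the read counts b_i given N_i, using the same latent
  beta parameterisation; this family respects per-site depth rather than
  treating x as continuous.

The uniform component has constant density 1/(0.85 − 0.15) on the ratio
truncation interval; for the count family it is discrete-uniform over the
counts whose ratio falls inside the interval.  Component densities are
evaluated un-renormalised over (0, 1) even though the data are truncated;
an optional `renormalize` flag divides each component by its mass on the
truncation interval (off by default — the difference is a near-constant
factor for the narrow components used here, and the default keeps the
likelihood directly comparable across layouts).

Three freedom schemes define which parameters EM may move:

| scheme    | free parameters                          | count (K comps, u ∈ {0,1}) |
|-----------|------------------------------------------|-----------------------------|
| `fixed`   | mixing proportions                       | K + u − 1                   |
| `fixed_2` | mixing proportions and component scales  | K + u − 1 + K               |
| `fixed_3` | component scales                         | K                           |

Families × {with, without uniform} × schemes give the 18 model shapes.  The
default starting values are equal heterozygote-class proportions (0.1 to the
uniform component when present, i.e. (0.3, 0.3, 0.3, 0.1) for the tetraploid
layout) and scales of 0.01.

## EM and model selection

The E-step computes responsibilities in log space; the M-step updates the
free parameters.  Mixing proportions use the standard closed form.  Normal
scales use the responsibility-weighted variance; beta and beta-binomial
scales are updated by a bounded one-dimensional maximisation of the
weighted component log likelihood, accepting the update only if it improves
the objective — a generalised EM whose log likelihood is non-decreasing by
construction (tested with slack 1e-9).  Scales are floored at 1e-3: with
fixed means a component could otherwise collapse onto repeated ratio values
and diverge.  Convergence is |Δ log L| < 1e-6, capped at 1000 iterations;
non-convergent fits are returned flagged rather than discarded.

Ploidy is selected within a shape by the lowest BIC across the three
layouts; exact ties resolve to the lower ploidy (parsimony toward diploidy).
Calibration against known-ploidy samples picks the shape with the highest
call accuracy, breaking ties toward fewer free parameters and then family
order normal < beta < beta-binomial.  Bootstrap competition resamples sites
with replacement (replicate r seeded `seed + r`), reruns the selection, and
tallies winners; the winning ploidy is *confident* when it takes more than
60% of replicates.

The no-uniform shapes deserve a caveat: when a sample contains uniform
noise sites (the generator plants 5% by default), a no-uniform layout with
more components can co-opt its extra components to absorb the noise tails,
biasing those shapes toward higher ploidy.  This is a property of the model
family, not a defect; the uniform-bearing shapes (including the default)
are unaffected.

## Inheritance mode

Mixing proportions (alphas) are estimated under the tetraploid
normal-uniform model with the documented starting values
α = (0.3, 0.3, 0.3, 0.1), means (0.25, 0.50, 0.75), scales (0.01)×3.  The
allopolyploid call requires α(0.5) to exceed both α(0.25) and α(0.75) by
more than a margin, default 0.05.  The margin matters: estimated alphas are
never exactly equal, so a margin-0 rule degenerates to "which of three noisy
numbers is largest" and would call a genuinely tetrasomic sample (equal
class weights) allopolyploid about a third of the time however much data is
available.  The default margin is roughly three standard errors of a
mixing-proportion estimate at ~1000 retained sites (se ≈ √(⅓·⅔/1000) ≈
0.015), so it demands dominance beyond estimation noise while costing no
sensitivity against the disomic expectation (α(0.5) ≈ 0.7 vs ≈ 0.15).
Setting `margin=0` recovers the strict verbatim rule.  Classification is
reported for every sample; non-tetraploid ploidy calls carry a
`not-tetraploid` caveat rather than being suppressed, since disomic
tetraploids are exactly the samples whose BIC call is most often diploid.

## Fritz's D

The observed statistic d sums |estimate(left) − estimate(right)| over the
internal nodes of a bifurcating rooted tree, where internal estimates are
branch-length-weighted pruning averages of the 0/1 tip states (node value =
(e_j·v_i + e_i·v_j)/(e_i + e_j) with effective child lengths grown by the
parallel-sum rule; an option ignores branch lengths).  D scales d between
the means of two simulated null ensembles — tip-state permutation
(prevalence preserved) and unit-rate Brownian liability thresholded by rank
to the observed prevalence — so D ≈ 1 for phylogenetically random traits
and D ≈ 0 for Brownian ones.  p-values use the (r+1)/(n+1) finite-sample
correction: p_random is the probability of as-or-more clumping (d ≤ d_obs)
under permutation, p_brownian of as-or-less clumping (d ≥ d_obs) under
Brownian evolution.  Zero-length branches (polytomy resolution) are offset
by 1e-8 in the weighting.  Because the pruning pass reduces to precomputed
per-node weights, thousands of null replicates evaluate in one vectorised
sweep; 10 000 permutations on a ~200-tip tree take well under a second.

Polytomies in input trees are resolved to bifurcations with zero-length
branches, deterministically given a seed; missing branch lengths become 1
with a warning.

## Selection enrichment

The module consumes per-locus raw p-values from branch-site selection tests
(the codon model itself is out of scope).  Foreground design: diploid sets
are drawn sequentially without replacement from a seeded shuffle of the
diploid pool, sizes as equal as possible within the requested range; when
the pool cannot supply all sets disjointly (160 diploids cannot fill six
sets of 27), the least-used taxa are reused and the reuse is logged on the
design object.  FDR adjustment is Benjamini–Hochberg step-up within each
run; a locus is selected at adjusted p < 0.05.  Chi-squared tests are
Pearson without continuity correction (a flag enables Yates), applied as
(i) selected/not × annotation within each diploid run — with a 2×K
selected-counts-only variant also emitted, since both table conventions are
defensible — and (ii) selected/not × ploidy per annotation, polyploid run
against each diploid run.  Degenerate tables are skipped with a logged
warning rather than aborting the comparison.

## Synthetic data

The depth generator draws, per site, a total depth (fixed, Poisson, or
negative-binomial with shape 5), then with probability `noise_prob`
(default 0.05) a uniform true ratio, otherwise a heterozygote class from
the class weights — tetrasomic default (1/3, 1/3, 1/3), disomic default
(0.15, 0.70, 0.15), chosen to give the 0.5 class a clear majority while
keeping the side classes non-empty.  Class means serve as true ratios (an
optional Gaussian within-class jitter exists for robustness checks); reads
are binomial after folding in the per-read error rate, or beta-binomial
under overdispersion.  Trees are Yule: starting from the root divergence,
each of k lineages splits at rate 1, and the tree is cut one Exp(n) interval
after reaching n tips, then rescaled to unit depth.  Binary traits are
assigned either uniformly at random at a fixed prevalence (state-1 count =
round-half-even of prevalence·n) or by thresholding a Brownian liability.
P-value tables draw signal loci from Beta(0.1, 1) and null loci from
Uniform(0, 1) at the per-annotation locus counts 113 / 1044 / 109 / 54.

What the generator does *not* emulate: linkage between sites, mapping and
reference bias, allele-specific expression or capture bias, contamination,
copy-number variation, and segregating allele frequencies within
heterozygote classes.  Passing recovery tests therefore demonstrates that
the inference machinery is correct and well calibrated under its own model
assumptions, not that real libraries are free of the artefacts above.

## Problem sizes and numerical choices

Recovery tests use cohorts of 30 samples per ploidy class and 50 per
inheritance class at 1000 sites and mean depth 50, 100 trees of 50 tips at
prevalence 0.15 with 1000 null replicates, and 1000 simulated datasets for
the chi-squared type-I calibration — sizes at which the binomial noise on a
90% recovery bound is a few percent.  All stochastic steps take explicit
integer seeds; EM itself is deterministic, and results for a fixed input
ordering are exactly reproducible (reordering sites changes only
floating-point summation order, i.e. last-ulp differences).

## Known limitations

* Ploidy levels above tetraploid are out of scope, as are mixtures across
  loci (all sites are pooled per sample).
* Allelic-ratio models assume a single genome-wide ploidy; mosaicism or
  large CNVs will blur the spectrum.
* Disomic (allo)tetraploids are intrinsically hard to separate from
  diploids by BIC at moderate depth — their spectra share the dominant 0.5
  mode.  The bootstrap split and the alpha-based classification, not the
  point BIC call, are the informative outputs for such samples.
* The chi-squared tests treat loci as independent; shared gene trees and
  linkage make the effective sample size somewhat smaller than the locus
  count.
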
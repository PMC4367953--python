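# Methods

## Similarity score

The genetic similarity between two individuals is their averaged
identity by state, `s_ij = 1 − Σ|g_ik − g_jk| / (2N)`, over the `N`
loci successfully typed in both, with `g ∈ {0,1,2}` counting minor
alleles.  Genotypes are stored 2 bits each with the unary-weight
encoding 0→00, 1→01, 2→11 (missing→10, masked), so the popcount of the
XOR of two packed rows *is* `Σ|g_ik − g_jk|`; the dense matrix is
computed instead through one-hot dosage indicator products (a handful
of BLAS calls on n×S matrices), and the two routes are tested against
each other and against a naive per-entry loop.  Optional nonnegative
locus weights enter both the numerator and the `2N` denominator;
the default is unweighted, as no canonical weighting formula is fixed
here.  Pairs sharing zero typed loci raise by default (an opt-in
policy scores them 0 with a warning).  A locus-subset argument allows
window-wise (local) similarity.

Note that all trend statistics below are invariant to which allele is
counted at a SNP, so the minor-allele orientation convention (ties at
frequency 0.5 broken lexicographically, monomorphic SNPs coded 0)
affects no result; it only fixes the PED/MAP round-trip.

## Structuring strategies

*Pairwise*: a maximum-weight assignment between cases and controls on
the IBS weights (scipy's Kuhn-Munkres implementation).  Unbalanced
samples are squared by appending ||O|−|A|| zero-weight sinks;
sink-matched individuals are removed, leaving min(|O|,|A|) pairs.

*Groupwise*: after an initial validated pairwise matching, unmatched
controls are assigned to already-matched cases and unmatched cases to
already-matched controls, one partner per round; each new edge is
validated like a fresh pair and the newcomer joins its partner's
existing unit (units never merge with each other).  Rounds repeat
until a full round matches nobody; the loop is bounded by |O|+|A|
rounds since every continuing round matches at least one individual.
The vicinity threshold keeps the original full-sample |O|, |A|
throughout, and the better-mate counts always range over the full
control/case sets — the validation rule is defined sample-wide, and
shrinking it to the residual pool would make acceptance easier exactly
when fewer alternatives remain, the opposite of its intent.  Under
cluster validation, re-matching is confined within clusters.

*Validation*: the `cluster` strategy requires all unit members to
share one cluster (equivalently, matching is run inside each cluster
separately); the `vicinity` strategy accepts a pair (case x, control
y) iff `(t_x < T_cc ∧ t_y < T_cc) ∨ t_x = 0 ∨ t_y = 0`, with strict
better-mate counts (equal weights never count) and
`T_cc = ln(|O||A|)`.  For multi-member units every internal
case-control pair must pass.

## Agglomerative clustering

Clustering is reconstructed behaviourally around the assignment
algorithm: each level solves a maximum-weight assignment on the
average-linkage cluster-cluster similarity (diagonal −∞, so every
cluster is proposed a distinct partner), the proposed edges are
validated, and connected components of validated edges merge;
iteration stops when no edge validates, so the cluster count is
emergent.  The merge validation compares the candidate edge's
between-cluster mean similarity with each cluster's internal cohesion
(mean member-pair similarity): the edge is accepted when at least one
side's cohesion deficit is within `T_all` standard errors, where the
SE combines the cross-block and within-cohesion sampling errors.
Singletons have no cohesion and abstain (two singletons always merge,
and stray individuals are absorbed by their nearest cluster rather
than surviving as spurious micro-clusters).

The default threshold is `T_all = 3 ln n`.  A pure better-mate count
criterion cannot terminate agglomeration (with few clusters left the
counts are trivially zero), which is why the validation is
cohesion-based; the multiple of ln n is needed because greedy
agglomeration selects the most similar pairs first, biasing early
cohesion estimates upward by an extreme-value effect of order
√(2 ln n) pairwise standard deviations.  `ln n` alone under-allows
this bias and stalls in ~100 micro-clusters on realistic data, while
on stratified data the final between-stratum deficit exceeds the
allowance by orders of magnitude, so any multiplier in roughly
[2, 30] stops identically; 3 ln n sits centrally.  The threshold is
exposed (`vicinity_param`), is monotone (raising it can only coarsen
the clustering), and the whole procedure is deterministic.  Any
external clustering (true strata, MDS-space clusters) can be supplied
instead wherever a cluster assignment is accepted.

## Matched trend tests

Within each unit the 2×3 genotype table yields the co-dominant
(t = (0,1,2)) trend statistics

    X_T2 = N/(n_co n_ca) · [n_co(n22+2n23) − n_ca(n12+2n13)]² / (N(n*2+4n*3) − (n*2+2n*3)²)
    X_U  = √((N−1)/(n_co n_ca)) · [n_co(n22+2n23) − n_ca(n12+2n13)] / √(N(n*2+4n*3) − (n*2+2n*3)²)

The √((N−1)/N) finite-population factor makes Var(X_U) = 1 *exactly*
under the within-table multivariate hypergeometric null (verified by
exhaustive enumeration in the tests), giving the identity
X_U² = ((N−1)/N)·X_T2.

Aggregation over the M units usable for a SNP:
`Y_T2 = |Σ sgn(f_ca − f_co) X_T2|` (MCAT², sign from the per-unit
reference-allele frequencies, `sgn(0) := 0`) and `Y_U = Σ X_U`
(MCAT¹, asymptotically N(0, M)).  Units rendered monomorphic or
one-sided for a SNP — including by per-SNP missingness — contribute 0
and do not increment M, which keeps Var(Y_U) = M exact; M is therefore
SNP-specific, and a SNP with no usable unit is reported untestable
(missing p) rather than p = 1.  With a single unit holding the whole
sample, MCAT² reduces to the plain trend test.

## Inference

MCAT² (and the within-unit trend test) use within-unit permutation of
the case-control labels, which preserves each unit's case/control
counts.  The default p estimator is add-one, `(1 + #{Y_b ≥ Y_obs}) /
(B + 1)`, avoiding zero p-values; the plain fraction `#{≥}/B` is
available as a mode.  One master seed drives a single permutation
stream shared by all SNPs within each cycle — the requirement for
minP validity — and results are reproducible bit-for-bit given the
seed.  The engine enumerates the ≤64 distinct case-subsets of small
units once and lets cycles index into the table; larger units use
dense relabelling.  Because the genotype column totals of a unit are
permutation-invariant, per-unit usability (and hence M) is constant
across cycles.

minP adjustment (Westfall-Young): per-cycle p-values are computed
rank-wise against each SNP's own null distribution and the adjusted p
of a SNP is the fraction of cycles whose minimum p over SNPs falls at
or below its observed p; this controls the familywise error under the
shared-stream construction without nested simulation.

MCAT¹ defaults to asymptotic two-sided N(0, M) inference (permutation
on |Y_U| is available).  The inflation factor is
λ = median(statistic)/0.4549364 (the χ²₁ median, displayed as 0.456);
for MCAT¹ the squared standardised statistic Y_U²/M feeds the median,
and for permutation-calibrated tests the p-values are mapped through
the upper-tail χ²₁ quantile first.  Genomic control rescales via
p → Q(χ²₁⁻¹(p)/λ); the power pipeline follows standard practice and
corrects with max(1, λ), so a deflated test (λ < 1, as pairwise
matching produces) is never boosted into extra significance.  The
`gc_correct` primitive itself accepts any λ > 0.

## Comparator arm

Classical (Torgerson) scaling of the distance 1 − s: eigendecomposition
of the double-centred squared-distance Gram matrix, coordinates =
eigenvectors × √eigenvalue, column-centred; negative-eigenvalue axes
are dropped.  The logistic-regression likelihood-ratio test compares
intercept + k MDS covariates against the same plus the additive
dosage, p from upper-tail χ²₁.  The IRLS fit standardises columns
internally (tolerance 1e-8, ≤50 iterations) and flags separation when
a per-SD coefficient exceeds 20 in magnitude; separated SNPs report a
missing p rather than a number.

## Synthetic stratified studies

The generator emulates merged multi-population case-control sampling:
ancestral frequencies p ~ Uniform(0.05, 0.5) per SNP; per-stratum
frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) (the Balding-Nichols model,
between-stratum variance F·p(1−p), F = 0 degenerate at p); within a
stratum, two haplotypes per individual from a first-order Markov chain
whose transitions realise a target adjacent-locus haplotype
correlation (`ld`, clipped to the feasible range; default 0), genotype
= haplotype sum (HWE within stratum).  SNPs monomorphic in any stratum
are removed.  What it does *not* emulate: higher-order LD, admixture
gradients and related individuals — so passing calibration here shows
correctness of the matching/testing machinery under clean stratified
structure, not robustness to cryptic relatedness or admixture.

Disease sampling in power mode uses multiplicative penetrances
f_g = f0·rr^g at one causal SNP (rr = 1.5 default), f0 normalised so
the stratum prevalence matches the configurable `prevalence` (default
0.1, a typical complex-disease figure; the per-stratum baseline
frequency is the stratum's own causal-SNP frequency).  Case and
control genotypes at the causal locus are drawn from the exact
conditional distributions P(g | status) ∝ HWE(g)·f_g and
HWE(g)·(1 − f_g) — algebraically the same law that per-individual
rejection sampling targets, without the rejection loop; infeasible
combinations (f0·rr² > 1) raise.  The matching panel is simulated
separately from the causal SNP, which realises the no-LD gap between
matching SNPs and the tested SNP by construction.

The packaged full design reproduces the published 14-population
distribution (967 controls / 878 cases, 1,845 individuals).  The
scaled profile used by the tests and the acceptance script keeps the
published per-stratum asymmetry *pattern* at reduced size: the five
representative populations — the largest control-heavy (130/65,
120/60), the largest case-heavy (66/133, 45/88) and the balanced
(73/74) — rescaled to 400 individuals, with 2,000 SNPs, F = 0.05
(F = 0.1 for clustering recovery, where a clearer divergence is the
quantity under test), 999 permutation cycles, 10 calibration
replicates and 300 power datasets.  These sizes keep a full grid run
in minutes on one core while leaving Monte-Carlo errors well below the
effects being checked (e.g. SE(f_p) ≈ 0.002 against contrasts of
0.05 vs 0.13).

## Numerical and design notes

- Assignment ties: any optimum is accepted; nothing downstream depends
  on which (tests use unique-optimum fixtures).
- Vicinity counts use strict inequality; tied weights are not "better
  mates".
- Groupwise rounds validate each *new* edge only; previously accepted
  units are not re-validated.  Re-validating whole groups each round
  could oscillate, and the accepted edges already passed the same
  criterion.
- λ from permutation tests is computed from p-values (inverse-χ²₁),
  the one definition that applies uniformly across statistics with
  different null scales.
- PED/MAP I/O: phenotype 1 = control, 2 = case, anything else excludes
  the individual with a warning; non-biallelic or ragged records
  raise.  Monomorphic SNPs decode to dosage 0 and frequency-0.5 ties
  are orientation-ambiguous by the lexicographic rule (both irrelevant
  to every statistic, as noted above).
- The float32 one-hot/permutation tallies are exact (small-integer
  counts) and are promoted to float64 before forming statistics.

## Known limitations

- The clustering is a faithful-behaviour reconstruction of an
  assignment-based agglomerative scheme, not a line-by-line
  reimplementation of any published variant; its guarantees here are
  the tested behavioural contracts (block separation, no-structure
  collapse, stratum recovery, monotone threshold, determinism).
- Power and calibration figures from the scaled profile are
  qualitative analogues of a full-size study: orderings and
  calibration transfer; absolute power values depend on n, F and the
  panel size.
- No handling of relatedness/family structure, sex chromosomes,
  dominant/recessive score vectors, or binary PLINK formats.
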
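# Methods

This note records the models implemented in `invpopgen`, their assumptions,
the defaults and why, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Diversity statistics

Statistics are computed over *silent sites*: all noncoding columns plus the
synonymous fraction of annotated coding columns. Potential synonymous sites
are counted by the Nei–Gojobori fractional method (each coding position
contributes syn/3, where syn is the number of the three possible point
changes that preserve the amino acid of the majority-rule codon), so the
surveyed-site denominator L is generally fractional. A variable coding
column counts as a silent polymorphism only when every observed allele is
synonymous in the majority codon context; columns whose majority codon is
incomplete, ambiguous or a stop are excluded from silent-site counting.
This single-context approximation ignores multi-hit codon paths, which is
adequate at the silent divergences involved (p ≈ 0.01–0.05 per site).

Missing data follow the **complete-deletion** convention: any column with a
gap or `N` in any ingroup sequence is dropped from every statistic, making
site counts identical across arrangement subsets of a locus. (The LD scan
is the exception: there, strains are excluded pairwise per site, which
maximises usable 2×2 tables.)

π is the mean over unordered sequence pairs of the per-site difference
proportion, each pair Jukes–Cantor corrected (d = −¾ ln(1 − 4p/3); p ≥ 0.75
is an error, not a clamp). Watterson's θ̂w = S/(aₙL) carries the
no-recombination variance Var(S) = aₙθL + bₙ(θL)² evaluated at θ̂ — the
conservative variance choice for a non-recombining inverted region.
Tajima's D uses the standard eight constants and is undefined (NaN) at
S = 0; its significance uses the scaled-beta approximation on the support
[D_min, D_max] at the 5% level, per locus, with no multiple-test
correction. Region summaries report the unweighted mean and the
*across-loci* SD of π (0 when a region holds a single locus) — the
estimator-variance alternative was rejected because region summaries pool
very few loci and the across-loci spread is what a reader can check.

## The coalescent neutrality envelope

The test conditions on the observed arrangement sample counts rather than
modelling inversion dynamics:

1. A genealogy of `n_tips` individuals is simulated (times in units of 2N
   generations). Constant size: waiting times Exp(k(k−1)/2). Exponential
   growth at rate α (default contrast: α = 0 vs α = 7): the population is
   N₀e^{−αt} backward in time, so the next coalescence at time t satisfies
   t' = ln(e^{αt} + αE/rate)/α with E ~ Exp(1) — the standard deterministic
   time rescaling.
2. Exactly K−1 inversion events (K = number of arrangements observed) are
   placed uniformly on the total branch length; a tip's class is the most
   recent event on its root path, else the ancestral class. K−1 is the
   minimum producing K classes and therefore maximises the acceptance rate;
   an event shadowed by a more recent one simply reduces the realised class
   count and leads to rejection.
3. Acceptance: exactly K classes realised and ascending-sorted class
   frequencies componentwise ≥ the observed counts ordered youngest →
   oldest (neutral allele age and frequency are positively associated).
   With counts (16, 19, 20, 18, 4, 30) of 5000 tips about 5–6% of
   genealogies are accepted; an acceptance rate below 10⁻⁴ (configurable,
   checked after a 20 000-attempt window) aborts with a diagnostic rather
   than looping forever.
4. Nucleotide mutations are Poisson((θ/2)·ℓ) per branch under infinite
   sites, with θ per locus taken as the locus's own all-arrangement θ̂w —
   the conventional plug-in when the mutation level is not otherwise
   specified. Classes are matched to arrangements by frequency rank ↔ age
   rank (the same map as the acceptance rule); frequency ties break by
   class birth time, the older event taking the older arrangement. Within
   each class exactly the observed number of alleles is drawn without
   replacement.
5. π and θ̂w (no Jukes–Cantor correction — simulated data are infinite
   sites) are computed within each arrangement and overall from the
   branch-wise carrier counts of the subsample, and the 2.5/50/97.5
   percentiles over `n_accepted` genealogies (default 1000) form the
   envelope. Observed values are flagged inside/below/above.

Loci sharing an observed-count vector share the accepted-genealogy stream
(acceptance depends only on the counts); mutations are dropped
independently per locus. One seeded `numpy` generator threads through every
stage, so envelopes are bit-reproducible; the attempt and acceptance counts
are logged. The hot loops (topology, tip labelling, descendant counts) are
numba kernels, which keeps a full 1000-acceptance run at n_tips = 5000 in
the seconds range.

The simulation contains no recombination within loci, no gene-conversion
flux between arrangements, and no migration — the no-flux single-locus
model. One structural consequence worth knowing: under this model every
mutation's carrier set is a clade, and a clade can partially overlap at
most one arrangement class, so *shared* polymorphisms (segregating in two
or more arrangements) cannot arise at all. Shared polymorphism in data is
therefore direct evidence of flux (or recurrent mutation), and synthetic
panels only contain shared sites when gene-conversion events are injected.

## The HKA test

For locus i with ingroup sample nᵢ, Lᵢ silent sites and a single outgroup
sequence, with T the species divergence in 2N generations and equal
ancestral population size:

    E[Sᵢ] = θᵢLᵢ a_{nᵢ}            Var(Sᵢ) = E[Sᵢ] + b_{nᵢ}(θᵢLᵢ)²
    E[Dᵢ] = θᵢLᵢ (T + 1)           Var(Dᵢ) = E[Dᵢ] + (θᵢLᵢ)²

Dᵢ is the mean over ingroup sequences of the Jukes–Cantor-corrected
difference count to the outgroup (hence fractional), restricted to silent
columns where the outgroup base is unambiguous so S and D share one L. The
divergence coefficient is T + 1 because the marginal coalescence of one
ingroup lineage with the outgroup lineage adds Exp(1) beyond the split
regardless of nᵢ; empirically the variance of the sample-mean divergence
stays close to the single-sequence formula (the shared ancestral segment
dominates), so the classic variance is kept. The fit expresses each θᵢ
through the per-locus total Sᵢ + Dᵢ = θᵢLᵢ(a_{nᵢ} + T + 1) and solves the
total-divergence equation for T by bracketed root finding (strictly
monotone, unique root, clamped at T = 0); the conservation identities
ΣE[S] = ΣS and ΣE[D] = ΣD then hold to solver precision. X² is referred to
χ²(L−1) *and* to refits of coalescent-simulated null data (two-population
coalescent: the outgroup lineage enters the ancestral pool at T). The χ²
reference is conservative under the null (measured 2–3% rejection at the 5%
level), so the simulation P — which is calibrated (uniform under the null)
— is the headline number. Simulated replicates whose refit is degenerate
(no polymorphism anywhere) count as extreme, which can only be
conservative. Because only one outgroup sequence is modelled, outgroup
polymorphism terms are dropped.

## The LD scan

Strains are isochromosomal lines, so two-site tables are direct
cross-tabulations of one haplotype per strain — no phasing. Sites with more
than two alleles are dropped (logged); strains missing at either site leave
that pair's table. The two-tailed Fisher P sums hypergeometric
probabilities ≤ the observed table's (relative tie tolerance 10⁻⁷),
computed by full enumeration of the margin-constrained support. A pair
enters the analysis only if the smaller of its two corner-table P values is
≤ 0.05 (configurable): tests that cannot reach nominal significance for any
allele configuration would otherwise dilute the FDR correction. Storey
q-values estimate π₀ on the λ-grid 0.05–0.95 with a cubic-polynomial
smoother evaluated at λ = 1 (clamped to [1/m, 1]; fewer than 20 tests fall
back to π₀ = 1, i.e. Benjamini–Hochberg, with a warning); the significance
cutoff is the largest p with q ≤ FDR. Combined subset scans pool the valid
P values of each subset into one Q analysis and re-flag every subset at the
pooled cutoff. The homogeneity χ² compares per-cell significant counts to
expectations proportional to valid-test counts (zero-valid cells removed
with a df reduction); cells are flagged above/below by a two-sided binomial
test at 5% against the overall significant fraction.

## Site classification

The outgroup base polarizes biallelic sites (mismatching both alleles, or
gap/N, means unpolarizable; such sites keep their unique/shared class but
leave derived-allele summaries). Arrangements with fewer than two sampled
strains cannot segregate and are excluded from configurations. The
independence null assigns configuration c ∈ {0,1}^K the expectation
N·Π pⱼ^{cⱼ}(1−pⱼ)^{1−cⱼ}. With the marginal probabilities pⱼ estimated
from the same table (the default, matching the conventional report with
df = 2^K − 1) the Pearson statistic is mildly conservative — its asymptotic
reference would be χ²(2^K−1−K); with externally supplied margins the df is
exact, which is how the calibration tests run. Expected cells below 1 are
additionally pooled into a rarest-configurations bin and both results
reported. The unique-excess test compares unique counts to shares of total
segregating sites (df = K−1); a generic category χ² is exposed for
user-defined fixed-difference splits, since no canonical category scheme is
assumed.

## The synthetic-data generator

Defaults emulate the survey conditions: 18 loci of 355–3293 bp, five
arrangements sampled (CH 16, AR 19, PP 20, ST 18, TL 4 chromosomes — 77
strains shared across loci so concatenated LD scans work), per-site θ
spanning 0.006–0.017, outgroup divergence T = 2.17, optional exponential
growth, and optional gene-conversion tracts of 300–400 bp. Each locus gets
an independent accepted genealogy (the same accept–reject machinery as the
envelope, at n_tips = 1000 by default — large enough that subsampling 77
tips is a small fraction, small enough that acceptance stays at a few
percent), nested subsampling to the exact counts, and infinite-sites
mutations mapped to uniformly drawn positions with a uniformly drawn
alternative base (transition/transversion structure is irrelevant to the
allele-count statistics in scope; multiple hits still arise on the outgroup
path, exercising the Jukes–Cantor correction). The outgroup lineage
coalesces with the sample's ancestral lineages at pairwise rate 1 starting
at T — the exact marginal law for the sample plus one outgroup lineage —
and the joint genealogy (outgroup as an extra tip, internal nodes
renumbered in time order) receives mutations on every branch visible to the
sample or outgroup. Gene-conversion events copy the donor-arrangement
consensus over the tract into a recipient strain and are recorded in the
truth log so conversion-removed reruns can be tested. Generation is
byte-deterministic given the seed.

What passing tests on these panels do **not** show about real data: the
generator has no within-locus recombination, no population structure or
migration, no indels or alignment error, no selection, and (by default) no
flux — so between-arrangement differentiation and LD are stronger than in
real surveys, every polymorphism is arrangement-private unless conversion
is injected, and an HKA fit on arrangement-conditioned panels recovers a
divergence time T̂ somewhat above the generating T (accepted genealogies
are deeper than neutral ones; verified to vanish when the conditioning is
removed). Statements about absolute diversity levels in real populations
need real data.

## Numerical and testing choices

Tolerances: Fisher tie tolerance 10⁻⁷ (relative); HKA root solve
xtol = 10⁻¹²; conservation asserted at 10⁻⁶ relative. Degenerate inputs:
S = 0 gives θ̂w = 0 and undefined D; all-zero S across HKA loci is an
error; zero-margin Fisher tables return P = 1 and are invalid upstream.
Simulation sizes in the test suite (e.g. 2000 replicates for estimator
calibration, 100 accepted genealogies at n_tips = 5000 for the
acceptance-rule check, 20 panels for envelope coverage, 500 shuffles for
FDR control) were chosen as the smallest sizes whose Monte-Carlo error is
well inside the asserted bounds; the acceptance script prints the size next
to every number it reports.
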
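# Methods

Statistical definitions, parameter conventions and numerical choices used
throughout the package. Units: positions are 1-based inclusive; rates named
"per site" are per alignment column; θ and ρ are the population-scaled
parameters 4N₀μ and 4N₀r per site unless suffixed `_locus`.

## Alignment model and site classification

An `AlignedLocus` is an (n × L) character matrix over `ACGTN-` with
per-sequence population/species/haplotype-group labels and a region
annotation (flank / exon / intron segments; exons carry a reading-frame
phase). Codons may span exon boundaries; the codon map stitches in-frame
exon positions together and drops trailing partial codons.

Polymorphic sites are classified by comparing the observed codons at a
column via **minimal mutational pathways**: all orderings of the differing
positions between two codons are enumerated, each step scored
synonymous/nonsynonymous by the genetic code, and the position's attribution
follows the majority over minimal pathways. When different minimal pathways
disagree the site is reported `ambiguous` rather than forced into a class.
Pathways through stop codons are excluded. Columns containing `-` in any
ingroup sequence are excluded from classification (indels are recorded
separately as events); `N` is treated as missing and excluded pairwise.

Synonymous/nonsynonymous site *opportunities* use Nei–Gojobori counting
(each codon position contributes the fraction of one-step changes that are
synonymous), averaged over sequences.

**Silent sites** = synonymous coding sites + noncoding (intron and flank)
sites.

## Diversity and divergence

- π: mean pairwise difference per site, computed pairwise-complete (each
  pair contributes only columns where both sequences have `ACGT`).
- Watterson's θ = S/(a₁·N) with a₁ = Σ_{i<n} 1/i and N the number of
  gap-free sites in the chosen mask.
- Divergence K to an outgroup: mean ingroup–outgroup difference per site,
  optionally Jukes–Cantor corrected, K = −(3/4)·ln(1 − 4p/3).
- Sliding windows report NaN (not zero) for windows without valid sites.

## Neutrality tests

- Tajima's D with the full variance constants (a₁, a₂, b₁, b₂, c₁, c₂,
  e₁, e₂).
- Kelly's Z_nS: mean r² over all pairs of biallelic segregating sites.
- Wall's B = B′/(S−1) where B′ counts adjacent segregating-site pairs
  inducing the same sample bipartition; Q = (B′ + A)/S with A the number of
  distinct bipartitions among those congruent pairs.
- Empirical p-values come from coalescent nulls simulated conditional on
  the observed (n, S, L) and a user-supplied ρ, using the (b+1)/(B+1)
  convention; Tajima's D is two-sided (twice the smaller tail), Z_nS, B, Q
  upper-tailed.
- McDonald–Kreitman: 2×2 table [[Ps, Pn], [Ds, Dn]]; fixed differences are
  ingroup-monomorphic positions differing from the outgroup, attributed
  syn/nonsyn by minimal pathways; two-sided Fisher exact test.
- HKA: method-of-moments fit of per-locus θᵢ and divergence time T under
  equal population sizes; goodness-of-fit X² summed over S and D deviations
  with df = 2·(loci) − (loci+1).
- Haplotype subset test: probability, over fixed-S coalescent replicates,
  that some subset of i sequences shows ≤ j segregating sites (exact subset
  search with a greedy fallback above a size budget).

## LD and recombination

- Pairwise D, D′ = D/D_max, r², with Fisher exact association p.
- R_m (Hudson–Kaplan): four-gamete-violating site pairs reduced to a
  maximal set of non-overlapping incompatibility intervals.
- ρ estimation: simulation-matched moment estimator. The observed variance
  of pairwise difference counts is compared with its coalescent expectation
  (at θ estimated from mean pairwise differences) simulated on the grid
  ρ/site ∈ {0} ∪ logspace(10⁻⁴, 10⁻⁰·⁷, 8); the expectation curve is made
  monotone and inverted by interpolation on log ρ. The grid top (0.2/site)
  is far above plausible nuclear values; estimates capped there are logged.

## Gene conversion (Sawyer scan)

Silent biallelic sites are condensed into a 0/1 matrix. For every
informative sequence pair, maximal runs of identity define fragments whose
physical bounds extend halfway-open to the flanking mismatches (clamped to
[1, L]; fragments touching the alignment ends are "outer"). Statistics:
SSCF = Σ (condensed fragment length)², SSUF likewise for uncondensed
lengths. Significance by permuting condensed column order: the global SSCF
p-value uses the summed statistic; each fragment is tested against the
permutation null of **its own pair's** maximum condensed run length (95th
percentile threshold), since pairs differ hugely in mismatch density and a
pooled null is dominated by near-identical pairs. When S! fits the
permutation budget, all column orders are enumerated and p-values are plain
fractions; otherwise (b+1)/(B+1). Mean tract length is reported over
significant inner fragments only.

## Coalescent simulation

msprime (Hudson algorithm), haploid samples, population size 1, so one
pairwise coalescence time unit = 2N₀ generations: per-site θ maps to
msprime mutation rate θ/2 and per-site ρ to recombination rate ρ/2.
Fixed-S mode places exactly S mutations multinomially proportional to
(branch length × span) over the marginal trees, then uniformly on branches
within a tree. Continuous positions are discretized to unique 1-based
coordinates (collisions redrawn uniformly among free sites).

## Codon models

GY94 rate matrix on the 61 sense codons (TCAG ordering):
q_ij = π_j·κ^[transition]·(α or β·ω) for one-step changes, 0 otherwise,
normalized so the expected rate over the site-class mixture is 1 (classes
share one normalization so branch lengths are expected substitutions per
codon). Transition probabilities by symmetrized eigendecomposition.
Likelihoods by Felsenstein pruning with site-pattern compression and
per-node scaling. Codon frequencies: F3×4 (positional) or F61, with 0.5
pseudocounts.

Models: M0 (single ω); M3 (K discrete ω classes, stick-breaking
proportions); M7 (β(p,q) discretized into 10 equal-probability categories
at quantile midpoints); M8 (M7 + one class with ω ≥ 1); Dual (3 synonymous
α classes × 3 nonsynonymous β classes, α rescaled to mean 1 for
identifiability; CVS/CVN report their coefficients of variation); ζ models
(coding M0 plus an HKY noncoding partition on shared branch lengths whose
rate is ζ × the synonymous flux per codon / 3; the null fixes the second ζ
class at 1). Optimization: L-BFGS-B with bounded parameters and
jittered multi-start (default 3 restarts). LRTs use the χ² approximation;
small negative statistics (≤ 10⁻³) are clamped to zero and flagged.
NEB site posteriors follow from the fitted class likelihoods; "positive
sites" are those with ≥ 0.95 posterior in classes with ω ≥ 1 (M8's last
class; any such class for M3/Dual).

## Haplotype structure

K2P distances with pairwise-complete deletion (saturation raises an error
or returns ∞ on request); NJ via scikit-bio with bootstrap support over
resampled columns. K_st = 1 − K_s/K_t with K_s the size-weighted mean
within-group pairwise difference; F_st variants: "hsm" (1 − H_w/H_b) or
"pi-ratio". Significance by label permutation (note: with two groups of
two, only three distinct splits exist, so the smallest achievable p is
~1/3). Group contrasts count fixed differences, shared and private
polymorphisms. The ΔG test compares per-sequence mRNA folding free
energies between groups with an exact Mann–Whitney U when feasible
(normal approximation above the exact-size budget).

## Synthetic generators

Defaults are fixed study conditions, not tuned values: `gen_neutral`
(n=28, L=2000, θ=0.005, ρ=0.006/site, GC 0.55, flank/exon/intron/exon/flank
annotation), `gen_dimorphic` (14+14 sequences, 19 planted fixed
differences, within-group θ of 0.0002 and 0.0011/site, optional conversion
tract and group-associated indels), `gen_codon` (6-taxon tree, κ=3.7,
single ω=0.22 class by default, endpoint sampling from the exact transition
matrices). Derived alleles avoid creating in-frame stop codons (fallbacks
are logged). All generators are deterministic given their seed and return
a JSON-serializable truth record.

## Reproducibility

Pipeline runs derive one seed per locus×analysis from the master seed via
SHA-256 (`{seed}:{label}`, first 4 bytes, mod 2³¹−1, plus 1) and write a
manifest with package/dependency versions, input/output SHA-256 hashes and
estimator variants. Identical config + seed ⇒ byte-identical outputs.

## Limitations

- The infinite-sites discretization redraws colliding coordinates, so
  reported positions are exact only at the discrete-site level.
- The ρ estimator is a moment method: noisy for short loci or few
  segregating sites; the returned report carries the matched grid.
- Codon-model fits on very similar sequences are weakly identified; fits
  flag near-zero tree lengths and optimizer non-convergence instead of
  failing.
- The synthetic generators emulate haplotype-level structure (fixed
  differences, conversion tracts, indels) but not base-composition
  evolution, selection on synonymous codon usage, or demography beyond a
  single panmictic coalescent per group.
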
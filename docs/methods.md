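# Methods

This note documents the statistical conventions, the simulator, the
numerical choices, and the limitations of `lapinpop`. Everything stated
here is either a definition or a property the test suite itself
exercises; no empirical claim beyond what the tests and
`scripts/acceptance.py` compute.

## Data model

Genotypes are diploid, codominant, multi-allelic, with alleles coded as
positive integer fragment sizes and 0 as the missing sentinel. A
genotype with exactly one missing allele is normalised to fully missing
during validation — a conservative choice that avoids biasing allele
frequencies toward the scored allele of half-calls. Each individual
carries a three-level hierarchy: group (wild Iberia / wild France /
domestic), unit (locality or breed), optional subunit (strain or colour
morph). Units must belong to exactly one group.

All loci are treated as diploid in every individual by default,
including X-linked loci; the data model records chromosome class, and
allele-frequency tallies accept an opt-in hemizygous coding (males
contribute one gene copy at X-linked loci) when individual sex is
recorded. The default exists because field datasets of this kind often
lack per-individual sex, and pooling X loci with autosomes changes
group-level summaries only marginally when X loci are a small minority.

File formats: GenePop (labels carried in the individual-name field so
round-trips are lossless), STRUCTURE two-rows-per-individual with
leading label columns, a two-column-per-locus CSV dialect (`NAME`,
`NAME.2`, 0 = missing), and the same table in XLSX. Every writer/reader
pair is the identity on validated datasets (property-tested).

## Diversity statistics

* **He** defaults to the plain frequency form `1 − Σp̂²` for summary
  tables. The unbiased small-sample form `N/(N−1)·(1 − Σp̂²)` is a flag,
  and is *always* used inside the loss resampler, whose pooled draws
  are tiny (as few as 4 gene copies); the biased form would deflate the
  source and derived sides asymmetrically when the two sides pool
  different numbers of copies, inflating apparent loss.
* **Ar(g), PAr(g)** are Kalinowski's hypergeometric rarefaction: the
  expected number of distinct (respectively private) alleles in a draw
  of g gene copies, evaluated with log-gamma binomials for stability.
  Default g = 8 gene copies. A locus contributes to a unit's rarefied
  mean only when that unit has at least g copies there; units below the
  threshold get NaN in the rarefied columns rather than a biased value.
  Private allelic richness multiplies the focal presence probability by
  independent absence probabilities in every other unit, so its
  comparison set is whatever level the summary is computed at.
* Per-locus statistics are averaged with equal locus weights; breed
  summary means and standard errors exclude strain subunits.

## Differentiation

* **θ** is the Weir & Cockerham (1984) variance-components estimator,
  computed allele-by-allele and locus-by-locus and combined as a ratio
  of sums Σa/Σ(a+b+c). Negative estimates are reported as computed.
  Loci informative in fewer than two units are skipped. Permutation
  p-values shuffle individuals between the pair (pairwise) or among all
  units (global), with `p = (hits + 1)/(P + 1)`.
* **AMOVA** uses the number-of-different-alleles distance between gene
  copies. The sums of squares come from the closed-form identity
  SS(2m copies with frequencies p) = m(1 − Σp²), which makes the
  within-individual SS equal to half the heterozygote count. Components
  are computed per locus (individuals untyped at a locus are dropped
  locus-wise, with per-locus coefficients) and summed over loci;
  percentages are component / total × 100, with negative components
  kept. Degrees of freedom reported are the whole-design genotypic df
  (r−1, N−r, N). The among-unit permutation shuffles individuals among
  units; the lower two components shuffle gene copies among individuals
  within units. θ and the AMOVA Φ-ratio are the same quantity through
  two independent code paths, which the suite exploits as a
  cross-check.
* **HW screening** is a chi-square goodness-of-fit over all genotype
  categories with df = k(k−1)/2, no pooling of rare classes (a
  documented caveat: expected counts can be small, so the chi-square
  approximation is rough at low n). The Bonferroni family defaults to
  within-unit-across-loci, because deviation percentages are reported
  per unit; a global family is available.

## Distances and trees

The chord distance has several published normalisations; this package
pins one and tests exactly it:

    d_l = (2/π) · sqrt(2(1 − Σᵢ sqrt(p_i q_i)))   per locus,
    D   = sqrt(mean_l d_l²)                        across loci,

so a single locus with disjoint allele sets gives (2/π)√2 ≈ 0.9003.
Individuals enter as two-gene-copy populations (frequencies 0/0.5/1).
The allele-sharing distance counts the multiset intersection of two
genotypes (AB–AC → 1, AB–AB → 2, AA–AB → 1): DAS = 1 − mean(shared/2).
Pairs with no shared typed locus are flagged absent (NaN) rather than
zero.

Neighbour joining is Saitou–Nei with deterministic lowest-index
tie-breaking; negative intermediate branch lengths are clamped to zero
with the deficit moved to the sister branch. The weighted least-squares
tree minimises Σ wᵢⱼ(dᵢⱼ − tᵢⱼ)² with wᵢⱼ = 1/dᵢⱼ² (capped for
near-zero distances), fitting non-negative branch lengths by NNLS and
hill-climbing over nearest-neighbour interchanges from the NJ topology;
moves are accepted only on strict improvement, so the objective never
increases. This is an approximation to a full global-rearrangement
least-squares search — exhaustive comparison at six taxa (105
topologies) shows the hill-climb reaching the global optimum in ≥90% of
noisy trials, which we judged a fair trade for trees of tens of units.

Bootstrap replicates resample loci with replacement — the natural unit
for multilocus distance trees, since individuals are the entities being
placed. The majority-rule (>50%) consensus is built greedily from
bipartition counts; supports are replicate counts on internal edges,
written as internal-node labels in Newick. Outgroup rooting places the
serialisation root on the edge to the first outgroup label.

## Diversity-loss resampling

Each replicate draws one gene copy per sampling unit per locus
independently (loci are unlinked, and He is a per-locus functional, so
nothing is gained by haplotype-consistent draws), pools the copies,
computes unbiased He per locus, averages across loci *within* the
replicate, and then takes loss = 1 − He_derived/He_source. The point
estimate is the replicate mean and the interval the 2.5/97.5 percentile
band (the interval method is a package choice; alternatives such as
normal-approximation bands differ negligibly at 1000 replicates).

Unit granularities: the colonization comparison draws per locality
(9 French vs 4 Iberian); domestication per unit (16 breeds vs 9 French
localities); breed formation per individual (each breed vs all domestic
individuals). A locus where any per-unit pool is empty is dropped from
*both* sides in that replicate, keeping numerator and denominator
comparable; in per-individual mode an untyped individual is simply
skipped at that locus (dropping the locus outright would discard nearly
every locus in any real dataset with scattered missingness).
Replicates with zero source-side He are discarded and counted.

Parameter recovery on simulated serial bottlenecks (programmed He
ratios 0.95/0.85/0.70 at the default design's unit counts and sample
sizes) shows mean bias below 0.03, and self-comparisons centre on zero.

## Population structure

* **Assignment** (Paetkau): per unit, the log₁₀ product over loci of HW
  genotype probabilities from unit allele frequencies; leave-one-out is
  on by default (the focal individual's two copies are removed from its
  own unit's counts — without it self-assignment is circular), and
  alleles unseen in a unit get the substitute frequency 0.005, a pinned
  convention exposed as a parameter. Ties go to the lowest label.
* **DAPC**: individuals are encoded as 0/1/2 allele counts, missing
  cells imputed to unit means, PCA retains the smallest component count
  reaching 90% cumulative variance, and an LDA with at most five
  discriminant functions is fitted on the retained components.
* **Admixture Gibbs sampler**: the uncorrelated-frequencies admixture
  model; gene-copy origins Z, cluster frequencies P (Dirichlet(1 +
  counts)) and membership vectors Q (Dirichlet(α + counts), α = 1
  fixed) are updated in turn. Missing copies are excluded everywhere.
  The K-selection statistic is the STRUCTURE-style
  `mean(lnL) − var(lnL)/2` over post-burn-in sweeps. Desk-scale
  defaults are 10,000 sweeps with 5,000 burn-in; strong-structure
  recovery in the test suite uses 1,000/500, which suffices at the
  drift depths simulated. A correlated-frequencies prior is not
  implemented: K-selection and strong-structure recovery — the
  behaviours the suite verifies — do not depend on that refinement.
* **Evanno's ΔK** = mean|L(K+1) − 2L(K) + L(K−1)| / sd(L(K)); undefined
  at boundary K (NaN), infinite when replicate sd is zero (reported as
  such, never silently dropped).
* **Run alignment**: columns of each replicate Q matrix are permuted to
  best match the first run by optimal assignment on the column-overlap
  score; the similarity coefficient is C = 1 − ‖Q − Q′‖_F/√(2n),
  which is 1 for identical runs, invariant to column permutation, and
  bounded in [0, 1] because simplex rows are at most √2 apart.

## The simulator

Each locus carries k allele states (k uniform on a configured range) on
a motif-spaced fragment-size ladder; ancestral frequencies are
symmetric Dirichlet(α). A founder event samples 2·founder_size gene
copies from the parent stage, then runs Wright–Fisher multinomial
resampling for drift_generations at 2·census_size copies with strict
stepwise mutation (±1 repeat, reflecting at the ladder edges; default
5×10⁻⁴ per copy per generation, appropriate for dinucleotide repeats).
Terminal units sample diploid genotypes under Hardy–Weinberg (an
optional inbreeding coefficient f forces identity-by-descent per
locus). One seeded generator drives the whole run, so identical
(scenario, seed) pairs give identical datasets, and the returned truth
sidecar records per-stage allele frequencies and He.

The default scenario mirrors the rabbit study's sampling design: 45
loci; 4 Iberian localities (n = 39), 9 French localities (n = 92), 16
breeds (n = 340, unit sizes 8–42; 471 individuals in all). Founder
sizes and drift lengths were chosen from the (1 − 1/2N)^t decay
heuristic so that expected group-level He lands within ±0.05 of
(0.82, 0.72, 0.58) — the wild-to-domestic gradient the design
emulates — and locality/breed founder events are deep enough that
among-unit variance fractions fall near the 22/14/7% pattern of the
emulated hierarchy. What the simulator does *not* emulate: linkage,
selection, admixture between breeds, null alleles, genotyping error,
and intrabreed stratification; real data will therefore show more HW
deviation and somewhat lower assignment accuracy than the simulated
datasets, and passing tests certify the estimators, not those
data pathologies.

## Numerical choices and degenerate inputs

Binomial coefficients in rarefaction go through log-gamma. Frequency
sums are validated to 1 ± 1e-9. Monomorphic (unit, locus) cells are
excluded from FIS and HW denominators rather than contributing 0/0.
Units with zero data at a locus are flagged absent, never zero-filled.
NJ requires a complete matrix and refuses NaN entries, directing the
caller to drop or impute entities (the bootstrap driver drops an
entity from a replicate when it has no data). Allele extinction during
simulation is allowed and logged by He = 0, not raised.

## Problem sizes in the verification suite

The suite runs at deliberately compact sizes — the full 471×45 design
for dataset-level checks, 20-replicate island models for the θ oracle,
1,000-sweep Gibbs runs, 100-replicate consensus bootstraps, and
400–1,000 loss replicates — chosen so the whole suite completes in
about half a minute while keeping Monte-Carlo error well inside every
asserted tolerance.
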
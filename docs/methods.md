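# Methods

This note records the models implemented in `liontree`, the defaults and
why, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Haplogroup model

A haplogroup tree is a rooted hierarchy of named clades whose branches
carry defining substitutions in `<ref><1-based position><alt>` notation on
reference coordinates (the lion mitogenome reference anchors positions).
The hierarchy itself is an input: it encodes the standardized A–F (modern
lion), S (Eurasian cave lion), X (American cave lion) nomenclature, and we
deliberately do not infer topology — full tree search is a different
problem, and classification against a fixed nomenclature is the use case.

**Mutation placement** uses Fitch parsimony per alignment column over
per-haplogroup consensus sequences (majority base; 50/50 ties become N and
the site contributes no evidence for that group). Haplogroups observed in
the data act as constrained leaves attached to their topology node.
Ambiguous Fitch states resolve toward the parent's state, then
alphabetically — internal placement for ambiguous states is
implementation-defined, and a different resolution would shift a mutation
along an unobserved chain of nodes without changing any classification.
Placement is only fully identifiable when every internal haplogroup has
sampled sequences and sites are not hit repeatedly; the recovery test
therefore samples all nodes at a rate low enough that repeated hits are
rare. A substitution assigned to more than one branch is kept on each and
listed in the homoplasy report; a reversion toward the root state is
stored with swapped ref/alt and a back-flag rather than silently dropped.

**Classification score.** For node h with expected derived states E(h),
restricted to positions callable in the query:

    score(h) = (|matched| − α·|private|) / |E(h) ∩ callable|,  α = 0.5,

clipped to [0, 1]. When E(h) is empty at callable sites (the root), the
score is 1 − α·|private|: a reference-identical query scores 1 at the
root, and privates still discriminate. Ties break toward the deeper node,
then lexicographically, and are reported. The authors of the original
classification script did not publish its scoring rule, so α = 0.5 and
the 50% coverage floor are this package's own operating point, chosen to
favour recall on partial cytb fragments; both are arguments. Queries with
under half of the tree-defining sites callable are refused rather than
guessed. One consequence of the deeper-wins tie-break: a sample of an
internal haplogroup whose child branch carries no defining mutation is
assigned to the child — the two names are empirically indistinguishable.

**Imputation** of a partial sequence fills missing positions from the
reference, except root→haplogroup defining sites, which take the derived
base; observed positions are never overwritten (a conflict with a defining
mutation logs a warning and keeps the observation). Every output position
is flagged observed/imputed.

## Diversity and NUMT scanning

Diversity is the mean pairwise Jukes–Cantor distance, reported in percent.
Missing data are handled by pairwise deletion (each pair compared over its
own callable sites) because partial sequences dominate real panels;
complete deletion would discard most of the locus. p ≥ 0.75 raises a
saturation error rather than returning a complex value. Between-group
diversity applies no net (within-group) correction — the published
between-haplogroup values this mirrors are plain between-group means. The
2% between-group threshold separates within-species from distinct-species
calls.

Sliding windows start at 1, 1+step, …; a trailing window shorter than the
window length is dropped. Window results carry both JC (`pi`) and the
uncorrected proportion (`mean_p`); only the latter recomposes exactly
across tiling windows, because the JC transform is nonlinear.

The ns/s ratio is a raw count ratio of nonsynonymous to synonymous branch
mutations per gene (not dN/dS: no per-site opportunity normalisation),
classifying each mutation by translating the path-reconstructed ancestral
codon against the mutated codon under the vertebrate mitochondrial code
(Biopython table 2); minus-strand genes are read on the reverse
complement, partial trailing codons are trimmed with mutations there
counted "uncalled", and stop-involving changes are flagged.

NUMT scanning slides a 500/250 window and records the minimum JC distance
from the query to any panel member. Runs of ≥2 consecutive windows above
2% merge into flagged segments. The verdict is "chimeric" only when ≥20%
of windows are flagged while ≥20% sit below 1% (threshold/2): the
qualitative field diagnosis is "half the genome looks conspecific, half
does not", and the 20%/20% operationalisation is this package's own; a
uniformly divergent query (a different species) is deliberately not
chimeric.

## Clock calibration and rho dating

The calibrated rate is (mean inter-group JC distance)/2 divided by the
anchor split time (default: leopard/lion at T = 2.96 Myr, 95% CI 1.4–4.5);
the factor 2 allocates the patristic distance to two lineages. The
mutation interval is 10⁶/(rate·L) years. With the package's cytb defaults
(rate 0.01797 /site/lineage/Myr, L = 1040) this gives ≈53.5 ky per
mutation; the whole-mitogenome rate 0.01327 on its ~15.5-kb alignment
gives ≈4.9 ky.

Node ages use the rho statistic: rho(node) = mean number of mutations on
node→tip paths, age = rho × interval, with Saillard's estimator
σ²(ρ) = Σ_branches (tips_below/n)²·k (homoplasies count once per
occurrence). The anchor-time CI propagates to ages by linear rescaling and
is reported alongside the sampling sd; the two uncertainties are of
different kinds and are not combined. Bayesian MCMC dating and skyline
demography are out of scope — the rho estimator is the reproducible
desk-scale stand-in, and on strict-clock simulations its ±2σ interval
covers the truth at the nominal rate (the recovery tests use 20 replicates
of 50 tips at a 151-ky founder age, sized to run in seconds).

## Haplotype networks

Sequences identical over mutually callable sites merge into haplotypes
(greedy, first-compatible; merges that relied on missing data are logged —
the compatibility relation is not transitive, so order matters only for
pathological missingness patterns). The network derives from the
haplogroup tree rather than median-joining: haplotypes sit on their
haplogroup's node, haplogroup nodes linked by zero-mutation branches are
unified (they are the same haplotype), unsampled nodes become inferred
(count-0) nodes, and an edge carrying k mutations is subdivided by k−1
inferred intermediates. On homoplasy-free data the path length between two
sampled haplotypes equals their pairwise Hamming distance; homoplasy can
only lengthen paths.

## SSR statistics

He uses Nei's small-sample correction (2n/(2n−1))(1−Σp²);
PIC = 1 − Σp² − Σ_{i<j} 2p²ᵢp²ⱼ; FIS = 1 − Ho/He, undefined (NA) for
monomorphic loci. Note the sign convention: heterozygote excess gives
FIS < 0. Genotypes with either allele missing are dropped per locus, not
per individual.

Weir–Cockerham θ sums the variance components a (among populations), b
(among individuals) and c (within individuals) over all alleles and loci
before taking the ratio (the 1984 multilocus convention, matching the
standard population-genetics packages), rather than averaging per-locus
ratios. Significance comes from permuting individuals among populations
(population sizes preserved; p = (hits+1)/(n+1)); the CI is a percentile
bootstrap over loci (default 1000 draws) — published totals of this kind
give a CI without stating its method, and the bootstrap-over-loci is this
package's choice.

Evanno's ΔK is mean over runs of |lnP(K+1) − 2lnP(K) + lnP(K−1)| divided
by the run-to-run sd of lnP(K); endpoints are undefined and zero sd is an
error. The admixture clustering itself is not reimplemented — any runs×K
likelihood table can be consumed.

## Synthetic data

The simulator evolves sequences on an ultrametric (strict-clock) tree with
node ages in years, under HKY85 with discrete-gamma rate heterogeneity
plus invariant sites. Defaults mirror the cytb study conditions: 1040
sites, rate 0.01797 /site/lineage/Myr, κ = 2, 8 equal-probability gamma
categories of shape 0.5, 50% invariant sites, uniform base frequencies.
Eight categories follow the Bayesian-analysis setting of the source
workflow (its ML stage used 32); both are arguments.

Simulation is counts-then-placement: each branch draws
Poisson(rate × L × t) substitutions, places them at sites proportional to
per-site multipliers (normalised to mean 1, so the Poisson mean is exact
and testable), and picks target bases with HKY transition bias — not exact
CTMC matrix exponentiation. At the divergences simulated here the
difference is negligible, and the event ledger this yields (every
substitution recorded per branch and per sample) is what makes truth-based
tests possible: replaying the ledger from the root reproduces every tip
byte-for-byte. Multiple hits are allowed, so homoplasy is observable.

SSR genotypes follow Balding–Nichols: per locus an ancestral frequency
vector (flat Dirichlet), per population a Dirichlet around it with
concentration (1−F)/F, genotypes drawn binomially; E[θ] ≈ F, which the
FST recovery test exploits at F = 0.20.

What the generator does **not** emulate: indels and alignment error (the
coordinate machinery supports insertion columns, but none are simulated —
the source analyses exclude indels), sequencing error, NUMT contamination
(constructed explicitly in the NUMT tests instead), selection,
recombination (absent in mtDNA), mutation-rate variation among SSR loci,
and coalescent demography within haplogroups (tips attach directly to
their haplogroup node). Passing tests therefore demonstrate correctness of
the estimators under their own model assumptions, not robustness to real
data pathologies such as misalignment or contamination.

## Numerical and degenerate-input choices

- JC distance: domain [0, 0.75); saturation raises.
- Consensus ties → N; N never matches or mismatches anywhere.
- Zero inter-group distance → "degenerate calibration" error, not an
  infinite interval.
- rho on a node with no descendant tips raises; a single tip gives
  sd = sqrt(k)/1 from its own branch count.
- θ with all loci monomorphic raises; permutations that degenerate count
  as exceeding the observed value (conservative).
- All randomness flows through numpy Generators seeded explicitly; any
  derived seeds stay below 2³¹.

## Problem sizes used in the test-suite

Simulated datasets are sized for fast, deterministic runs: ~200 queries
for classification accuracy, 20 replicates for each recovery experiment
(dating coverage, rate recovery, FST), 200–500 seeds for distributional
checks on the simulator. These sizes were chosen as the package's own
verification conditions and are arguments everywhere, so heavier
experiments are one call away.
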
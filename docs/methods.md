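# Methods

## Model

`holeysim` simulates haploid populations of fixed-length genotypes evolving
on *holey fitness landscapes*: genotype spaces in which genotypes are
either viable or inviable, and the viable genotypes form a *neutral
network* connected by single-mutation steps. Allopatric populations
diverging on such a landscape accumulate *incompatible introgressions*
(IIs): divergent alleles that are lethal when substituted alone into the
other population's genetic background. Each II implies at least one
Dobzhansky–Muller incompatibility, and the mean hybrid fitness deficit
(postzygotic reproductive isolation, RI = 1 − mean recombinant-hybrid
fitness) grows with the II count. The package exists to measure how the
rate of II accumulation depends on mutational robustness, and how
population size (genetic drift) and recombination shape the evolution of
that robustness.

Two genotype–fitness maps are implemented behind one landscape interface:

**Russian roulette.** Binary genotypes of length L (default 30). Every
genotype is independently viable with probability p; viable genotypes all
have fitness 1. Verdicts are a pure function of `(landscape_seed,
genotype)`: the genotype's bits are packed into a 64-bit key and passed
through a seeded SplitMix64 avalanche, and the genotype is viable when the
resulting uniform deviate is below p. This gives O(1) memory, bit-stable
verdicts across processes, and statistically independent verdicts across
genotypes and seeds; calibration tests verify the Bernoulli(p) margin, the
p² + (1 − p)² cross-seed agreement, and Var[ν] = p(1 − p)/L. The neutral
network percolates when p exceeds roughly 1/L, so all supported
configurations use p ≫ 1/L (a warning is emitted otherwise).

**RNA folding.** RNA genotypes of length L (default 100 nt), folded to
their minimum-free-energy (MFE) secondary structure. With β the number of
base pairs in the genotype's own structure and δ the base-pair distance
(symmetric difference of base-pair sets) between that structure and a
reference structure, fitness is

    w = 1 − σ δ   if β > α ≥ δ,   else 0

with defaults σ = 0.025 (selection strength per unit of structural
distance) and α = 12 (viability threshold). The ancestor is a random
sequence whose MFE structure has β > α; its structure *is* the reference,
so the ancestor starts at w = 1. Folding goes through a pluggable
`StructureProvider`; the default binds the ViennaRNA python bindings
(v2.7.2 here, default thermodynamic parameters) with an unbounded
per-sequence memo cache, and a deterministic `FakeFolder` stub (hash-keyed
structures from a fixed hairpin pool with known β) makes all measurement
code testable without the engine. Base-pair distance is computed by our
own pair-set implementation and cross-checked against the engine's
`bp_distance` in the test suite.

An `ExplicitLandscape` (fully enumerated fitness table with a plain-text
serialization) backs worked examples and exact tests.

## Evolution

**Weak mutation (blind ant).** When 2N²U ≪ 1 the population is modelled as
a single viable genotype; each time step proposes one uniformly random
mutational neighbor and moves iff it is viable. The stationary
distribution is uniform over the connected network, so the mean robustness
ν of visited genotypes equals the network mean (= p under Russian
roulette), which the tests verify.

**Wright–Fisher life cycle** (selection → recombination → mutation). Each
generation two parent sets S₁, S₂ of size N are drawn with replacement,
with probability proportional to fitness (inviable members are never
drawn; if total fitness is zero the replicate is marked extinct and
excluded from aggregation rather than silently resampled). S₁[i] mates
with S₂[i]; self-mating is possible when the same member lands in both
sets. Recombination regimes: *free* (independent crossover with
probability 0.5 at each of the L − 1 boundaries, i.e. an expected
0.5·(L − 1) crossovers — 49.5 at L = 100), *limited r* (with probability r
a single crossover at one uniform boundary, else a clone of a random
parent), and *none* (clone of a random parent). Mutation is per-site
binomial at μ = U/L with all point mutations equally likely; insertions
and deletions are not modelled. We chose fitness-proportional selection
rather than uniform-among-viable sampling because the σ term of the RNA
map must act as selection for the σ = 0 configuration to mean anything.

**Random-number streams.** Each evolving population owns named
selection / recombination / mutation streams; measurement uses a separate
stream. Streams are derived from seed *values* (not the stateful spawn
protocol), so equal seeds provably give identical trajectories — the
divergence control test (identical streams ⇒ D = 0 forever) depends on
this — while distinct populations and replicates get independent streams.

## Equilibration

Experiments start by evolving a clone of the ancestor to an approximate
mutation–recombination–selection–drift equilibrium of robustness ν and
diversity π. The criterion is a sliding-window slope test (windows of
max(200, 2N) generations; equilibrium when the OLS slope of both mean ν
and π over the last two windows is below 10⁻⁵ per generation) behind a
hard burn-in of 40N generations. The burn-in dominates in practice and
was set from long-trajectory diagnostics: at N = 500 (Russian roulette,
p = 0.5, U = 0.1, free recombination) mean ν relaxes from ~0.59 at
generation 1000 toward a plateau of ~0.632 with a relaxation time of
roughly 8N generations, so the burn-in allows about five relaxation
times; the residual drift before the plateau (order 10⁻⁶ per generation)
is smaller than the slope estimator's noise, so a slope test alone stops
too early and under-reports equilibrium robustness. Equilibrium ν is
reported as the time-average of the robustness samples in the final
window, which is unbiased at equilibrium and roughly 3× less noisy than a
single end-point sample. Non-convergence at the generation cap sets a
diagnostic flag rather than raising.

## Divergence and measurements

The equilibrated population is copied and the two copies evolve
independently under the same parameters (mutation-order divergence; no
gene flow) until Jost's D reaches a target or a generation cap. Every
`cadence` generations (default max(1, N/10)) we record:

- **Jost's D**: per locus, with n = 2 demes,
  D = ((H_T − H_S)/(1 − H_S))·n/(n − 1), averaged over all L loci, where
  H_S is the mean within-deme expected heterozygosity and H_T that of the
  pooled allele frequencies; loci with H_S → 1 use the finite
  n/(n − 1)·(1 − H_S/H_T) form. A locus fixed for different alleles
  contributes 1, so monomorphic populations differing at k loci give
  D = k/L, matching the weak-mutation distance.
- **Between-population II**, both directions, as the mean over
  min(100, N) cross-population pairs of viable individuals sampled without
  replacement: every divergent-site allele of the donor is introgressed
  singly into the recipient and inviable constructs are counted.
- **Within-population (segregating) II**: the same count over pairs drawn
  from one population.
- **Population robustness ν**: mean fraction of viable single-mutation
  neighbors over min(100, N) viable members ("not inviable" is the
  criterion, so any RNA neighbor with w > 0 counts).
- **Diversity π**: mean per-locus heterozygosity 1 − Σ f².
- Optionally **RI** = 1 − mean fitness of hybrids formed by recombining
  the populations' members pairwise under the experiment's regime (free
  recombination is substituted when the regime is `none`, since a cloned
  "hybrid" would trivially give RI = 0).

The distribution of fitness effects applies a fixed number of random
single-site mutations (default 100) to every viable member; effects are
s = w′/w − 1 with lethal s = −1, neutral s = 0 (|s| < 10⁻¹² guard; σδ
arithmetic makes exact ties the norm rather than the exception), and
beneficial s > 0.

## Fitting

The II–distance relation is summarized per replicate by OLS of II = a + bD
on measurement events with D > 0. The D = 0 events are excluded: the
linear theory II(k) = (1 − ν̃)(k − 1), with ν̃ = (νL − 1)/(L − 1) the
robustness corrected for the one neighbor known to be viable, predicts the
count of the k − 1 *untested* introgressions, while the measurement
introgresses all k divergent sites; the constant offset is absorbed by the
intercept. A nonlinear variant II = a + b(LD − 1)^c (c bounded to
[0.5, 4], initialized at c = 1 with the linear slope) discriminates linear
accumulation (c = 1) from combinatorial "snowballing" (c ≳ 2). Divergence
rate is the OLS slope of D against generation over events below 80% of the
target D (avoiding plateau curvature), and the rate–N relation is
summarized by a log–log OLS exponent. Replicate aggregation is mean ±
1.96·SEM over per-replicate estimates, never over pooled points.

**Known systematic offset.** Faithful measurement makes the blind-ant
II(k) curves sit ~2–7% *above* the linear theory with ν = p, and the
fitted b/L above 1 − ν̃ (e.g. 0.85 vs 0.83 at p = 0.2), for two reasons we
verified by experiment: (i) all k divergent sites are introgressed while
the theory counts k − 1 untested ones, and the guaranteed-viable
transitional introgression is not always among the divergent set; (ii)
divergent sites whose introgression targets are inviable persist longer
than compatible ones (a walker can erase a compatible divergent site by
moving through it, but not an incompatible one), enriching standing
divergence for incompatibility. The offset is robust to the measurement
protocol (per time step, per move, or per change of k) and is not a
landscape-hash artifact (mean ν of visited genotypes equals p exactly and
Var[ν] matches p(1 − p)/L). Tests that demand the theory value inside the
95% CI of the replicate mean at ≥100 replicates therefore fail at the p
values where the relative offset exceeds the CI width; the linear theory
is an approximation to the process, not an exact law.

## Backcross assay

With per-generation snapshots and an allele-origin log retained, the assay
scans derived alleles in order of origin (ties: lowest site, then allele).
The *focal* mutation is the earliest to reach frequency ≥ 0.5 in its
population and be lethal when introgressed into ≥ 1 sampled viable member
of the sister population at a measurement event at or after
qualification; the *control* is the earliest to reach ≥ 0.5 without ever
causing an II at a checked event. Each is substituted into every
individual of the snapshot of the generation in which it arose, and the
proportion of viable constructs reported together with population ν at
origin and at qualification.

## Synthetic fixtures

The worked-example landscape (5 diallelic loci) pins exactly the facts the
example states — the two lethal introgressed genotypes, the fully viable
substitution path including the transitional genotype, 5 neighbors per
genotype, 7/32 inviable — and fills the remaining verdicts arbitrarily but
deterministically, subject to the viable network being connected (checked
by graph search). Scripted 4-locus histories annotate which introgressed
genotypes have been tested by selection (1) versus not (k − 1 = 3), in
both a one-sided and a two-sided divergence scenario. `FakeFolder` draws
structures from a fixed hairpin pool via a keyed hash with a configurable
low-β fraction, so viability rates on the stub landscape are controllable
and exact. What the fixtures do **not** emulate: thermodynamic
correlations between similar sequences (the stub assigns structures
independently), fitness gradations within the viable network of real
folding, and genotype spaces too large to enumerate — so fixture-based
tests validate bookkeeping and exact combinatorics, not the evolutionary
phenomenology, which is exercised on the real maps.

## Problem sizes and numerical choices

Simulation scale in the shipped tests and acceptance script was chosen for
a desk-scale machine: folding an L = 100 sequence costs ~7 ms here and an
equilibrating N = 100 RNA population folds ~50–70k distinct sequences per
1000 generations, so the RNA DFE assay runs a single replicate of ~10⁴ assayed
mutations (the printed reference values are means over 100 replicates);
the Russian-roulette robustness contrast runs 30 paired replicates (the
same landscape and ancestor evolved at both population sizes, which
cancels most landscape-to-landscape variation in the contrast, with a
44N-generation burn-in and the final 4N generations time-averaged);
weak-mutation checks run 100 replicates. Replicate DFE variance is large because the random
reference structure varies (references with few base pairs leave most
sites unpaired and inflate the neutral fraction), and our neutral fraction
runs above the reference values even at typical β — consistent with
folding-engine version sensitivity, which the fraction tolerances
acknowledge. Extinction (possible at small N under recombination load) is
flagged per replicate and excluded from aggregation. All experiments are
reproducible bit-for-bit from a master seed; per-replicate seeds are
derived from (master seed, cell index, replicate index) so grid cells can
run independently in any order.

## Limitations

Haploid, constant-N, strictly allopatric populations under identical
selection regimes; no diploidy, dominance, migration, or demographic
change. Binary landscapes are limited to L ≤ 64 (bit-packed keys). The
RNA map uses a single MFE structure per sequence (no suboptimal
ensembles). Robustness selection conclusions at N larger than a few
thousand, and the printed extended-run contrasts (power-law exponents,
N = 500 RNA contrasts, asexual RNA backcross proportions), require longer
runs than the desk-scale defaults exercise.
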
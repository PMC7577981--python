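# Methods

`clonalevo` reconstructs the clonal architecture of a tumor from targeted
single-cell DNA sequencing (scDNA-seq): thousands of cells genotyped at a
small panel of driver loci, with the error profile characteristic of
droplet/amplicon platforms — allele dropout, sporadic false positives,
amplicon-dependent missingness, and occasional cell multiplets.  This note
describes the statistical models, the defaults and why they are set where
they are, what the synthetic-data generator does and does not emulate, and
the numerically load-bearing choices.

## Genotype calling and sample QC

Raw input is a pair of per-cell × per-locus matrices (total depth, alternate
read count).  A call is made only when depth ≥ 10×; a mutant call requires at
least 3 alternate reads, and additionally a variant allele fraction of at
least 15% in the 20–99× band or 10% at ≥ 100×.  Entries failing the depth
gate are *missing* (code 3).  Two remarks:

* In the 10–19× band no VAF clause applies.  This is not an omission: with
  alt ≥ 3 and depth ≤ 19 the VAF is at least 3/19 ≈ 0.158 > 0.15, so a 15%
  clause would be inert there (a property test pins this down).
* Alternate evidence above the count gate but below the VAF gate is called
  wild type by default, on the reasoning that the VAF bands exist to absorb
  the ~1% per-base sequencing error; `ambiguous_as_missing=True` treats such
  entries as missing instead.

Zygosity-aware calling (code 2, homozygous) is an optional mode using a
VAF ≥ 0.9 cut; it is on by default for germline SNP loci, where it is needed
to see dropout in both directions.

**Allele dropout (ADO)** is estimated from panel loci known to be
heterozygous in the germline: the fraction of non-missing calls at those
loci that look homozygous in either direction (hom-ref via loss of the
alternate allele, hom-alt via loss of the reference).  The platform does not
publish its exact formula; ours is stated, not claimed identical.  Closed-loop
simulation (read-level generation at a target ADO, followed by calling and
estimation) recovers the truth to within ±0.01 at 5,000 cells.

The pooled single-cell VAF (scVAF) of a locus is the ratio of summed
alternate reads to summed depth across cells.

## Mutation-tree model

The evolutionary history is a rooted *mutation tree*: non-root nodes are
mutation-acquisition events, the root is the unmutated state, and a cell
attached at node v carries exactly the events on the root path of v.  With
false-positive rate α (default 0.01) and false-negative rate β_j per locus
(default: the sample ADO estimate), the likelihood of a genotype matrix D
marginalizes each cell's attachment over all E + 1 nodes with a uniform
prior:

    P(D | T, α, β) = ∏_c (E+1)^{-1} Σ_v ∏_j P(D_cj | E_j(v))

where E_j(v) indicates whether event j is an ancestor-or-self of v, and
missing entries contribute no factor (a partially genotyped cell still
informs the tree).  The engine collapses duplicate genotype rows and writes
the per-attachment log-likelihood as a rank-one update (a weight matrix
times the tree's ancestor matrix), so one tree evaluation costs
O(unique rows × events) and is memoized by parent vector while β is fixed.

Inference is Metropolis–Hastings over parent vectors with three symmetric
tree moves — prune-and-reattach (new parent uniform among non-descendants),
node label swap, and subtree swap of non-nested node pairs — plus an
error-rate move when β is learned.  Four standard configurations are
supported: models 1/3 learn a shared β (uniform prior on [0, 1], reflected
Gaussian random-walk proposals, σ = 0.1); models 2/4 fix β to the
platform/sample ADO; models 3/4 restrict to cells with complete genotypes.
The locus-specific mode learns independent β_j under a Gaussian prior
centred on the sample ADO estimate with SD 0.002, truncated to [0, 1]
(proposal σ = 2 × prior SD).

Default chains are 3 × 200,000 iterations, 25% burn-in, thinning 10 — sized
for panels up to ~37 loci and 10⁴ cells on one CPU.  The benchmark suite and
examples use shorter chains (4,000–20,000 iterations, 1–2 chains), which the
collapsed likelihood makes sufficient for ≤ 12-event panels: the MAP matches
exhaustive enumeration on 100% of small random instances, and unthinned
visit frequencies on a 3-event instance match the enumerated posterior to
total-variation < 0.01 at 10⁶ iterations.  A split-chain potential scale
reduction factor on the log-likelihood trace is reported with every run.

Ties among equal-likelihood MAP trees resolve to the lexicographically
smallest parent vector, making outputs deterministic under a seed.

### A note on learned error rates

Under the uniform-attachment marginal, a dropout at a locus whose event has
no descendants is explained equally well by attaching the cell one node up,
so the learned β is biased low roughly in proportion to the fraction of
terminal loci (profiling the likelihood of a 5-leaf, 8-event simulation
shows the peak at β ≈ 0.035 when the truth is 0.06).  On linear trees, where
only one locus is terminal, recovery is nearly unbiased (±0.005 at 3,000
cells).  This is also why the locus-specific prior hardly moves: with SD
0.002 the prior precision (250,000) exceeds the β_j information that even
several thousand mutant cells carry (≈ 9.5 per cell), so per-locus estimates
stay within a percentage point of the sample-wide rate — consistent with
locus-specific and locus-independent runs producing near-identical trees.

## Zygosity and LOH ordering

Copy-neutral LOH converts heterozygous driver mutations to homozygous.  A
locus with homozygous calls is split into two binary event rows: M (mutation
acquired; observed for codes 1 and 2) and L (LOH; observed for code 2 only),
with missing propagating to both.  The MCMC search is restricted to trees in
which M is a proper ancestor of L — a hard constraint, enforced by proposal
rejection, reflecting that a homozygous mutation arises from a pre-existing
heterozygous one rather than directly from wild type.  (The alternative
encoding in which the het row excludes homozygous cells is internally
inconsistent with that ordering — a homozygous cell would be scored 0 on a
row its ancestors require — so the inclusive encoding is used.)  Because
sporadic dropout creates rare spurious homozygous calls (~ADO/2) at truly
heterozygous loci, `encode_zygosity` accepts a minimum homozygous-call
fraction below which no LOH event is created (default 0: any code-2 call
creates one).

## Cell attachment, subclone sizes and credible intervals

For each retained posterior draw (tree, β), cells are assigned to nodes and
the per-node assigned-cell counts form one draw of the subclone sizes; the
point estimate is the mean and the 95% credible interval the 2.5/97.5
percentiles across draws.

The attachment *prior* matters more than it first appears.  With a fixed
uniform prior, a cell whose mutant allele dropped attaches mostly to an
ancestral node — the posterior odds are (1−α)/β ≈ 16 — so each subclone
leaks ≈ β of its cells upward, a bias two orders of magnitude larger than
the credible-interval width.  The default therefore learns the attachment
weights per posterior draw: a symmetric Dirichlet(1) hyperprior over node
weights and a short collapsed Gibbs sweep (default 30 alternations of
multinomial assignments and Dirichlet weight updates, operating on collapsed
genotype rows) yields draws from the joint posterior of weights and
assignments.  This removes the dropout pull and propagates weight
uncertainty into the intervals; measured coverage of the true clone counts
is 92–95% for 95% intervals in a 3-clone, 5,000-cell benchmark.
`prior="uniform"` restores the plain likelihood-proportional assignment.

For longitudinal data, all timepoints (which must share a locus panel) are
pooled into a single tree inference; at attachment, a cell from timepoint t
receives exactly zero mass at any node whose root path uses an event
unobserved at t (renormalized).  A subclone can therefore read 0% at a
timepoint without implying extinction.  "Observed at t" defaults to a
mutant-call fraction above 2% among non-missing calls at that timepoint —
deliberately above the ~1% false-positive floor — and can be overridden with
explicit per-timepoint event sets.

## Clones, diversity, evolution patterns

A subclone is a tree node with assigned cells, labeled by its root-path
mutation set; wild-type (root) cells are excluded.  Fractions are taken
among mutated cells; clones under 1% are retained but flagged and excluded
from association analyses.  Clonal diversity is the Shannon index in bits,
H = −Σ p_i log₂ p_i, over (renormalized) subclone fractions — exactly 0 for
a single clone and log₂ k for k equal clones.

Evolution patterns are classified on the tree restricted to events carried
by at least one surviving subclone: *linear* if at most one branch point
exists and all its children are leaves (a terminal fork still reads as
stepwise acquisition); otherwise *branching*; a stricter pure-path rule is
available via `strict_linear`.  *Convergent* evolution is called on
branching trees when two events in the same gene — or the same pathway,
given a gene→pathway map; a default AML driver map ships with the package —
sit on incomparable nodes (neither ancestral to the other).

## Co-occurrence statistics

Three levels share one 2×2-table machinery.  Cell level: units are cells of
one sample, pairwise-complete over missing entries; Haldane-corrected
(+0.5 per cell) log₂ odds ratio; two-sided Fisher exact p;
Benjamini–Hochberg q across the sample's pairs.  Patient level: units are
patients with gene presence/absence; natural-log Haldane odds ratio; G-test
(G = 2 Σ O ln(O/E) on uncorrected counts, 0·ln(0/E) = 0; p from χ², 1 df);
BH q.  Clone level: units are subclones ≥ 1% pooled across samples, same
statistics as the patient level.  Under an independence null at 10,000
cells, the empirical FDR of q < 0.1 discoveries stays at ~0.1 over hundreds
of replicates.

## Synthetic data: what it does and does not emulate

The generator produces: a random recursive tree over 2–15 driver events
(label-exchangeable, so for two events the fork/chain split is 1/2, 1/4,
1/4); clone prevalences from a symmetric Dirichlet rescaled around a
wild-type fraction, optionally perturbed across timepoints by
logistic-normal drift; true genotypes by multinomial cell-to-node
assignment; genotype-level noise (false positives, per-locus dropout,
per-locus missingness, doublets as the elementwise maximum of two cells'
genotypes); and read-level data (negative-binomial depth, mean 48×,
gamma-shape dispersion 5; per-allele dropout at rate d = ADO/(2−ADO) so the
hom-looking fraction among non-missing het calls equals the target ADO;
binomial alternate reads with base error 0.003).  Defaults mirror a typical
AML cohort: ~6,000 cells, ADO 5.8%, FPR 1%, panels of a dozen to a few dozen
loci.  No cohort value is claimed for the doublet rate; it defaults to 0 and
is configurable.

`simulate_clone_fractions` additionally accepts a `selection_strength` s:
each clone's Dirichlet mass is weighted by s^depth, modeling cumulative
fitness gains of successive drivers.  At the neutral default (s = 1) the
fraction distribution is exchangeable across clones and therefore carries no
information about topology — linear and branching trees then have identical
Shannon-index distributions.  The documented contrast between patterns
(branching architectures averaging higher diversity than linear ones of
equal event count) requires s > 1; the benchmark uses s = 2.

Not emulated: raw reads and barcodes, GC-driven coverage bias beyond
per-locus parameters, copy-number change other than copy-neutral LOH, and
doublet structure in the *likelihood* (doublets exist only as a simulation
stress; the inference model deliberately ignores them, as the platform
pipeline does).  Passing tests on this generator demonstrate correctness of
the inference machinery under its stated noise model, not robustness to
artifacts the generator does not produce.

## Benchmark design and problem sizes

Recovery benchmarks use near-balanced clones (Dirichlet α = 10, wild-type
fraction 5%): a recovery rate is only meaningful when the truth is
identifiable, and a clone with a handful of cells cannot constrain its
event's position in principle.  Benchmark sizes — 50 enumeration instances,
100 recovery replicates at 3,000 cells, 100 coverage replicates at 5,000
cells, 200 null-association replicates at 10,000 cells — are the package's
standard regression settings; `scripts/acceptance.py` runs slightly reduced
replicate counts of the same measurements.

## Numerical choices

Probabilities entering logs are clipped to [1e-12, 1 − 1e-12], so α = β = 0
is usable (the noiseless likelihood is exact to ~1e-11).  Random-walk
proposals for rates reflect at the [0, 1] bounds, keeping them symmetric.
Equal-likelihood comparisons use a 1e-9 tolerance with lexicographic
tie-breaks.  All randomness flows through seeded `numpy.random.Generator`
instances; identical seeds give byte-identical outputs end to end, and the
pipeline derives per-stage seeds from the run seed by hashing, so stage
caching cannot perturb downstream results.

## Known limitations

Learned error rates inherit the terminal-locus bias described above; on
branching trees with many leaves the shared β can undershoot by a few
percentage points (the fixed-β models 2/4, which the headline analyses use,
are unaffected).  The locus-specific mode is, by its prior's construction,
a consistency check rather than a per-locus measurement device.  Doublets
are not modeled in the likelihood and inflate apparent co-occurrence if
frequent.  Clone-level association pools clones across samples as
independent units, ignoring within-patient correlation.  The evolution-
pattern rule is a topological convention; borderline architectures (e.g. a
terminal fork with one child acquiring a later event at low prevalence) can
switch labels with the clone-survival threshold.
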
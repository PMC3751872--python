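# Methods

This note documents the models behind each stage, the defaults and why, the
numerical choices, and what the synthetic benchmark does and does not show.

## Differential expression

Inputs are normalized log2-scale measurements (two-channel log ratios or
log intensities) with replicate pairing across states. A contrast produces,
per gene, the vector of replicate-wise differences in log2 space; the test
statistic is the one-sample z over replicates,

    Z = mean(log2 R) / (SD(log2 R) / sqrt(n)),

with the sample (ddof = 1) standard deviation. The significance rule is
conjunctive and inclusive: |mean log2 R| ≥ 1.0 (two-fold) AND |Z| ≥ 2.0.
The z formula is a design choice — the rule's effect-size-plus-consistency
structure pins down the thresholds but not the exact statistic — and both
cutoffs are parameters. A zero-variance replicate vector gets Z = ±inf so
its call is decided by the ratio cutoff alone. Genes with any missing
replicate are excluded from that contrast (absent from the result, by key).

With triplicates and homoscedastic Gaussian noise of SD 0.25 log2 units the
rule is very conservative: the null probability of |mean| ≥ 1 is ~3·10⁻¹²,
so the observed false-positive rate on a 10 000-gene null simulation is
essentially zero, and a planted 2.0 log2-unit effect is recovered at ~100%.
Real microarray noise is heavier-tailed and spot-correlated; the synthetic
result demonstrates the rule's arithmetic and its conservatism, not a
platform-calibrated error rate.

Temporal patterns are clustered by Euclidean K-means on the genes × time
points matrix of mean log2 ratios, k = 10 by default (the number of
temporal waves a shock response of this kind resolves into), 10 restarts,
fixed seed. K-means is used deliberately even though such patterns are
often shown as hierarchical trees: the deliverable is k archetypal
centroids, not a dendrogram. Duplicate-point degeneracy (fewer distinct
profiles than k) is reported via `n_effective`.

## State space

Distances are d = 1 − r (Pearson), range [0, 2]; the alternative (1 − r)/2
normalisation is not used because the magnitudes practitioners quote for
transcriptome state separation (≈0.1–0.3) correspond to the unnormalised
form. Absolute states use all genes, unfiltered; relative states keep a
gene iff its maximum |mean log2 R| over the contrast set strictly exceeds
log2(2) — "more than two-fold", a strict inequality, applied before any
pairwise comparison so all relative states share one gene set.

The dendrogram is average linkage on the Pearson distance. Bootstrap
support resamples genes (matrix rows) with replacement; the support of an
internal node is the percentage of resampled trees containing the same leaf
set (clade-based, appropriate for rooted dendrograms). Resamples in which
any profile degenerates to zero variance are skipped and contribute no
support — a conservative choice that only matters at unrealistically small
gene counts. The root clade is trivial and not reported.

Microevolution metrics over the two distance matrices:

* distinctness — min between-group distance vs max within-group distance
  for a stated two-group labelling; "distinct" iff min-inter > max-intra;
* discreteness — distance of a designated state to its nearest neighbour;
* resilience — along a stated trajectory, whether the last state is closer
  to the origin than every intermediate state;
* memory — stated relative-state pairs ranked by ascending distance;
* convergence — the global off-diagonal arg-min of the relative-state
  matrix; ties broken lexicographically on the sorted label pair.

## Co-expression networks

Edges join gene pairs with |r| above the threshold, carrying the
correlation sign; isolated genes are not nodes. The default cutoff is 0.98.
The data-driven alternative scans an ascending grid: at each candidate the
matrix is pruned (entries below the cutoff zeroed, unit diagonal kept),
genes isolated at that cutoff are removed, and the eigenvalue spectrum is
tested for Poisson nearest-neighbour spacing statistics. Dense correlated
noise produces GOE-like level repulsion; modular signal produces Poisson
spacings; the selected threshold is the smallest candidate whose NNSD is
not rejected (chi-square, α = 0.05).

Unfolding uses the cumulative spectral function smoothed with a cubic
spline, after collapsing near-degenerate eigenvalues (tolerance 1e-8):
hard thresholding produces symmetric degenerate blocks whose zero spacings
are artefacts, and a raw empirical-CDF unfolding is degenerate (it maps
every spacing to a constant). The goodness-of-fit test uses ~√N
equal-probability bins under Exp(1) (expected counts ≥ 5 by construction)
with one further degree of freedom removed for the estimated mean. On true
exponential samples the test accepts at ~95/100 trials at α = 0.05, and on
Wigner-surmise samples it rejects essentially always — the discrimination
the criterion rests on. If a candidate prunes the spectrum below 10
distinct eigenvalues the matrix is already in the sparse modular regime
and that candidate is accepted with a warning; if no candidate passes, the
grid maximum is returned with a warning.

Modules are fast-greedy (Clauset–Newman–Moore) modularity communities of
the unweighted edge set, numbered by decreasing size; communities below
`min_size` (default 5) stay in the partition but are listed separately.
Fast-greedy is a heuristic: on arbitrary small random graphs it reaches the
exhaustive maximal-modularity partition in roughly 9 cases out of 10 (both
the networkx and igraph implementations behave identically here), while on
modular structure — disjoint cliques, planted correlation blocks — it is
exact. The package keeps the canonical algorithm rather than patching it
with local refinement, and the benchmark reports the measured agreement.

Network comparison is node-set algebra (shared, A-specific, B-specific,
with |shared| + |specific| = |network| identities asserted), shrinkage
(|B|−|A|)/|B|·100, top-k degree hubs (ties broken by node label), and for
shared nodes the (module in A, module in B) table exposing rewiring.

## Dynamic operons

Per-gene coverage is the mean per-base depth over the gene's coding
interval (1-based inclusive on disk, half-open internally). A gene with
mean depth below `min_depth` (default 5; the threshold is a free parameter
— any small positive floor on "expressed" behaves identically at the
simulated depths) is unexpressed, excluded from membership, and breaks
contiguity.

Within each contiguous expressed run, a boundary is placed between
adjacent genes gi, gi+1 iff max(di, di+1)/min(di, di+1) > fold (default
2.0, strict — a ratio of exactly two never splits) in **every** replicate.
Then, in the default `within` mode, each multi-gene suboperon must show ≥
`min_pairs` uniquely mapped bridging read pairs across every internal
adjacency in every replicate; unsupported adjacencies are split and the
resulting singletons emitted as monocistrons. The alternative `across`
mode instead uses pair detection to gate the split itself (a coverage step
only becomes a boundary where pairs confirm the adjacency was
co-transcribed); it exists because the two-requirement rule admits both
readings. The ratio rule makes calls invariant to uniform depth scaling
within a replicate (library-size changes).

The generator plants boundaries as alternating depth tiers (fold step 3 by
default) with Poisson per-base counts and 1 + Poisson bridging pairs inside
transcription units, zero across boundaries. At depth 50× and fold step 3,
boundary recovery at the 2-fold threshold is 100% with zero false
boundaries over 100 polycistrons; real RNA-seq adds positional coverage
bias the Poisson model lacks, so on real data the fold threshold, not the
noise model, is the binding constraint.

## Mutation analysis

Consensus is the strict intersection of all caller sets keyed on (chrom,
pos, ref, alt) — same position with different alternate alleles never
merges — with caller support recorded and non-consensus calls written to a
side report (a machine-readable replacement for manual review). Effects:
region by overlap with annotated CDS; for coding SNPs the affected codon is
rebuilt respecting strand and translated with bacterial table 11 (stop
gain → nonsense, other amino-acid change → missense); single-base indels
in CDS → frameshift; everything else intergenic. A reference-allele
mismatch with the genome is an error naming the locus.

Pooled frequency is alt/(ref+alt) at a locus (undefined at zero depth —
error). The candidate-beneficial rule is: effect non-synonymous (missense,
nonsense or frameshift) AND frequency strictly greater than 0.80. At 140×
binomial depth, the estimator's mean absolute error at a true frequency of
0.85 is ≈0.024 over 1000 loci — comfortably inside the 0.04 working
tolerance, so a mutation near fixation is not mistaken for an intermediate
one.

μ_g = fixed mutations / generations, reported to two significant figures;
all consensus mutations count, indels included (20 mutations over 440
generations → 0.045). The generation count is an input, not recomputed.
The non-coding/coding ratio is percent to one decimal (3 vs 17 → 17.6).

## Synthetic-data generator

The expression generator emulates a nine-state triplicate design: one
unstressed wild-type control, four shock time points (0.5/1/2/4 h), and two
adapted lineages each with and without its stressor. Defaults: 500 genes,
noise SD 0.25 log2 units (homoscedastic Gaussian — the simplest model
consistent with ratio-based analysis; real array noise is
intensity-dependent), DE fraction 0.1 at effect 2.0 log2 units with random
sign, depth 140×, one memory pair (the 4-h shock state and the
high-tolerance lineage without stressor share a contrast signature, so the
convergence metric has a planted answer). Co-expression blocks are
single-latent-factor: gene = loading·factor + noise with loading chosen so
the within-block correlation equals the requested value in expectation.
Group signatures (shared by a stated state set) plant two-group tree
structure. Pooled counts are binomial at Poisson-distributed depth —
matching the "fraction of mutated reads" estimand. All generators draw
from per-purpose substreams of one integer seed (SeedSequence spawning),
so outputs are byte-identical across runs and generators stay decoupled.

What passing the synthetic benchmark shows: the arithmetic of every rule,
the determinism contract, and each stage's recovery behaviour under its
stated noise model. What it does not show: platform-specific error rates,
operon calls under real coverage bias, or any of the original experiment's
biological conclusions — those require the deposited expression and
sequencing data, which this package deliberately replaces with simulation.

## Problem sizes

The test suite and the benchmark script run at desk scale by design: 400–
10 000 genes for expression stages, 30–120-gene correlation matrices for
network stages, 100 simulated polycistrons, 1000 pooled loci, 1000
bootstrap resamples. Each was chosen as the smallest size at which the
measured quantity is stable to the reported precision.

## Known limitations

* The RMT scan's GOE regime needs a dense correlated matrix; on very small
  gene sets the spectrum is short and the scan falls back (with a warning)
  to treating sparseness as modularity.
* Bootstrap supports are clade-based; they are not comparable to
  split-based (unrooted) supports from phylogenetic software.
* The effect annotator assumes single-CDS, non-overlapping-frame genes;
  overlapping genes on the same strand are annotated against the first
  containing interval.
* K-means with k above the number of distinct profiles silently collapses
  clusters (reported via `n_effective`) rather than erroring.
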
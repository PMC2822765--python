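# Methods

`cghindel` analyzes two-color array-CGH comparisons of nematode natural
isolates against a reference strain.  Each probe reports
log2(test/reference) fluorescence; contiguous runs of strongly negative
ratios indicate sequence deleted in the isolate (or inserted in the
reference lineage), strongly positive runs indicate amplified sequence.
The pipeline normalizes raw ratios, segments them, calls and classifies
indels, matches alleles across strains into loci, annotates affected
genes, and treats deletion loci as binary markers for parsimony tree
inference and multilocus linkage-disequilibrium testing.

## Synthetic study generator

The generator emulates the statistical structure of an exon-centric
whole-genome oligo array: six chromosomes totaling ~100 Mb, ~380,000
probes of 50 bp at a mean start-to-start spacing of 260 bp.  Spacing
jitter is exponential with the mean offset so probes never overlap; the
published descriptions of this class of array quote both a ~64 bp median
and a 260 bp mean spacing depending on how overlapping probe sets are
counted, so spacing is a configuration knob rather than a constant.
Autosome probes in the outer fraction of each chromosome are labeled
`arm` (default `arm_fraction = 0.23` per side, which puts ~38% of all
probes on arms once the armless X is included); the X chromosome is a
single `X` region.

Indels are planted on the branches of a strain genealogy given as
Newick: a locus arises once on a branch and is inherited by every
descendant strain, so carrier sets are clades of the rooted genealogy.
Optional interval swaps between two strains emulate recombination.
Defaults follow the biology the pipeline targets: deletions outnumber
amplifications 8:1; 85% of indels are placed on arms; lengths are
log-normal with median ~2.7 kb and a long right tail; deletion signal is
−3 log2 units and amplification signal +1.5.  Each indel is re-drawn
until it covers at least 3 probes and is at least `min_gap_probes`
(default 5) probes clear of every other locus, so planted loci are
distinguishable by construction.

The forward model gives every probe overlapping a planted indel the full
signal (breakpoint probes are treated as affected, not attenuated), adds
i.i.d. Gaussian noise (`probe_sd`, default 0.25), draws a per-probe mean
log-intensity A ~ U(8, 16), and adds a cubic dye-bias
`trend_amplitude * ((A − 12)/4)^3` so the normalization stage has a
smooth nonlinear target.  Test and reference intensities are
reconstructed as 2^(A ± r/2).  Randomness flows from one root seed
through per-purpose child seeds (first four bytes of
`sha256("{seed}:{label}")`, masked to 31 bits), so every artifact is
reproducible and independent stages do not share streams.

What the generator does *not* model: probe sequence and hybridization
thermodynamics, SNP-dense regions masquerading as deletions, spatial
slide artifacts, or dye-swap structure.  Passing recovery tests
therefore demonstrate correctness of the algorithms under the stated
noise model, not robustness to those real-data confounders.

## LOWESS normalization

Ratios are regressed on the per-probe mean log-intensity
A = (log2 T + log2 R)/2 — the standard two-color MA convention — with
robust locally weighted regression (span 0.4, degree-1 local fits,
3 bisquare reweighting iterations) and replaced by their residuals.
Normalization is strictly per array; pooling strains would let one
strain's deletions bias another's fit.  The implementation delegates to
statsmodels' `lowess` with `delta` set to 1% of the covariate range,
which makes the fit effectively linear-time on 380k probes.

Two measured properties worth knowing: adding a constant to all ratios
leaves the output unchanged (the fit absorbs it), and a span-0.4
local-linear smoother retains roughly 4% of a strong cubic's curvature,
so renormalizing an already-normalized profile can still move ratios by
~2% of the original bias amplitude.  At study conditions (bias amplitude
0.5, noise sd 0.25) the residual intensity slope is below 0.003 and a
planted −3 deletion's mean moves by well under 0.05, so copy-number
signal survives intact.

## Segmentation and indel calling

Each chromosome is segmented independently, bottom-up.  Every probe
starts as its own segment; a heap prioritizes all adjacent-pair mergers
by the two-sample Welch t-test probability that the two segments share a
mean; the most probable merger is performed, the merged segment's
statistics and its two neighbor P-values are recomputed, and the process
repeats until the best remaining merger has P below `merge_alpha`
(default 0.05).  Heap entries are lazily invalidated via per-segment
version counters — behaviorally identical to eager updating — and equal
P-values resolve to the leftmost pair, making reruns deterministic.
Note that the sequence of accepted merge P-values is not monotone: a
merger can create a new adjacent pair whose P exceeds earlier ones; the
invariant maintained is that every accepted merger is the global best at
its moment.

Variance handling: a singleton segment has no sample variance, so a
per-chromosome noise variance stands in, estimated as the squared scaled
median absolute successive difference
(σ = median|x_{i+1} − x_i| / 0.9539), which is insensitive to sparse
copy-number steps.  Substituted variances contribute no degrees of
freedom to the Welch–Satterthwaite approximation; when neither side has
any, the test degenerates to a z-test.  Exactly identical segments give
P = 1 (always merged first); zero variance with unequal means gives
P = 0.  This estimator assumes the chromosome is mostly copy-neutral; on
toy chromosomes only a few probes long where indel steps dominate the
successive differences it degrades, which is why fixtures and simulated
chromosomes carry a realistic fraction of neutral probes.

Classification: each remaining segment is tested against 0 with a
one-sample t-test and labeled a deletion (mean log2 ≤ −2), an
amplification (mean ≥ +1), or normal, requiring P ≤ 0.01; adjacent
same-label segments are then merged with statistics recomputed, and
aberrant segments covering fewer than 3 probes are relabeled normal.
Two deliberate choices for tiny segments: (i) segments under 3 probes
use the chromosome noise variance (z-test) in place of a df ≤ 1 sample
t-test, which has essentially no power and would otherwise split long
aberrations at unlucky interior pairs; (ii) a 2-probe segment whose two
ratios are both ≤ −2 is accepted as a deletion on that evidence alone —
the mean cutoff has no meaningful accompanying t-test at that size.
Raw P-values are reported throughout; no multiple-testing correction is
applied.

Each aberrant segment becomes an indel call: its first and last probes
are the breakpoint probes; the indel length is measured midpoint to
midpoint between them.  Flanking probes are found by scanning outward
from each breakpoint for the first probe whose ratio is back past the
return threshold (> −0.8 for deletions, < +0.5 for amplifications) with
at least 2 of the following 3 probes agreeing (all remaining probes if
the chromosome ends sooner); the flank is absent at a chromosome end.
The 2-of-3 quantification of "ratios consistently back to normal" is a
design choice; it reproduces the expectation that the large majority of
flanks sit immediately adjacent to their breakpoints.  In place of
manual breakpoint curation the pipeline emits a review table of every
call with ±10 probes of context for human audit.

Known limitation: a probe inside a long amplification whose ratio dips
below the +1 mean cutoff can occasionally survive as its own normal
segment and split the call in two; at study noise levels this costs a
small number of extra fragments (FDR well under 5%) and is the kind of
case the review table is for.

## Catalog: loci, markers, genes, statistics

Two same-kind calls on the same chromosome represent the same allele
when they overlap and both breakpoint probes are within 3 probes of each
other (probe-index distance, since the rule is about array resolution,
not bp), or when one call's breakpoint probes both fall strictly
between the other's flanking probes (for calls with ambiguous
shoulders).  Locus identity is the union-find transitive closure of this
pairwise relation, so it is a well-defined partition even when chained
matches exceed the pairwise tolerance (chains are logged).  Canonical
locus breakpoints are the modal member breakpoints (ties toward the
left).  Amplification loci are matched with the same rule but flagged
position-unknown: the array only shows that the probed sequence is
over-represented, not where the copies sit.

Deletion loci become a binary strain × locus presence/absence matrix
(amplifications excluded by default, as less robustly detected); the
reference strain carries no markers by construction and is excluded.
Gene annotation intersects the span from the left breakpoint probe's
start to the right breakpoint probe's end with gene intervals (1-based
inclusive internally; GFF3 on disk, BED 0-based half-open for
exports): contained genes are wholly affected, others partially.
Arm/center/X assignment uses the midpoint of the left breakpoint probe
against supplied arm intervals; X is always X, and autosome positions
outside every arm interval default to center.

Catalog statistics: chi-square goodness-of-fit of per-chromosome
deletion and amplification counts against probe-share expectations;
one-way ANOVA of raw midpoint-to-midpoint lengths by strain and by
chromosome (groups with fewer than 2 indels are dropped with a warning;
indels found in several strains count once per strain); and Welch's
two-sample t-test of lengths on autosome arms versus centers plus X.

## Parsimony trees from deletion markers

Wagner parsimony weighs gain and loss equally and presumes no ancestral
state; for binary characters it is the Fitch count, computed here by the
set-intersection pass vectorized across loci, and is independent of
rooting.  Camin-Sokal parsimony treats deletions as derived and forbids
reversal: the minimum number of gains for a character equals the number
of maximal carrier-only subtrees of the tree rooted at a deletion-free
ancestor, so the count depends on where that ancestor attaches.  A tree
is scored as rooted at its own base node; the searches build and report
trees based at the first strain's terminal edge, one consistent
convention for enumeration, scoring and output.  For every tree and
matrix the Camin-Sokal score is at least the Wagner score, since an
irreversible scenario is a special case of a reversible one.

Search strategies: exhaustive enumeration of all unrooted topologies
(n ≤ 8; 10,395 topologies at n = 8), exact branch-and-bound (practical
to n = 12; partial trees are pruned because parsimony cost never
decreases as taxa are added), and a heuristic of stepwise addition under
seeded jumbled input orders (default 10 per search) refined by
nearest-neighbor interchange to a local optimum.  All tied optimal
trees found are returned.  Scoring cost is kept low by collapsing
duplicate locus columns into weights, which also makes bootstrap
replicates pure reweightings.

Bootstrap: each replicate resamples the locus columns with replacement
and reruns the search; tied optimal trees contribute fractionally (1/k)
to bipartition counts.  The consensus contains the bipartitions present
in more than 50% of replicates (which are automatically mutually
compatible) with their percentages as support; replicate split sets are
archived so the frequency of any strain group can be queried afterward.
A consensus can carry both methods' percentages as "CS/W" labels.
Consensus trees are reported unrooted (written with a base polytomy);
the data cannot place the root.

## Index of association

For n strains typed at l biallelic loci, pairwise mismatch distances d
over the n(n−1)/2 strain pairs have variance V_D; at linkage
equilibrium its expectation is V_e = Σ_j h_j with
h_j = n/(n−1) · (1 − p_j² − q_j²).  The standardized index of
association I_A^S = (V_D/V_e − 1)/(l − 1) is 0 at equilibrium and grows
with inter-locus association; with l identical columns it approaches
its finite-sample ceiling 1 − θ, where θ is the mismatch probability of
the shared column.  V_D is the population variance over the pair
population and h_j carries the n/(n−1) correction, following the
standard multilocus-LD formulation.  Constant columns are rejected — a
locus with no variation contributes nothing to either variance and
would silently dilute l.

Significance is Monte Carlo: each locus column is permuted independently
among strains, which destroys inter-locus association while preserving
allele frequencies — the null the statistic is designed against (a mere
reordering of locus columns would leave I_A^S unchanged, so that reading
of "scrambling" cannot generate a null).  P is the +1-corrected fraction
of permuted values at least as large as the observed one.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` run the same experiments:
noise-free recovery (6 strains × ~387k probes; every planted indel
recovered with exact breakpoints, zero spurious calls), noisy recovery
at sd 0.25 (40 deletions + 5 amplifications per strain; sensitivity
≥ 0.95, FDR ≤ 0.05, ≥ 90% of breakpoints within ±1 probe),
segmentation agreement with an exhaustive least-squares change-point
oracle on 200 30-probe instances, exactness of branch-and-bound versus
full enumeration and of both scoring functions versus brute-force state
enumeration at n = 6, recovery of a 12-strain clonal genealogy with 30
loci per branch from 200 bootstrap replicates under both methods with
all supports ≥ 95%, I_A^S calibration (mean within ±0.01 of 0 over 100
equilibrium matrices, uniform Monte Carlo P, near-ceiling value and
P ≤ 0.01 under perfect linkage), and LOWESS bias removal (residual
slope < 0.02, deletion mean shift < 0.05 at bias amplitude 0.5).  These
sizes match the study conditions the pipeline is designed for while
keeping a full run in minutes on one CPU.
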
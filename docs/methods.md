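# Methods

## The model: a reverse-time nested speciation process

`cophylokit.simulator` generates a pathogen phylogeny *inside* a fixed,
time-scaled host phylogeny.  The host tree is an input, not a random
object: host speciation events are deterministic, read off the tree's
internal node heights τ_i (measured above the most recent tip, t = 0).
Tips need not be contemporaneous; a serially sampled host tip simply
enters the process at its sampling time τ*_j.

The simulation runs backwards in time from the sampled tips, with one
pathogen lineage per sampled host.  While more than one host lineage is
extant, stochastic events occur at total rate

    λ = λ_P + λ_M = Σ_i C(n_pi, 2)·Λ + n_p·M,

where n_p is the number of extant pathogen lineages and n_pi the number in
host i.  Waiting times are exponential (standard Gillespie updates); a
draw that overshoots the next host node is discarded and the host event is
applied instead — valid by memorylessness of the exponential.  An event is
a **host switch** with probability λ_M/λ (one uniformly chosen lineage
reassigned to a uniformly chosen *different* extant host, recorded as a
unary node on its branch) and otherwise a **within-host speciation /
duplication** (a pair of lineages, uniform over all within-host pairs,
coalesces).  When only one host lineage is extant the host-switch clock is
off.  At each internal host node the two derived host lineages merge; all
their pathogen lineages transfer to the ancestral host, and with
**cospeciation probability P** — one attempt per host node, requiring at
least one lineage on each side — one uniformly chosen lineage from each
side coalesces exactly at the host node's height.  After the host root,
surviving lineages coalesce at constant rate C(n_p, 2)·Λ until one
remains.  Reaching that phase with more than one lineage and Λ = 0 is a
hard error (`NonTerminatingConfigurationError`) rather than an infinite
wait.

Interpretation of the parameters (units matter: host branches are in Ma):

| parameter | meaning | range used here |
|---|---|---|
| Λ | within-host duplication rate, per lineage pair per Ma; effectively net speciation minus extinction | [1e-6, 1] |
| M | host-switch rate, per lineage per Ma; switches are "complete" (followed by speciation) | [1e-6, 1] |
| P | cospeciation probability per host node | [0, 1] |

Each run uses a single seeded `numpy` generator and draws in a fixed order
(waiting time, event type, lineage choices, destination host), so outputs
are byte-reproducible.  Two trees are emitted: an *annotated* tree whose
unary nodes mark host switches (written in a Newick dialect that labels
them, e.g. `HS`), and the *collapsed* strictly binary tree with tips
labeled by host, which is what the distance measures consume.  Useful
consequences used as test oracles: with P = 1 and M = 0 every host always
carries exactly one lineage, so the collapsed tree equals the host tree in
topology, labels and node heights; cospeciation node heights always
coincide exactly with host node heights; the unary-node count equals the
host-switch count.

## Distance measures

All non-kernel measures require the two trees to share one set of tip
labels; `graft_zero_branches` enforces a one-to-one map for real data by
replacing multiply-associated tips with polytomies of zero-length tips
(one tip per association row).  Because duplicate labels would break every
label-matched measure, grafted tips are labeled `host` when unambiguous
and `host|pathogen` otherwise — the only place this package departs from
"label by host" and a deliberate design choice.

Conventions that the literature leaves open were fixed as follows and are
stable across the package:

* **RF** is rooted and normalized by the total number of nontrivial clades
  in the two trees; **nPH85** uses unrooted nontrivial bipartitions over
  2(n−3) and is invariant to rerooting.  nPH85 is purely topological here
  even though it is sometimes tabulated among length-using measures.
* **KF** (branch score) is the L2 norm over the union of unrooted splits,
  pendant edges included; the two root-child edges of a rooted tree merge
  into one split with summed length.
* **pathdist/pathdistw** are L2 norms over tip-pair path lengths in edge
  counts resp. branch lengths; **Node** is the L1 counterpart on edge
  counts.
* **Align** scores branch pairs by the best-orientation minimum Jaccard
  agreement of their bipartition sides and takes an optimal one-to-one
  assignment (Hungarian algorithm; deterministic lowest-index tie-break);
  unmatched branches cost 1.
* **MAST** is the n − |maximum agreement subtree| dynamic program over
  node pairs of rooted binary trees.
* **Trip** is the fraction of discordant rooted triplets.  **TripL**
  replaces the 0/1 score with internal branch lengths: |d1 − d2| for
  concordant triplets and d1 + d2 for discordant ones, where d is the
  internal path separating the triplet's cherry from its outgroup.  The
  absolute (not relative) form is used because it makes TripL respond to
  branch-length discordance like the other length-weighted measures (KF,
  pathdistw, KCw), which is how the measure behaves empirically.
* **KC/KCw** are the Kendall–Colijn vectors of root-to-MRCA depths over
  tip pairs plus per-tip pendant entries, blended by λ_mix (0 topological,
  1 branch lengths).
* **Sim** is 1 minus the symmetrized, branch-length-weighted probability
  that a random point lies on a branch whose subtended clade exists in the
  other tree.

Polytomies (from zero-length grafting) are consumed directly by the
set-based and path-based measures; MAST and the kernels require binary
trees and receive a seeded zero-length resolution.

## The subset-tree kernels

The kernels (kU unlabeled, kL labeled) count subset trees — fragments
rooted at a node that extend toward the descendants but need not reach the
tips — shared by two trees.  The dynamic program is

    Δ(tip, tip)   = 1            (kU)   or   1[label₁ = label₂]   (kL)
    Δ(n₁, n₂)     = decay · exp(−‖ℓ₁ − ℓ₂‖² / (2σ)) · Π_c (s + Δ(c₁, c₂))
    K(T₁, T₂)     = Σ over all node pairs Δ(n₁, n₂)

with ℓ the 2-vectors of child branch lengths and children paired after a
canonical ordering (by descendant tip count, then total subtree length,
then smallest tip label — phylogenies are unordered, so a deterministic
canonical form is required for reproducibility).  Defaults: decay = 0.2,
σ = 2, s = 1 (kU); the labeled kernel fixes s = 0, so only complete
subtrees match and tip labels are decisive — otherwise shared shape
overwhelms the label signal.  Numerical conventions, both recorded in
`KernelConfig.metadata()`: the Gaussian denominator is 2σ (σ acts as a
variance-like scale), and the distance is 1 − cosine score, with cosine
normalization K₁₂/√(K₁₁K₂₂) correcting for tree size.  The kernel sum is
accumulated with `math.fsum` so that K(a, b) = K(b, a) holds exactly, not
just to rounding.  The `kUn`/`kLn` variants divide branch lengths by the
per-tree mean first, making scores invariant to overall evolutionary rate.

The test suite validates the dynamic program against an explicit
fragment-enumeration oracle (every fragment of every node, matched
structurally) on small trees, exhaustively over all 4-tip topology pairs.

## Experiments

**Edge cases.** Three scenarios vary one parameter with the others pinned:
speciation-only (M = 0, P = 0), migration-only (Λ = 1, P = 1),
cospeciation-only (Λ = 1e-6, M = 0).  Default grids: 20 log-spaced points
in [1e-6, 1] for Λ and M, 21 linear points in [0, 1] for P.  Per-measure
mean curves are rescaled to [0, 1] over the grid and summarized by the 0.5
crossing (Λ50/M50/P50), linearly interpolated on the log scale for log
axes, first crossing reported and multiplicity flagged.  The CV (sd/mean)
per grid point is tabulated alongside.

**Latin hypercube.** Λ and M axes are partitioned into n log-spaced
intervals over [1e-6, 1] (a log partition of [0, 1] is undefined at 0, so
the smallest simulated rate is the lower bound), P into n linear intervals
over [0, 1]; a random permutation per axis assigns one interval to each
point and the point is drawn uniformly inside it — every interval used
exactly once per axis.  Replicate r at point i derives its simulator seed
from `SeedSequence(master_seed, spawn_key=(i, r))`, keeping replicates
independent and the whole table reproducible.

**Statistics.** Spearman matrices are computed on average ranks (constant
columns yield NaN, flagged not raised).  Mutual information is the plug-in
estimate on a 10×10 equal-width histogram over observed ranges, in nats;
constrained variants filter rows (e.g. P > 0.8) with a configurable
minimum-sample floor.  The MI estimator choice matters at small n (plug-in
bias ≈ (b−1)²/2n nats), so cross-study comparisons of MI magnitudes are
qualitative.  The pairing randomization test scores every host×pathogen
pair with a cosine-normalized kernel, takes the mean over the true pairing
as observed, and builds the null from means under uniformly random
permutations of the pathogen list (identity allowed — conservative);
empirical p = (1 + #{null ≥ obs})/(n_null + 1) and a normal-approximation
p are reported separately and never conflated, because a percentile like
99.9 from 1,000 draws cannot produce an empirical p of 2×10⁻⁴.  PCA
biplots standardize columns and can exclude measures whose MI against the
focal parameters is below a threshold (default 0.1 nats).

## The surrogate host tree

`fixtures.surrogate_host_tree` generates ultrametric pure-birth (Yule)
trees, rescaled to a requested root age — default 20 tips and 500 Ma,
the scale of a vertebrate host clade.  The construction appends an extra
Exp(n·rate) interval after the n-th birth so no terminal branch has zero
length.  The host tree is an *input* to the model, so any ultrametric
generator suffices for testing the machinery; what a Yule tree does not
emulate is the node-height profile of real timetrees, whose splits are
concentrated by radiations and taxon sampling rather than spread as in a
rescaled pure-birth tree.  Consequently the *qualitative* results
(response directions, measure orderings, correlation grouping) transfer,
while quantitative sensitivity landmarks shift with the host tree: on
surrogate hosts the Λ50 of the topology-group measures sits around
0.006–0.009 /pair/Ma and the M50 of Node/Align/KF around 1e-3 /lineage/Ma,
each within roughly half an order of magnitude of values obtained on a
real pruned timetree host phylogeny.  Tests that pass on surrogates
therefore establish correctness of the machinery and the directionality of
parameter responses, not host-tree-specific constants.

## Problem sizes

The default experiment sizes in the test suite and `scripts/acceptance.py`
(20-tip hosts; 20-point grids with 15–25 replicates; 100 hypercube points
with 10–20 replicates) were chosen as the smallest sizes at which the
sensitivity landmarks and the correlation structure are stable across
seeds; the full-scale study design (500 points × 100 replicates) is
available through the same API and CLI.

## Known limitations

* No pathogen extinction parameter: Λ is a net rate (reverse-time
  coalescence), so extinct unsampled lineages are not represented.
* One sampled pathogen lineage per host tip; host switches are complete.
* Exactly one cospeciation attempt (one pair) per host node; a failed
  attempt simply transfers lineages.
* The MAST/kernel zero-length polytomy resolution is arbitrary (seeded);
  measures on heavily multifurcating inputs inherit that arbitrariness.
* MI magnitudes depend on the binning and estimator; only within-package
  comparisons at a fixed n are meaningful.
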
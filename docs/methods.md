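# Methods

This note documents the models, algorithms, numerical choices, and known
limitations behind each analysis stage, and what the synthetic-data
generator does and does not emulate.

## Parsimony scoring and search

Unordered (non-additive) characters are scored by the Fitch/Hartigan
downpass: at each internal node every state "votes" once per child
state-set containing it; the node's preferred set is the set of
maximum-vote states, and each child short of the maximum costs one step.
For binary nodes this reduces to the classic Fitch intersection/union
rule (used as a fast path); for polytomies the vote rule remains exact
under uniform step costs. Ordered (additive) characters use Sankoff
dynamic programming with step cost |i−j|. Missing cells carry the full
observed state universe of their character, so they can never contribute
steps on their own; polymorphic cells carry their state-set and count as
agreement with any shared state.

The heuristic search is the standard two-phase recipe: a seeded random
addition sequence with greedy stepwise insertion, then tree bisection
and reconnection (TBR) hill climbing. Replicate *r* uses seed
`seed + r`, making runs bit-reproducible and embarrassingly parallel in
principle. On the optimal plateau every distinct topology (identity =
the set of non-trivial unrooted bipartitions) is retained, bounded by
`max_trees_held`; an unlimited pool is the default but can make
low-signal matrices expensive, because each plateau member is itself
TBR-swapped. Zero-length-branch collapse is deliberately off, so tree
counts are comparable to searches that hold all binary resolutions;
counts on plateau-rich matrices are reported but not considered a stable
statistic.

Ensemble indices follow the usual definitions over all included
characters: CI = Σmin/L, RI = (Σmax − L)/(Σmax − Σmin), RC = CI·RI,
where a character's minimum is the smallest number of states covering
all of its cells minus one (an exact set-cover; the state counts are
tiny) and its maximum is its length on the star tree, which for
unordered characters equals scored-tips minus the best achievable
frequency of a single state. When the matrix has no parsimony-informative
variation, RI is undefined and reported as absent rather than forced.

Bremer decay uses reverse-constraint search: the same heuristic search
with a large constant penalty added to any tree containing the clade's
bipartition, so the hill climber is free to pass through constrained
trees but never rests on one. The decay index is the penalised optimum
minus the global optimum; trivial bipartitions are reported as infinite.
This trades the memory cost of suboptimal-tree pools for one extra
search per clade.

## Time-calibration

Tip ages default to the FAD because diversity counting and trend fitting
both treat a taxon as existing from its first appearance; a midpoint
option exists. Initial node ages follow the oldest-descendant rule,
which necessarily creates zero-length branches. Two smoothing methods
are provided, since practice varies:

* **mbl** (default): every branch is forced to at least `min_duration`
  (default 1 Myr) by pushing ancestral nodes older.
* **equal**: each chain of zero branches is spaced evenly under the
  closest ancestral positive branch, processed root-to-tip.

The root is finally pulled back to at least the oldest tip plus
`root_extension` (default 1 Myr), which also guarantees the "equal"
method a positive span to distribute. Both constants are conventional
round values; with `min_duration = 0` and `root_extension = 0` the
calibration is exactly the oldest-descendant rule, which the tests
exploit. Polytomies are calibrated as hard polytomies.

## Phylogenetic diversity

A lineage's temporal span is its branch duration; terminal branches
extend through the tip's observed range to its LAD, so one terminal
lineage covers both its ghost segment and its sampled duration. A
lineage counts in a bin when the two intervals overlap, with bins and
lineage spans both half-open at their younger end: a lineage ending
exactly on a shared bin boundary counts once, in the older bin, and a
point range counts in the single bin containing it. An internal branch
crossing a bin with no tip in it still counts — that is precisely the
ghost-lineage contribution. Counting by presence at the bin midpoint is
available as an alternative rule. Taxa outside the tree are added by
their raw ranges; a terminal standing for several species can be
expanded into its member species' ranges, in which case the members
replace the terminal's own interval and the stem counts only where no
member does.

## Disparity

Dissimilarity between two taxa is the proportion of comparable cells
(scored in both) whose state-sets are disjoint. A shared polymorphic
state counts as agreement; any stricter rule would let a taxon differ
from itself under re-scoring. Pairs with no comparable cells are
undefined; `drop_undefined_taxa` greedily removes the taxon in the most
undefined pairs until none remain (this mirrors the practical situation
of a skull-only taxon versus postcranium-only taxa, which cannot be
compared at all).

Principal coordinates: Gower double-centering of −½d², symmetric
eigendecomposition, scores = eigenvectors × √eigenvalue. The Cailliez
constant — the smallest additive constant making the configuration
Euclidean — is the largest real eigenvalue of the standard 2n×2n
companion problem and is applied to the off-diagonal before
re-embedding; it is computed only when the uncorrected matrix actually
has negative eigenvalues beyond tolerance, so Euclidean inputs report a
constant of exactly zero. Axes with eigenvalue ≤ 1e−10 are dropped; the
number of retained axes is therefore data-driven rather than fixed,
since it depends on the taxon count of the particular matrix. The full
retained set reconstructs the corrected dissimilarities to well below
1e−8, which the tests assert.

Per-bin disparity uses the mean pairwise dissimilarity (computed on the
raw dissimilarities, matching its definition) and the sum of per-axis
sample variances (n−1 denominator). Confidence intervals are 2.5/97.5
percentiles over resamples without replacement at a common sample size,
defaulting to the smallest bin's taxon count so sampling intensity is
equal across bins; the resampling generator is seeded and recorded.

## Body-size evolutionary models

Three models of a continuous trait (trunk length, mm) on the time tree:

* **stasis** — white noise, tips i.i.d. N(mean, variance); ignores the
  tree entirely, 2 parameters;
* **bm** — Brownian motion, covariance σ²·C where C holds shared
  root-to-ancestor path lengths in Myr, 2 parameters;
* **trend** — BM plus drift, E[tip] = root + μ·(root-to-tip Myr),
  3 parameters. Identifiable only on non-ultrametric trees; an
  ultrametric input is refused rather than silently fitted.

Within-taxon measurement error enters as sd² on the covariance diagonal.
One global sd is the default; after a natural-log transform the sd is
transported per tip by the delta method (sd/value), because a single
absolute sd cannot be correct on the log scale across a five-fold body
size range. Location parameters (root state, trend) are profiled out by
generalised least squares via Cholesky factorisation; the step variance
is optimised on the log scale with bounded scalar minimisation
(tolerance 1e−10 in log-variance, bounds e±25). Likelihoods match
brute-force multivariate-normal evaluations to 1e−8. Stasis with a
global sd has a closed-form ML (variance clipped at zero when the
measurement variance exceeds the total); the all-equal, sd = 0 case is
degenerate and flagged rather than raised. Models are compared by AICc
(−2lnL + 2k + 2k(k+1)/(n−k−1)) and Akaike weights.

A practical identifiability note: with the generator's default 55 mm
measurement sd (variance 3025 mm²) and a 20 mm²/Myr step variance on
trees ~25 Myr deep, the Brownian signal is a minor share of each tip's
variance and the ML step variance frequently collapses to the zero
boundary. Parameter-recovery checks therefore simulate without
measurement noise; they recover the step variance and trend within a few
percent (medians across hundreds of replicates at 28 taxa). Model
*selection* (BM vs trend) remains reliable at the full noise level and
is tested there.

## Synthetic data generator

The generator emulates an early-Mesozoic marine-reptile study system.
Defaults are the study-scale conditions: 32 taxa, 207 characters with
states 0–2 and a 40% missing fraction, a 205–175 Ma window with Lower
Jurassic sampling bins, a 55 mm measurement sd, and trend parameters of
16.1 mm/Myr drift with 20 mm²/Myr step variance around a 1000 mm root
state.

* **Tree + ranges**: a forward birth process (default 0.4 splits/Myr)
  in which each lineage is also terminated — last sampled — at 0.12/Myr;
  splitting freezes once the target taxon count is reached, so the tip
  count is exact, and the simulation restarts on early extinction. A
  tip's FAD is its branch end; its LAD is an exponential range-length
  (mean 2 Myr) younger, truncated at the window.
* **Characters**: a symmetric k-state Markov process along the true
  branch durations at 0.01 changes/character/Myr. This rate was chosen
  for realism of signal structure: terminal branches of ~20 Myr then
  differ in under a fifth of characters (no saturation) while a 2 Myr
  internal branch accumulates several shared changes on a 200-character
  matrix. Cells are masked missing i.i.d.; an optional block mask blanks
  a contiguous character range per taxon to emulate an anatomical region
  a fossil does not preserve.
* **Traits**: exact multivariate-normal draws under whichever model is
  configured, using the same covariance construction as the fitters,
  plus measurement noise.

One master seed feeds independent per-component substreams, so each
stage regenerates deterministically in isolation.

What the generator does **not** emulate: correlated characters or
morphological integration, among-character rate variation,
non-uniform missing-data structure beyond the block mask, taphonomic
biases in sampling through time, and taxonomic error. Passing tests on
these data show the machinery is correct under its own assumptions, not
that real matrices satisfy them.

Because the tree process produces some internal branches far shorter
than 1 Myr, a strict consensus legitimately collapses clades no
character had time to mark. Topology-recovery checks therefore score
recall on *resolvable* clades (subtending branch ≥ 2 Myr), where
recovery exceeds 90% across seeds at the default rate.

## Pipeline

`run_pipeline` wires the stages in dependency order, skips stages whose
inputs are absent (with a logged warning), halts naming the failing
stage otherwise, and writes a versioned JSON report plus per-stage
outputs and a one-JSON-line-per-event log. Given identical inputs,
config and seed, the report is byte-identical across runs.

## Known limitations

* The TBR plateau walk revisits neighbour topologies of every
  equal-length tree; on matrices with thousands of optimal trees an
  unlimited pool is slow — cap `max_trees_held` when the tree count
  itself is not of interest.
* Ordered characters use exact Sankoff scoring but the search's fast
  path is tuned for unordered data; searches on heavily ordered
  matrices are slower.
* Bremer decay by reverse constraint finds an upper bound that equals
  the true decay when the constrained search succeeds; on larger
  matrices the same search-hardness caveats apply as for the optimum
  itself.
* The trend model's step variance is weakly identified when measurement
  variance dominates (see above); report and interpret Akaike weights,
  not point estimates, in that regime.
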
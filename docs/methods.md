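# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `phyplace`, in the spirit of a statistical methods
appendix.

## Trees, edges and the error metric

Trees are rooted node structures with optional branch lengths and node
ages (Ma, present = 0). All placement bookkeeping happens on *unrooted*
bipartition keys: an edge is identified by the frozenset of tip labels
on the side not containing the lexicographically smallest tip. This
makes edge identities stable across I/O, re-rooting and child
reordering, and collapses the two rooted child edges of a bifurcating
root into the single unrooted branch they represent. Newick parsing and
writing go through dendropy; the writer emits children in label-sorted
order so serialization is canonical.

The nodal distance between two edges counts the nodes strictly between
them on the unrooted backbone: 0 for the same edge, 1 for adjacent
edges. This is the breadth-first-search distance on the line graph of
the tree. The normalizer of the scaled error is the maximum nodal
distance from the true edge over all backbone edges, which equals the
attachment node's eccentricity minus one for binary trees; computing it
as a maximum over edges guarantees d_s = d/(ε−1) ≤ 1 in every case,
including degenerate star-like backbones. Whether the original analyses
counted path endpoints is not documented anywhere we could check; the
convention here (same edge = 0, adjacent = 1) is fixed by the
requirement that d = 0 mean "correct branch" and max d = ε − 1 hold by
construction.

Placements come in four kinds: single (one query), and for two queries
cherry (sisters on one branch), sequential (both on one branch, one
rootward of the other) and independent pair (two distinct branches). A
backbone with E edges admits E singles, or E cherries + 2E sequentials +
E(E−1) pairs; the parsimony engine enumerates them exhaustively, which
for one or two queries strictly dominates heuristic rearrangement
searches and is deterministic.

## Continuous characters

Log-ratio characters are ln(Σ numerator segments / Σ denominator
segments) of inter-landmark distances (natural logs throughout; the
base is irrelevant after z-scoring and only rescales raw/range
analyses). The size filter keeps a ratio iff its Pearson correlation
with log centroid size lies strictly inside (−0.3, 0.3); the default
correlates per-specimen values, with species means as an alternative.
Intraspecific variation over n specimens is summarized as the 95% CI of
the mean using the normal quantile 1.959964 (the convention of the
original protocol; Student's t is available via the `z` argument), so a
single specimen yields a degenerate interval. Scaling constants (unit
range or z-score) are estimated from extant species' means only and
applied to all rows including fossils — fossils are the objects being
placed and must not influence the scale. Range scaling over all rows is
available as a switch.

## Parsimony

Two kernels cover the combined matrix:

* Unordered characters: unit-cost Sankoff dynamic programming,
  vectorized across characters. Tip cost vectors are 0 on the states in
  the cell (polymorphism = ambiguity, resolved best-case) and 0 on all
  observed states for missing cells. This reduces to Fitch on binary
  trees and remains exact on polytomies.
* Ordered discrete and continuous characters: interval (linear)
  parsimony. Each child passes its parent a flat-bottom V-shaped cost
  profile with slopes ±1; the sum of k such profiles is minimized
  exactly between the k-th and (k+1)-th order statistics of the pooled
  child interval bounds, which is the classic two-child Farris rule and
  generalizes it to polytomies. 95% CI cells are intervals; point means
  degenerate intervals; ordered polymorphisms the spanning interval
  [min observed, max observed] (the additive convention — an
  approximation for non-contiguous state sets); missing cells unbounded
  intervals contributing zero length.

Minimum conceivable lengths (for homoplasy h = length − minimum) are
max(0, max lo − min hi) for interval characters and, for unordered
characters, the size of the smallest state set hitting every observed
cell minus one (exact hitting-set search; state spaces are ≤ 6).
Implied weighting scores Σ w_c·h_c/(h_c + k_c); under extended implied
weighting the homoplasy hidden in missing entries is extrapolated as a
proportion R of the observed homoplasy per observed cell, which folds
into the concavity as k_c = k/(1 + R·m_c/o_c) (m, o = missing and
observed counts). This form is the package's own: it satisfies k_c = k
at R = 0 or m = 0 and decreases monotonically in the missing fraction.
Exact numeric agreement with other implementations of
missing-data-adjusted concavities is not guaranteed. Parsimony-
uninformative discrete characters (fewer than two states each fixed in
two or more species; polymorphic observations count toward no state)
receive weight zero everywhere.

Bootstrap support resamples weighted characters as exchangeable columns
(multinomial counts over the active characters); per replicate the
co-optimal placements share one unit of mass equally. Co-optimal sets
use an absolute score tolerance of 1e-9; ties are always reported, and
downstream error metrics use the median of the tied placements' scaled
errors.

## Strict-clock Brownian ML

Characters are independent Brownian motions with per-character rates
σ²_c (trait²/Myr) constant over the dated tree. Felsenstein pruning
yields, per character, the contrast sum of squares Q_c at unit rate,
the summed log contrast variances, and the effective root variance;
with the root state profiled by GLS the log-likelihood is
−½[n log(2πσ²) + log|V| + Q/σ²] and the profile rate is Q_c/n (a
shared-rate variant pools ΣQ_c/(nC)). REML (n−1, contrasts only) is
available and is invariant to rooting; the ML profile-root likelihood is
*not* root-invariant, so placement evaluation eliminates toward the
model root. For speed, downward messages are precomputed per edge
together with the off-path sibling messages along the path to the root;
evaluating a candidate attachment then costs O(path length × C) instead
of a full tree traversal.

Per branch, the attachment age ranges over [max(child age, lower
bound), parent age] and the fossil tip age over [lower, min(upper,
attachment age)]; extant queries pin the tip age to 0. The
two-dimensional profile likelihood is maximized by a deterministic
coarse scan (9 × 5 including the interval endpoints) followed by
coordinate-wise bounded Brent refinement (tolerance 1e-8 in
log-likelihood, verified against dense grids to 1e-4). Branches whose
age interval lies entirely below the lower bound are reported as
infeasible; if no branch is feasible an error lists the violations.
Query cells missing a character drop that character from the fit (a
constant shift across candidate branches). Phylogenetic PCA estimates
the evolutionary covariance by GLS against the tree covariance and
rotates the data (no truncation); query rows are rotated with the same
center and loadings. Missing cells are refused with instructions to
impute or exclude explicitly.

## Bayesian variable-rate placement

The no-clock model frees every branch length (units of accumulated
Brownian variance, rate ≡ 1); the likelihood is weighted REML via
contrasts, so it is invariant to rooting and the chain operates on an
unrooted representation (basal multifurcation; one parameter per
unrooted branch). Character weights follow the
reference-versus-random-trees protocol: f_c is the fraction of random
topologies (uniform over labelled topologies via random sequential
addition, branch lengths freshly optimized by coordinate-ascent REML)
against which the reference tree has the higher per-character
likelihood; exact ties count as non-wins. Modes: equal, fractional
(weights = f) and binary (zero below the 0.95 cutoff). Weights are JSON
serializable so identical weights can be reused across runs.

The branch-length prior is compound Dirichlet: tree length T ~
Gamma(shape 1), proportions flat Dirichlet, giving log density
log β − βT + log Γ(m) − (m−1) log T over the m branch lengths. The
published description of the Gamma's second parameter ("beta equal to
the sum of branch lengths of the ML tree") is ambiguous between a rate
and a mean; the default here anchors the *mean* at the ML tree length
(rate β = 1/T_ML), with the literal rate-β = T_ML reading switchable
(`literal_beta=True`). Moves: single-branch multiplier, whole-tree
rescale, and query reattachment (prune one query, regraft to a
uniformly chosen branch at a uniform position, keeping the pendant
length; Hastings ratio = target length / merged length). All two-query
arrangements are reachable through single-query reattachment because a
query pendant is itself a valid target, so no dedicated cherry move is
needed for ergodicity. Chains are bit-reproducible from the seed.
Prior-only runs (likelihood disabled) reproduce the Gamma moments,
which validates the sampler.

Convergence uses the Geweke z (window means 10%/50%, variances adjusted
by the integrated autocorrelation time, Geyer initial positive
sequence) and ESS = n/τ. The burn-in protocol starts at 10%, escalates
by 10% while |z| ≥ 1.96 or ESS < 500, and flags a 2× re-run beyond 50%.
Posterior summaries are empirical frequencies per (branch, mode) from
post-burn-in samples — an edge-frequency summary rather than a
maximum-clade-credibility tree, which needs no external software and is
exactly recountable from the samples. Leave-one-out with this engine
uses the maximum-posterior branch.

Default chain length is a desk-scale 200,000 generations sampled every
100; production-scale settings (millions of generations, 1,000 random
trees for weights) are plain configuration values.

## Evaluation

The leave-one-out driver prunes each extant species, asks an engine for
its co-optimal placements, and records d, ε−1 and the median-of-ties
d_s. AUC is the exact integral of the empirical step CDF of d_s, which
equals 1 − mean(d_s); a trapezoid variant over the sorted curve points
is provided (differences < 1/(2n)). Species an engine cannot place are
excluded with a logged warning rather than assigned worst-case error.
The cost-scheme grid is the full factorial of 3 scalings × (equal ∪ 14
concavities × 5 R values) = 213 schemes; per-character placement
lengths are cached per scaling so the 71 weighting settings per scaling
reuse one set of tree scorings, and all AUC-maximal schemes are
reported on ties.

## Synthetic data

The generator mirrors the empirical study shape: 45-tip dated Yule
trees (birth rate 0.04/Myr, giving root ages near the deep-testudinoid
~90 Ma scale), 25 continuous characters (Brownian rate 0.01/Myr²·trait²
with lognormal among-branch rate multipliers, sd 0.5 by default; sd 0
recovers the strict clock, so one generator serves both Brownian
engines), specimen sampling with ~20% multi-specimen cells (1–10
specimens, within-species sd = 0.2 of the root-depth Brownian sd), and
60 discrete characters (2–5 states, ~40% ordered, Mk rate 0.004/Myr,
15% polymorphism by adding an adjacent/other state, 10% missing).
Queries are evolved on the *placed* tree and then pruned, so the truth
is exact. Host-edge policy: `random` (default), or `pendant`/`longest`
for clear-signal fixtures — attachment mid-way along the longest
(pendant) branch with a short query pendant, conditions under which a
correct method should concentrate on the true branch. Deep attachments
are intrinsically weakly identified under the no-clock model (free
branch lengths absorb much of the signal), which is a property of the
inference problem, not of the implementation.

What passing synthetic tests do *not* show: robustness to correlated
characters (characters are simulated independently), taphonomic
deformation, non-random missingness, or model misspecification beyond
lognormal rate variation. Real matrices also carry far fewer effective
characters per branch than the clear-signal fixtures.

## Problem sizes used in tests and the acceptance script

Oracle comparisons run on trees of ≤ 7 tips (exhaustive enumeration)
and 5–6 tips (dense MVN). Statistical recovery uses 20 seeds of the
45-tip default dataset at low noise for parsimony leave-one-out, a
25-tip/100-character clear-signal fixture with a 200,000-generation
chain for the Bayesian posterior, and 300,000 prior-only generations
for prior recovery. The acceptance script runs the 45-tip LOO for
parsimony and strict-clock ML, 10 single-fossil and 5 cherry fixtures,
a 1,000-replicate bootstrap, and one desk-scale Bayesian chain; the
REML weight computation in examples uses 25–30 random trees. These
sizes are the package's defaults for quick, reproducible desk-scale
runs; all scale up by configuration.

## Known limitations

* Extended implied weighting uses the package's own concavity
  adjustment (documented above); cross-software score identity is not
  expected beyond plain implied weighting.
* The parsimony engine never searches tree space; it only places 1–2
  queries on a fixed backbone.
* The ML engine assumes complete continuous rows for reference species.
* The Bayesian engine models continuous characters only (no discrete
  likelihood), and two-query chains mix more slowly than single-query
  chains because reattachment acceptance drops when the posterior is
  concentrated.
* Sequential-placement order is defined relative to the original rooted
  reference tree; for queries placed on the root branch the orientation
  follows the reference root's side conventions.
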
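# Methods

This note records the models, conventions and design choices behind
`socioscope`, in the order the pipeline applies them.

## Data model and association scoring

A *sampling period* is one scan occasion: every present group member is
recorded with behavior and nearest neighbor (an individual within one body
length, or an explicit `NONE` token when alone). The recorded
nearest-neighbor relation is asymmetric; the simple ratio index (SRI) is
dyadic, so the relation is symmetrized: `a` and `b` are in association in a
period if either named the other. An individual counts as observed in a
period if it appears as a scanned individual or is named as a neighbor.

For each unordered pair, periods in which at least one member was observed
are partitioned into the four SRI classes — `x` (both observed, in
association), `y_ab` (both observed, not in association), `y_a` / `y_b`
(only one observed) — and `SRI = x/(x + y_a + y_b + y_ab)`. "Observed
alone" (the `NONE` token) matters only as absence of association; it does
not form a separate count class, which keeps the four classes an exact
partition of the joint observation history. All-zero counts yield SRI 0
with a warning.

Network construction: nodes are the harem members at least 12 months old
(unknown ages are retained); edges carry positive SRI weights. Degree
counts positive-SRI edges; zero-SRI dyads are non-edges. Density is edge
count over `C(n,2)`. Mean SRI and CV of SRI, per node and per harem, are by
default computed over *all* co-resident dyads including structural zeros —
excluding them would conflate density with heterogeneity — and
`include_zero_dyads=False` toggles the other convention. CVs use the sample
standard deviation (n−1): harems are small and the unbiased dispersion
estimate is preferable; the choice is visible in the API so the population
variant can be recomputed.

## Preferred-associate permutation test

The scientific question: is the harem's CV of bond strengths higher than
expected if individuals associated indiscriminately? The test refuses
harems of ≤ 4 network members, where strong bonds with every member are
simultaneously attainable and the CV is uninformative.

Two null models are implemented, because the obvious one is degenerate:

* **Edge shuffle** (`method="edge_shuffle"`): place the observed multiset
  of SRI weights on a uniformly random simple graph with the same node and
  edge counts (G(n,m); isolated nodes permitted). Any statistic of the
  *dyadic-SRI multiset* — including the CV of dyadic SRIs, with or without
  structural zeros — is invariant under this null, since the replicate's
  value set is identical to the observed one. The edge-shuffle test
  therefore uses the CV of **per-node mean SRIs**, which does respond to
  how weights are arranged on the graph. This null is exactly enumerable on
  small instances (labeled graphs × weight assignments) and the sampled
  distribution is checked against that enumeration. Note its power target
  is weight *arrangement* (e.g. strong weights concentrated on few
  individuals), not weight heterogeneity per se: a single preferred dyad
  barely moves node means, so this null has little power against it.

* **Node-label data-stream permutation** (`method="node_label"`, default;
  requires the scan records): within every sampling period, permute the
  identities of the present individuals, re-tally SRIs, and recompute the
  CV of dyadic SRIs (zeros included). Presence, per-period group structure
  and gregariousness are all preserved; only the cross-period *identity*
  of who associates with whom — exactly the preferred-associate signal —
  is destroyed. Under an exchangeable null process the observed statistic
  is exchangeable with the replicates, so the test is calibrated, and a
  consistently preferred dyad inflates the observed CV far above the null.
  This is the data-stream style of permutation generally recommended for
  association indices, and it is the null used for calibration and
  recovery validation.

p-values use the count-over-n convention — the fraction of null statistics
≥ the observed (ties toward the tail) — with `(count+1)/(n+1)` available
via `convention="plus_one"`. Every stochastic routine takes an explicit
integer seed.

## Communication networks

Co-occurrence unit: an edge weight counts *postures* in which two
components co-occur (postures are the coded unit and edge thickness should
reflect co-occurrence frequency); `unit="interaction"` counts distinct
interactions instead.

Cleaning: postures containing a component observed in fewer than two
distinct interactions are removed, since such components cannot support
co-occurrence estimates. Removal can drop another component below
threshold, so the filter iterates to a fixpoint by default
(`to_fixpoint=False` gives the single pass; pass count is reported).
Components appearing only in removed postures leave the node set entirely.

Diversity is the number of connected (degree ≥ 1) nodes. Adjusted density
corrects the pair denominator for mutually exclusive morphological groups:
`|E| / (C(n,2) − Σ_g n_g(n_g−1)/2)`, evaluated on the node set of the
network at hand — node-subsampled nulls recompute group sizes from the
subset, since the correction concerns realizable connections among present
nodes. With all groups singletons the correction vanishes and the measure
equals plain graph density.

Cross-period nulls resample the reference (larger-effort) period:

* **Diversity jackknife**: draw `n_sub` postures without replacement
  (`n_sub` = the comparison period's posture count), rebuild the network,
  record diversity. The comparison period's observed diversity is placed
  against the null.
* **Density node subsample**: induce the subgraph on a uniform random node
  subset of the comparison period's node count — preserving the sampled
  nodes' connectivity — and recompute adjusted density. This is the null
  of pure repertoire-size reduction without loss of combinatorial
  flexibility.

Both are two-tailed at the 0.025/0.975 percentiles. Cutoffs are the k-th
extreme order statistics of the null with `k = ⌊α/2·(n_perm+1)⌋`: the exact
permutation construction, for which each tail rejects with probability
`k/(n_perm+1) ≤ α/2` (equality for continuous statistics) at any
permutation count. Interpolated quantiles would round outward on discrete
statistics such as diversity counts and make the rule needlessly
conservative. Exact ties with a cutoff are non-significant.

Modules come from greedy agglomerative (Clauset–Newman–Moore) modularity
maximization on the weighted graph (networkx implementation,
deterministic); isolated nodes form singleton modules and an edgeless graph
has Q = 0. The returned Q is checked in the test suite against an
independent closed-form recomputation from the partition. The conventional
`Q > 0.3` threshold for "discrete modules" is reported as an annotation
only, never used as a filter. Module flow across periods is a long-format
table (retained / lost / gained, with `LOST` marking components absent from
the later network), plus a per-modality loss summary.

## Activity budgets

Budgets are computed over coded time only: a category's proportion is its
summed interval duration divided by total coded duration per focal and
period, within the 5-minute subsample windows; uncodeable time is excluded
from the denominator. Overlapping intervals within a focal's window are a
hard error. Passive social categories (social grazing, social rest) are
distinct from their concurrent maintenance behaviors, so proportions never
double-count. Interaction rates count only *active* social interactions
(affiliation, aggression, greeting, harem maintenance, sex, play) per
30-minute block. Statistical comparisons (Mann–Whitney, GLMM/LMM, AICc
selection, chi-square) are deliberately out of scope: the module emits
analysis-ready long-format tables for standard routines.

## Synthetic data

`simulate_scans` emulates harems of 2–13 members (the field range): per
period each individual is present with probability 0.95, alone with
probability 0.2, otherwise names a neighbor among present harem-mates.
Planted preferred dyads are specified by an *association-probability
multiplier*: the dyad's symmetrized per-period association probability is
`m ×` the baseline dyad's (capped at 0.95), realized through per-individual
choice weights so draws stay independent per individual and are symmetrized
downstream, like the real scoring.

`simulate_interactions` draws a latent context per interaction; a component
appears in a posture with probability `√p_within` when its module matches
the context and `√p_between` otherwise (so two active-module components
co-occur with ≈ `p_within`), scaled by per-component base rates (rarity
control), masked by per-period lost-component sets, and constrained to at
most one component per morphological group by construction. `force_rare`
injects a component into an exact number of interactions for
cleaning-filter tests. `simulate_budgets` apportions window seconds to
categories by largest remainder (exact targets, optional Dirichlet
jitter).

What the generators do *not* emulate: spatial structure and movement,
temporal autocorrelation between scan periods, posture ordering within
interactions, observer effort imbalance, and age/sex-specific behavior.
Passing tests therefore demonstrate correctness of the estimators and the
calibration/power of the resampling machinery under exchangeable,
well-mixed data — not robustness to the autocorrelation or unevenness of
real field data.

## Validation studies (evaluation module)

Study sizes are scaled-down but structurally faithful analogues of a field
campaign, chosen once: single harems of 6 adults over 40 sampling periods
(preferred-associate calibration at multiplier 1 over 500 replicates,
recovery at multiplier 3 over 200); 81-component inventories (24 components
in multi-state morphological groups, 57 free) with per-component rarity
drawn log-uniformly over 10^[−2, −0.2], ~100 interactions per dataset, 400
replicate datasets for the communication-test calibrations; 200 inner
permutations per replicate (the analysis default is 1000 — the paper-scale
convention — but the exact-rank cutoffs keep the decision rule
level-accurate at any permutation count). Communication-test calibration
generates the observed period under each test's own null (a uniform posture
subsample for the diversity jackknife; a uniform induced node subset for
the density null), which makes the observed statistic exchangeable with the
null replicates, so the measured rejection rate isolates the correctness of
the resampling and decision machinery.

Known limitation, stated plainly: when the comparison period is an
*independent* dataset observed at lower effort, the diversity jackknife
inherits a cleaning-scale mismatch (cleaning at low effort removes more
than cleaning the reference then subsampling), and the density
node-subsample null does not model posture-sampling noise at all, so both
tests read pure effort differences as repertoire change. This mirrors the
tests' published design; users should match or model observation effort
before interpreting a rejection as biology.

## Numerical conventions

Degenerate inputs return missing values with warnings rather than raising,
wherever the quantity is genuinely undefined: CV of fewer than two values
or of a zero mean, density of a < 2-node network, adjusted density with no
possible pairs, regression with < 3 shared dyads. Validation failures at
ingest are hard errors with row-numbered diagnostics. All resampling takes
explicit seeds; the pipeline derives per-stage seeds deterministically from
one master seed, and a fixed (inputs, seed, flags) triple reproduces a run
byte-for-byte.
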
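# Methods

## Problem setting

Given a rooted species tree with branch lengths and a binary genomes × OGs
presence/absence matrix, every unordered OG pair is scored for co-evolution
(association of gains and losses beyond shared ancestry) or contrapositive
evolution (mutual avoidance). All methods reduce a pair to a 2×2 table and a
Fisher exact test; they differ in what the table counts.

## Trees and ancestral states

Trees are taken as rooted exactly as given; no re-rooting. Unnamed internal
nodes receive deterministic `N<k>` labels by post-order rank so externally
produced ancestral-state tables (e.g. pastML's, where a node listed with
several states is uncertain) can be regenerated against the same labelling.
Missing branch lengths default to 1.0 with a warning — only ASA consumes
lengths. Polytomies are resolved to binary by left-fold insertion of
zero-length branches: the event-based test's population size and
no-parallel-change constraint presume binary trees, and zero-length
insertions leave the ASA sums unchanged.

Internal ancestral reconstruction is Fitch parsimony with a deterministic
top-down refinement: each node takes its parent's state when that state is
in the node's preliminary set, otherwise the forced alternative. On binary
trees this labelling (i) attains the parsimony score and (ii) never places
a same-direction change on both child branches of one node — the property
the simultaneous-evolution table requires. When the root's set is {0, 1} the
root is assigned absent by default; the alternative (`root_tie="uncertain"`)
leaves the root uncertain, in which case no change is counted on its child
branches. Branches whose parent or child state is uncertain never carry an
event. External maximum-likelihood tables are accepted for ASA; SEV uses
internal parsimony unless explicitly overridden, and overrides that violate
the no-parallel-change constraint are rejected with the offending node and
OG named.

## The six scores

* **naive** — cells count genomes per joint state; population = #genomes.
* **RLE** — consecutive runs of identical joint states along the depth-first
  leaf order count once. Depends on child order, hence on branch rotation;
  kept primarily as a comparator and as the rotation-sensitivity witness.
* **CWA** — each maximal clade whose leaves all share a joint state counts
  once; paraphyletic groups are not merged. Rotation-invariant.
* **ASA** — the tree is partitioned by tracing each leaf back through
  ancestors with the same certain joint state; leaves stopping at the same
  ancestor form a subtree block. A block's genome count M is corrected by

      Mc = M · Σ bₙ / Σ (bₙ · lₙ)

  over the block's nodes (the block root contributes its stem branch; 0 at
  the tree root), where lₙ counts block leaves at or below n. Only nodes on
  a leaf→block-root path belong to the block: a same-state side branch with
  no block leaves beneath it is not part of any trace-back path and is
  excluded (including it could push Mc above M). The four per-state sums of
  Mc are rounded up to integers (Fisher needs integer cells; ceiling applied
  per cell, with a 1e-9 guard against float noise at integers). The
  `asa_unweighted` variant counts each block as 1. The stem branch is
  included by default because the star-tree identity — the denominator is
  the star tree converted from the subtree — only balances when the shared
  time on which the state arose enters both sums; `include_stem=False`
  (`--asa-stem exclude`) provides the other convention.
* **cotransitions** — events are state changes in the gaps between adjacent
  genomes in the leaf order (+1 gain, −1 loss); population n = genomes − 1.
  An optional collapse flag zeroes an event when the same OG also changed in
  the immediately preceding gap, approximating implementations that ignore
  consecutive changes; the default keeps the pure matrix form.
* **SEV** — events are per-branch changes of the parsimony states;
  population n = number of internal nodes. For all pairs at once,
  k = concordances − discordances is the Gram matrix EᵀE of the event
  matrix; targeted pair lists use a column-wise einsum instead of the full
  product to bound memory.

Both transition methods test the table (|k|, t₁−|k| / t₂−|k|,
n−t₁−t₂+|k|) with a one-tailed exact test, P(X ≥ |k|). If a user-supplied
labelling makes the bottom-right cell negative the observed table is outside
the hypergeometric support; |k| is clamped to the most extreme supported
table and the pair flagged rather than crashing (unreachable under internal
parsimony). Concordance is strictly same-branch: opposite-direction changes
of the two OGs on the two sibling branches of one node are not counted as
discordance — the matrix-product definition; the alternative would require
abandoning the Gram-matrix form.

Weighted methods use a two-sided test by default (both association signs
are of interest); a `greater` alternative is available. Every result
carries the raw p-value, the association sign (of c11·c00 − c10·c01, or of
k), and a direction label that applies the caller's α (default 0.05);
Benjamini–Hochberg adjustment is optional at report time.

## Exact test

The Fisher p-value is computed from log-gamma binomial coefficients with
compensated summation; the two-sided rule sums tables whose point
probability is ≤ the observed one up to a relative epsilon of 1e-7
(the common convention for float ties). The vectorised one-tailed path used
by the transition methods goes through scipy's hypergeometric survival
function; agreement of the two routes, and of both with exact rational
enumeration for every table with N ≤ 30, is asserted in the test suite.

## Simulator

`yule_tree` draws a pure-birth tree: waiting times are exponential with
rate (birth rate × active lineages), a uniformly chosen lineage splits, and
a final waiting period at the full tip count sets the terminal segment, so
trees are ultrametric with expected total length (n−1)/birth-rate (the
root-edge wait is discarded). Default birth rate 1.0, the common pure-birth
default; note this puts the tree depth near ln(n) time units.

`simulate_pair` evolves a joint 4-state continuous-time Markov chain
root-to-tips by exact event-time (Gillespie) sampling per branch, with
per-OG rates gain = exp(α + β + c·x_partner), loss = exp(α − β −
c·x_partner): α sets the overall speed, β is half the log gain/loss
asymmetry (log gain − log loss = 2β + 2c·x_partner at fixed partner), and
c ≥ 0 couples the pair (c = 0 is the independent null). This preserves the
stated roles of the five parameters of the community-coevolution model used
for data generation; exact numerical equivalence with that model's own
implementation is not claimed. The root state is drawn per OG from the
single-OG stationary distribution at partner state 0 (uniform available
behind a flag).

`generate_dataset` concatenates pair columns with per-pair parameters
c ~ U(0.2, 0.75) for co-evolved pairs (c = 0 otherwise), α ~ U(−0.5, 1),
β ~ U(−0.5, 0.3), and co-evolved : independent at 1:99 by default.

What the simulator does **not** emulate: horizontal transfer, lineage
heterogeneity of rates, correlated negatives (all independent pairs are
mutually independent by construction), tree estimation error, and annotation
noise in profiles. Passing tests on this generator therefore demonstrate
correctness of the statistics and the expected qualitative behaviour of the
methods, not their ranking on real prokaryotic datasets, which depends on
how slowly gene content evolves relative to the tree depth.

## Evaluation

Only labelled pairs are ranked. The ranking score is signed −log₁₀ p: pairs
whose point association is co-occurrence rank by significance, contrapositive
pairs at or below zero (an `include_negative` option ranks by |association|
instead). Tie blocks enter the precision–recall curve as one step, and the
area is the interpolation-free step sum Σ (Rᵢ − Rᵢ₋₁)·Pᵢ; positives-at-TPR
returns the true positives at the loosest threshold whose recall reaches the
target.

## Problem sizes and test design

The packaged checks run at desk scale chosen to keep the full suite fast
while leaving each property falsifiable: exact-test enumeration covers all
tables with N ≤ 30; parsimony is checked against exhaustive labelling
enumeration on ≤ 8-leaf trees (500 columns); rotation invariance uses a
64-leaf tree and 50 random rotation sequences; the discrimination study
uses 500-leaf trees with 200 pairs per replicate and positives enriched to
1:19 so that 10 positives exist per replicate. Under these fast-evolving
conditions SEV's PRAUC (~0.65) exceeds the 5× prevalence bar by a wide
margin, but the naive method is not confounded (negatives rarely share deep
single origins when every OG changes many times per lineage) and actually
ranks above SEV — the ordering seen on real data requires slow evolution
relative to tree depth. The corresponding acceptance test documents this
honestly rather than rescaling the simulation to force the ordering.

## Known limitations

* ACCTRAN here is the deterministic binary-state refinement described
  above; it does not implement multi-state ACCTRAN/DELTRAN distinctions.
* SEV's exact test treats |k| as the overlap count of a hypergeometric
  table; when per-OG event counts approach the number of internal nodes
  (fast evolution) the expected chance overlap is large and p-values become
  conservative, although the k-ranking remains informative.
* RLE and cotransitions are intentionally order-dependent; results change
  under branch rotation, which the `rotate-check` subcommand demonstrates.
* All-pairs scoring of the weighted methods loops over pairs in Python;
  they are practical to a few thousand OGs, while SEV/cotransitions scale
  via the matrix product.
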
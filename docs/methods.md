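# Methods

This note records the statistical model behind `ecobnet`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic data
do and do not establish about behaviour on real surveys.

## Data model

The unit of observation is a sample — a seafloor photograph, or a transect
event formed by pooling photographs. Variables carry a role: `taxon` and
`bin_group` columns are non-negative integer counts, `continuous` columns
finite reals, `categorical` columns labels. Missing values are not
permitted: photographic annotation yields complete count tables, and the
package makes no attempt at imputation.

Aggregation from photo to event scale sums counts, averages continuous
columns, and takes the per-event mode of categoricals with ties broken by the
lexicographically smallest label (a determinism choice; ties are rare and no
principled ordering exists).

## Discretization

Count variables map to three states. Zero is its own state: presence of a
single individual is a different ecological fact from absence, unlike, say, a
zero gene-expression read. The low/high boundary is the median of the
positive values only; including the zeros in the median would, for most of
these taxa, collapse "low" onto "zero". Positive values equal to the boundary
map to low — the boundary definition leaves equality unassigned, and mapping
down keeps both bins non-empty more often. A count column whose positive
values never exceed the boundary (constant positives) is flagged: its "high"
state is empty and the variable carries little signal.

Continuous variables get four states at the empirical quartiles
(linear-interpolation quantiles; values equal to a cut map down). Three
states would collide with the zero-state convention these variables do not
have, and two would waste information. A continuous variable with fewer than
four distinct values cannot be quartile-binned; the pipeline drops it with a
warning rather than aborting, since a degenerate covariate (e.g. a depth
column with three fixed survey strata at event scale) should not kill the
analysis — it should either be declared categorical by the user or excluded.

Categorical maps are lexicographic and therefore independent of row order.
Recorded boundaries, cuts and maps are exported alongside the state matrix
and re-applying them to the raw values reproduces the states exactly; this
round trip is tested.

## Pre-filtering

Two guards run before structure search, both aimed at the Type-I artifacts
that zero inflation induces:

* **Rare-taxon filter.** Count variables present in strictly fewer than 1/3
  of samples are removed. Physical variables are never removed by this rule.
  Occupancy is judged at the scale of the table being analysed (photo or
  event), since pooling to events raises occupancy and the filter should see
  what the search sees.
* **Contingency filter.** Every unordered pair of discretized variables gets
  a Pearson chi-squared test (no continuity correction; empty rows/columns of
  the contingency table dropped before computing df = (r−1)(c−1)), and pairs
  with p > 0.25 are barred as edges in all subsequent searches. The
  threshold is deliberately anti-conservative — the filter must only remove
  pairs with essentially no joint signal, never genuinely dependent ones —
  so no multiple-testing correction is applied. Under simulated independence
  the exclusion rate is 0.75 by construction of the p-value, and this
  calibration is tested.

## Scoring and search

Structures are scored by the log BDeu marginal likelihood with equivalent
sample size `ess = 1` and a uniform structure prior, so structures compare by
likelihood alone. The score decomposes over families; the implementation
caches family scores, so the score of a proposal is one table lookup after
its first evaluation.

Search is hill climbing over single-edge add/delete/reverse moves with random
restarts. Each restart draws a random legal DAG (each allowed edge with
probability 0.1, repaired to acyclic) and then accepts strictly improving
legal proposals. A move is legal if it preserves acyclicity, respects the
parent cap (3 — larger parent sets overfit tables of this size and slow the
search combinatorially), and joins no barred pair. `n_iterations` counts
total proposals, split evenly across `n_restarts` (defaults 50,000 / 50; the
evaluation runs use 20,000 / 10 per bootstrap replicate, a scale at which
adding proposals no longer changed the recovered consensus networks on the
synthetic communities). The returned network never scores below the empty
DAG, which is always a candidate. The search is reproducible bit-for-bit
from its seed, and on 3-node problems it attains the exhaustively enumerated
optimum in ≥95% of random datasets (tested).

## Bootstrap consensus

100 subsamples of 95% of the samples are drawn **without replacement** — the
point is robustness to outlier samples, not a sampling-distribution
bootstrap — and one network is learned per subsample with a derived seed.
Per-pair occurrence frequencies are then fit with 1- and 2-component Gaussian
mixtures by EM (scikit-learn, fixed random state, BIC selection). If two
components win, the cutoff is the crossing point of the two weighted
component densities between their means (midpoint of means if they do not
cross there); if one component wins, or EM fails to converge, the cutoff
falls back to simple majority (0.5). On the synthetic communities the fitted
thresholds land around 0.4–0.6, bracketing the low-50s percentages such
occurrence distributions typically produce.

Direction is the majority orientation among the replicates containing the
edge; a forward fraction in [0.4, 0.6] is recorded as a mutual dependency.
Edge strength is the mean influence score over the containing replicates
only — averaging in zeros for absent replicates would conflate occurrence
with strength.

Summary statistics follow the usual network conventions: connectance =
edges / (k(k−1)) and link density = edges / k over the k connected nodes. A
*chain* is a maximal simple path of at least 2 edges in the undirected
consensus graph (not extendable at either end), counted once per distinct
endpoint pair with the longest such path setting the pair's length in edges.
This counting rule is one of several defensible readings of "series of
dependencies spanning more than two nodes"; it is fixed here and verified
against brute-force path enumeration on small graphs.

## Influence score

CPTs are fit with add-one smoothing — `(count + 1) / (row total + arity)` —
which keeps every entry positive and the Bayes inversion below well defined.
Node marginals are the plain empirical state frequencies.

For an edge parent → child, every configuration π of the child's other
parents and every ordered pair of parent states p < p′ casts a vote: +1 if
the child CDF under p′ lies at or below the CDF under p everywhere and
strictly below somewhere (a shift toward higher states), −1 for the reverse
dominance, 0 if the CDFs cross. Votes are weighted by the probability of π
(product of the other parents' empirical marginals — conditioning on or
jointly weighting other-parent configurations are alternatives, but the
product weighting is computable from the fitted CPT set alone and the choice
only matters for nodes with ≥2 parents) and averaged. Consequences, all
tested: IS ∈ [−1, 1]; strictly monotone tables give exactly ±1; identical
rows give 0; reversing the child state order negates the score; and IS = 0
does *not* imply independence — a V-shaped table scores 0 while the
chi-squared test still rejects independence, which is precisely the
non-monotone case the score is designed to flag as 0.

## Chain inference

To predict the effect of forcing node A into a state on node B, the
computation walks the chain of dependencies between them in the consensus
graph — the shortest undirected path, lexicographic-smallest on ties (a
deterministic single chain; no averaging over alternative paths). Each step
multiplies by a transition matrix:

* **along** a fitted edge u → v: P(v | u) from v's CPT with v's other
  parents marginalized by their empirical frequencies;
* **against** a fitted edge v → u: Bayes inversion
  P(v | u) = P(u | v) P(v) / Σₘ P(u | vₘ) P(vₘ), defined everywhere thanks
  to the smoothing.

Marginalizing other parents (rather than conditioning on them) makes each
step a function of the chain alone. On singly connected structures — each
node with at most one parent — the composition of steps is the exact
conditional, and the implementation matches brute-force joint enumeration to
1e−10 over random trees (tested). On graphs with colliders or multiple
paths the chain result is an approximation; exact inference over the full
joint is deliberately out of scope, with the enumeration routine retained
only as a small-scale reference.

A state-change report contrasts two forced source states and tabulates
Δp(state) = P(state | to) − P(state | from) for every node. The scalar
summary `mean_delta_p` is the mean of |Δp| over all states of all *connected*
nodes, equally weighted; unconnected nodes appear in the tables with Δp = 0
but do not dilute the mean. On homogeneous noisy-copy chains the maximum
|Δp| is non-increasing in chain length — forced-state effects attenuate with
network distance — and this is tested.

## Synthetic communities

The generator emulates the structure of a benthic photo survey: a 3-level
substrate root and a continuous depth covariate drawn once per ~25-photo
transect event and shared within it (habitat is homogeneous at transect
scale); taxa with 3 abundance states generated from a known random DAG
(substrate → taxon and taxon → taxon edges under the parent cap); counts
emitted from disjoint uniform ranges (low 1–3, high 6–12, state 0 always 0),
so that discretization recovers the latent states exactly when low/high are
balanced and tests stay deterministic. Depth is generated unconnected, as a
realistic decoy covariate.

Each taxon CPT row is `lam · (point mass at the monotone target state) +
(1 − lam) · uniform`, then tilted toward state 0 by `zero_weight`; the
monotone target rises (or falls, for negative edges) with the mean of the
parents' normalized states, so every edge's influence-score sign is known by
construction, `lam = 0` is the no-signal limit and `lam = 1` (with zero
tilt) gives deterministic tables with IS exactly ±1.

Two zero-inflation mechanisms are deliberately separate. `zero_weight`
(default 0.10) sets the network taxa's zero tilt; the default is chosen so
that taxa at the end of dependency chains — whose zero probability compounds
along the chain — still exceed the 1/3 occupancy threshold, as the retained
taxa in a real analysis necessarily do. The raw table's heavy zero
inflation is instead carried by 27 rare background taxa outside the network
(present in ~3% of photos), which brings the default table to ~84–85% zero
cells and gives the rare-taxon filter something real to do.

What the synthetic data do **not** model: spatial autocorrelation beyond
event-level sharing, overdispersed (e.g. negative binomial) counts,
observation error, taxonomic misassignment, and percent-cover variables.
Passing the recovery tests therefore shows that the pipeline recovers
monotone dependencies from zero-inflated multi-type tables at survey-like
sample sizes — not that it is robust to spatially structured or
overdispersed noise.

## Evaluation scales

The bundled evaluation (`ecobnet.evaluation`, driven by the tests and
`scripts/acceptance.py`) uses 8 taxa + substrate, 8 edges, `lam = 0.8`,
2,000 photos, 100 bootstrap replicates at 20,000 proposals each, and 20
independent seeds — sizes at which a full run takes about a minute on one
CPU while leaving the consensus networks stable from seed to seed. Consensus
F1 against the generating network is ≥0.8 in ≥18 of 20 seeds, influence-score
signs are recovered in ≥95 of 100 runs, and chain propagation matches exact
enumeration to 1e−10.

## Known limitations

* Greedy search finds local optima; the restart scheme makes misses rare at
  these problem sizes but offers no guarantee.
* BDeu with `ess = 1` is a convention; edge counts are mildly sensitive to
  the equivalent sample size.
* Directionality from observational bootstrap frequencies reflects
  score-equivalence asymmetries, not causal identification; mutual edges are
  honest about this.
* Chain inference is exact only on singly connected structures and ignores
  alternative paths between a source and a target.
* The mixture threshold assumes the occurrence distribution is at most
  bimodal; exotic multimodal distributions fall back to the 2-component fit.
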
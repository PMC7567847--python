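# ecobnet

Bayesian network inference for zero-inflated ecological abundance surveys.

Benthic photographic surveys produce sample × taxon count matrices that are
dominated by zeros, mix count, continuous and categorical variables, and hide
both environmental forcing and taxon–taxon dependence. `ecobnet` learns the
dependency structure of such a community as a discrete Bayesian network and
then uses it to predict how the community shifts when a key node — a
habitat-forming taxon, or the substrate type — is forced into a different
state.

## The method

1. **Discretization.** Counts become three states — zero, low, high — with
   zero kept as its own state (one individual is ecologically different from
   none) and the low/high boundary at the median of the *positive* counts.
   Continuous variables (depth, percent encrusting) get four quartile states,
   categorical variables (substrate, region) a stable label map. Photo-scale
   tables can be aggregated to transect events (counts summed, continuous
   averaged, categoricals by mode).
2. **Pre-filtering.** Taxa present in under a third of samples are removed;
   every remaining variable pair is chi-squared-tested against independence
   and pairs with p > 0.25 are barred as edges, so that co-zero artifacts
   never enter the search.
3. **Structure search.** Networks are scored by the log BDeu marginal
   likelihood (uniform priors, equivalent sample size 1) and searched by
   greedy hill climbing over single-edge add/delete/reverse moves with random
   restarts, a parent cap of 3, and the exclusion constraints.
4. **Bootstrap consensus.** The search is repeated on 100 random 95%
   subsamples. Per-pair occurrence frequencies are fit with 1- and
   2-component Gaussian mixtures (BIC-selected); when bimodal, the edge
   cutoff is the density crossing between the modes. Edge direction is the
   majority bootstrap orientation; 40–60% splits are recorded as mutual
   dependencies.
5. **Influence scores.** Each dependency gets a signed strength in [-1, 1]
   from cumulative-distribution dominance of the child's states across parent
   states: +1 for a strictly monotone positive (aggregation), -1 for monotone
   negative (segregation), 0 for independence or non-monotone dependence.
6. **Chain inference.** Forcing a source node into a state propagates along
   the chain of dependencies to every connected node, stepping through
   conditional tables and inverting by Bayes' rule where the chain runs
   against an edge: P(parent|child) = P(child|parent)P(parent) / Σₘ
   P(child|parentₘ)P(parentₘ). Reports tabulate Δp per state per taxon.

A synthetic-community generator with a known ground-truth network (monotone
conditional tables, transect-event structure, ~85% raw zero inflation) makes
every stage testable end to end.

## Worked example

```python
import warnings
from ecobnet import (simulate_ground_truth, sample_community, exclude_rare,
                     discretize_table, contingency_exclusions, SearchSettings,
                     run_bootstrap, ensemble_edge_is, edge_stats,
                     occurrence_threshold, assemble_consensus, recovery_metrics,
                     consensus_dag, fit_cpts, state_change_report)

gt = simulate_ground_truth(n_taxa=8, n_edges=8, lam=0.8, seed=7)
table = sample_community(gt, n_photos=2000, photos_per_event=25, seed=8)

kept, rare = exclude_rare(table)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    dtable = discretize_table(table, keep=kept)
constraint = rare.merged_with(contingency_exclusions(dtable))

settings = SearchSettings(n_iterations=20_000, n_restarts=10, seed=9)
ensemble = run_bootstrap(dtable, constraint, settings, B=100, frac=0.95, seed=10)
is_values = ensemble_edge_is(ensemble, dtable)
stats = edge_stats(ensemble, is_values)
threshold = occurrence_threshold([s.occurrence for s in stats])
network = assemble_consensus(ensemble, threshold, is_values,
                             nodes=dtable.variable_names)
m = recovery_metrics(network, gt)

cpts = fit_cpts(dtable, consensus_dag(network))
report = state_change_report(network, cpts, "Taxon01", 2, 0)
tgt = report.targets["Taxon05"]

print(f"kept {len(kept)} of {len(table.specs)} variables; "
      f"{len(constraint.excluded_pairs)} pairs barred by the chi-squared filter")
print(f"occurrence threshold {threshold:.2%}; {network.n_edges} consensus edges")
print(f"recovery vs ground truth: precision {m.edge_precision:.2f}, "
      f"recall {m.edge_recall:.2f}, F1 {m.f1:.2f}")
print(f"forcing Taxon01 High -> Zero: mean |delta p| {report.mean_delta_p:.4f}")
print("Taxon05 state probabilities:",
      tgt["p_from"].round(3), "->", tgt["p_to"].round(3))
```

prints:

```
kept 10 of 37 variables; 10 pairs barred by the chi-squared filter
occurrence threshold 39.69%; 9 consensus edges
recovery vs ground truth: precision 0.89, recall 1.00, F1 0.94
forcing Taxon01 High -> Zero: mean |delta p| 0.3572
Taxon05 state probabilities: [0.189 0.095 0.716] -> [0.679 0.173 0.147]
```

The 27 rare background taxa (and none of the network taxa) fall to the
occupancy filter; the mixture model splits the bimodal occurrence
distribution; the consensus network recovers all 8 true dependencies plus one
spurious edge; and removing `Taxon01` (forcing it from High to Zero) collapses
its dependent `Taxon05` from a mostly-high to a mostly-zero abundance state,
with the effect attenuating along longer chains.

The same pipeline runs from a shell via the `ecobnet` command
(`simulate`, `discretize`, `prefilter`, `learn`, `consensus`, `infer`, or
`run` for all stages) driven by a YAML config; see
`ecobnet run --help`.

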
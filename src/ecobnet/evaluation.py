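"""End-to-end evaluation runs on synthetic study conditions.

These routines drive the whole pipeline — simulate, discretize, pre-filter,
bootstrap, consensus, influence, inference — on generated communities and
measure how well the known ground truth is recovered.  They are shared by the
test suite and the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import (
    bootstrap_consensus as bc,
    discretize as dz,
    influence as infl,
    prefilter as pf,
    structure_search as ss,
    synthetic_data as syn,
)

__all__ = ["learn_consensus", "recovery_run", "independence_exclusion_rate"]


def learn_consensus(
    dtable,
    constraint,
    seed: int,
    n_iterations: int = 20_000,
    n_restarts: int = 10,
    B: int = 100,
    frac: float = 0.95,
):
    """Bootstrap + threshold + influence scores on a discretized table."""
    settings = ss.SearchSettings(
        n_iterations=n_iterations, n_restarts=n_restarts, seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ensemble = bc.run_bootstrap(dtable, constraint, settings,
                                    B=B, frac=frac, seed=seed + 1)
    is_values = infl.ensemble_edge_is(ensemble, dtable)
    stats = bc.edge_stats(ensemble, is_values)
    try:
        threshold = bc.occurrence_threshold([s.occurrence for s in stats])
    except ValueError:
        threshold = 0.5
    network = bc.assemble_consensus(ensemble, threshold, is_values,
                                    nodes=dtable.variable_names)
    return network, ensemble, threshold


def recovery_run(
    seed: int,
    n_taxa: int = 8,
    n_edges: int = 8,
    lam: float = 0.8,
    n_photos: int = 2000,
    photos_per_event: int = 25,
    n_iterations: int = 20_000,
    n_restarts: int = 10,
    B: int = 100,
):
    """One full simulate-and-recover cycle; returns (metrics, network, gt).

    Seeds for the generator, the community sample and the search are derived
    from ``seed`` by fixed offsets so every stage is reproducible.
    """
    gt = syn.simulate_ground_truth(n_taxa=n_taxa, n_edges=n_edges, lam=lam,
                                   seed=seed)
    table = syn.sample_community(gt, n_photos=n_photos,
                                 photos_per_event=photos_per_event,
                                 seed=seed + 10_000)
    kept, rare = pf.exclude_rare(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dtable = dz.discretize_table(table, keep=kept)
    constraint = rare.merged_with(pf.contingency_exclusions(dtable))
    network, _, threshold = learn_consensus(
        dtable, constraint, seed=seed + 20_000,
        n_iterations=n_iterations, n_restarts=n_restarts, B=B,
    )
    metrics = syn.recovery_metrics(network, gt)
    return metrics, network, gt, dtable, threshold


def independence_exclusion_rate(seed: int, n_pairs: int = 1000,
                                n_samples: int = 200) -> float:
    """Fraction of independent uniform 3-state pairs barred by the p > 0.25
    contingency filter (expected 0.75 under the null)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    excluded = 0
    for _ in range(n_pairs):
        df = pd.DataFrame({
            "A": rng.integers(0, 3, n_samples),
            "B": rng.integers(0, 3, n_samples),
        })
        dt = dz.DiscretizedTable(
            states=df, arity={"A": 3, "B": 3},
            boundaries={"A": 0.0, "B": 0.0},
            rules={"A": "zero_low_high", "B": "zero_low_high"},
        )
        excluded += pf.contingency_exclusions(dt).blocks("A", "B")
    return excluded / n_pairs
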
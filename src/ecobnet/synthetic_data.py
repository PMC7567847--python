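"""Synthetic photographic-survey communities from a known ground-truth network.

The generator emulates the structure of a benthic photo survey: photographs
are grouped ~25 to a transect event; a categorical substrate node (Gravel /
Rocky / Silt) and a continuous depth covariate are drawn once per event and
shared by the event's photographs; taxon abundance states are drawn from a
known DAG whose conditional tables are monotone by construction, so every
edge has a known influence-score sign; counts are then emitted from disjoint
per-state ranges (state 0 always emits a zero count), which makes the
zero/low/high discretization of the emitted counts recover the latent states
exactly when the ranges are balanced.

Each taxon CPT row is the mixture ``lam * (monotone point mass) +
(1 - lam) * uniform``, optionally tilted toward the zero state by
``zero_weight`` to control zero-inflation.  Real surveys are dominated by
rare taxa, so by default the sampled table also carries rare "background"
taxa outside the network whose near-total absence brings the raw matrix to
roughly 85% zero entries; they are exactly what the rare-taxon filter is
there to remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .influence import CPT, CPTSet
from .structure_search import DAG
from .tabular_io import AbundanceTable, VariableSpec

__all__ = [
    "GroundTruth",
    "RecoveryMetrics",
    "simulate_ground_truth",
    "sample_community",
    "recovery_metrics",
]

SUBSTRATE = "Substrate"
DEPTH = "Depth"
SUBSTRATE_LEVELS = ("Gravel", "Rocky", "Silt")
SUBSTRATE_PROBS = (0.30, 0.25, 0.45)  # silt-dominated seafloor
DEPTH_RANGE = (450.0, 1050.0)  # metres
LOW_RANGE = (1, 3)  # counts emitted for the "low" state
HIGH_RANGE = (6, 12)  # counts emitted for the "high" state
N_BACKGROUND = 27  # rare taxa outside the network (raw zero fraction ~0.85)
BACKGROUND_PRESENCE = 0.03


@dataclass
class GroundTruth:
    """A known DAG with monotone CPTs and count-emission ranges."""

    dag: DAG
    cpts: CPTSet
    edge_signs: dict[tuple[str, str], int]
    emission: dict[str, dict[str, tuple[int, int]]]
    lam: float
    zero_weight: float
    seed: int

    @property
    def taxa(self) -> list[str]:
        return [n for n in self.dag.nodes if n not in (SUBSTRATE, DEPTH)]

    @property
    def true_edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.dag.edges}

    def export(self, path) -> None:
        payload = {
            "nodes": list(self.dag.nodes),
            "edges": [
                {"source": p, "target": c, "sign": self.edge_signs[(p, c)]}
                for p, c in self.dag.edges
            ],
            "lam": self.lam,
            "zero_weight": self.zero_weight,
            "seed": self.seed,
            "emission": {
                t: {k: list(v) for k, v in r.items()}
                for t, r in self.emission.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class RecoveryMetrics:
    """How well a consensus network recovers the generating DAG."""

    edge_precision: float
    edge_recall: float
    f1: float
    direction_accuracy: float

    def __post_init__(self):
        for v in (self.edge_precision, self.edge_recall, self.f1,
                  self.direction_accuracy):
            if not 0.0 <= v <= 1.0:
                raise ValueError("metrics must lie in [0, 1]")


def _monotone_row(t: float, arity: int, lam: float, zero_weight: float) -> np.ndarray:
    """lam * point mass at round(t * (arity-1)) + (1-lam) * uniform, then a
    zero_weight tilt toward state 0."""
    row = np.full(arity, (1.0 - lam) / arity)
    row[int(round(t * (arity - 1)))] += lam
    row *= 1.0 - zero_weight
    row[0] += zero_weight
    return row


def simulate_ground_truth(
    n_taxa: int = 8,
    n_edges: int = 8,
    lam: float = 0.8,
    seed: int = 0,
    zero_weight: float = 0.1,
    random_signs: bool = False,
    max_parents: int = 3,
) -> GroundTruth:
    """Random ground-truth network over a substrate root and ``n_taxa`` taxa.

    Candidate edges run from substrate to taxa and between taxa along a fixed
    topological order; ``n_edges`` of them are drawn at random under the
    parent cap.  ``lam`` in [0, 1] sets the monotone signal strength: 0 gives
    uniform rows (every true IS is 0), 1 gives deterministic monotone rows
    (IS exactly +-1 when ``zero_weight`` is 0).  Edge signs are positive
    unless ``random_signs``.  Depth is included as an unconnected continuous
    covariate.  Deterministic given ``seed``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    taxa = [f"Taxon{i + 1:02d}" for i in range(n_taxa)]
    order = [SUBSTRATE] + taxa  # topological order; depth stays unconnected
    candidates = [
        (order[i], order[j])
        for i in range(len(order))
        for j in range(max(i + 1, 1), len(order))
        if order[j] != SUBSTRATE
    ]
    rng.shuffle(candidates)
    parents: dict[str, list[str]] = {n: [] for n in order}
    chosen: list[tuple[str, str]] = []
    for p, c in candidates:
        if len(chosen) == n_edges:
            break
        if len(parents[c]) < max_parents:
            parents[c].append(p)
            chosen.append((p, c))
    if len(chosen) < n_edges:
        raise ValueError(
            f"cannot place {n_edges} edges over {n_taxa} taxa under the "
            f"parent cap {max_parents}"
        )
    signs = {
        e: (int(rng.choice([-1, 1])) if random_signs else 1) for e in chosen
    }

    arity = {SUBSTRATE: len(SUBSTRATE_LEVELS)}
    arity.update({t: 3 for t in taxa})
    cpts: dict[str, CPT] = {}
    cpts[SUBSTRATE] = CPT(
        SUBSTRATE, (), arity[SUBSTRATE], (),
        np.array(SUBSTRATE_PROBS, dtype=float)[np.newaxis, :],
    )
    for t in taxa:
        ps = tuple(sorted(parents[t], key=order.index))
        p_ar = tuple(arity[p] for p in ps)
        q = int(np.prod(p_ar)) if ps else 1
        table = np.empty((q, arity[t]))
        for row_idx in range(q):
            if ps:
                config = np.unravel_index(row_idx, p_ar)
                contrib = [
                    s / (a - 1) if signs[(p, t)] > 0 else 1.0 - s / (a - 1)
                    for p, a, s in zip(ps, p_ar, config)
                ]
                t_pos = float(np.mean(contrib))
                table[row_idx] = _monotone_row(t_pos, arity[t], lam, zero_weight)
            else:
                row = np.full(arity[t], 1.0 / arity[t]) * (1.0 - zero_weight)
                row[0] += zero_weight
                table[row_idx] = row
        cpts[t] = CPT(t, ps, arity[t], p_ar, table)

    dag = DAG(
        tuple([SUBSTRATE, DEPTH] + taxa),
        {t: tuple(sorted(parents[t], key=order.index)) for t in order},
        max_parents,
    )
    marginals = _forward_marginals(cpts, [SUBSTRATE] + taxa)
    cptset = CPTSet(cpts=cpts, marginals=marginals)
    emission = {t: {"low": LOW_RANGE, "high": HIGH_RANGE} for t in taxa}
    return GroundTruth(
        dag=dag, cpts=cptset, edge_signs=signs, emission=emission,
        lam=lam, zero_weight=zero_weight, seed=seed,
    )


def _forward_marginals(cpts: dict[str, CPT], order: list[str]) -> dict[str, np.ndarray]:
    """Node marginals by forward propagation assuming independent parents
    (exact for root nodes; an adequate reference elsewhere)."""
    marg: dict[str, np.ndarray] = {}
    for v in order:
        cpt = cpts[v]
        if not cpt.parents:
            marg[v] = cpt.table[0].copy()
            continue
        m = np.zeros(cpt.child_arity)
        p_ar = cpt.parent_arities
        for row_idx in range(cpt.table.shape[0]):
            config = np.unravel_index(row_idx, p_ar)
            w = 1.0
            for p, s in zip(cpt.parents, config):
                w *= marg[p][s]
            m += w * cpt.table[row_idx]
        marg[v] = m / m.sum()
    return marg


def sample_community(
    gt: GroundTruth,
    n_photos: int = 525,
    photos_per_event: int = 25,
    seed: int = 0,
    n_background: int = N_BACKGROUND,
    background_presence: float = BACKGROUND_PRESENCE,
    return_states: bool = False,
) -> AbundanceTable:
    """Sample a photo-scale abundance table from the ground truth.

    Substrate and depth are drawn once per transect event and shared by its
    photographs; taxon states are sampled photo-by-photo from the DAG and
    emitted as counts (state 0 -> 0, state 1 -> low range, state 2 -> high
    range).  ``n_background`` rare taxa outside the network are appended,
    each present (count 1-2) in a ``background_presence`` fraction of photos.
    With ``return_states`` the latent state matrix of the network nodes is
    returned alongside the table.
    """
    if n_photos % photos_per_event:
        raise ValueError("n_photos must be divisible by photos_per_event")
    rng = np.random.default_rng(seed)
    n_events = n_photos // photos_per_event
    taxa = gt.taxa
    order = [SUBSTRATE] + taxa

    sub_states = rng.choice(
        len(SUBSTRATE_LEVELS), size=n_events, p=gt.cpts.cpts[SUBSTRATE].table[0]
    )
    depths = rng.uniform(*DEPTH_RANGE, size=n_events).round(1)

    columns: dict[str, np.ndarray] = {}
    states = np.zeros((n_photos, len(order)), dtype=np.int64)
    idx = {n: i for i, n in enumerate(order)}
    states[:, 0] = np.repeat(sub_states, photos_per_event)
    for t in taxa:
        cpt = gt.cpts.cpts[t]
        if cpt.parents:
            p_cols = states[:, [idx[p] for p in cpt.parents]]
            rows = np.ravel_multi_index(p_cols.T, cpt.parent_arities)
        else:
            rows = np.zeros(n_photos, dtype=np.int64)
        u = rng.random(n_photos)
        cum = np.cumsum(cpt.table, axis=1)
        states[:, idx[t]] = (u[:, np.newaxis] > cum[rows]).sum(axis=1)

    for t in taxa:
        st = states[:, idx[t]]
        lo, hi = gt.emission[t]["low"], gt.emission[t]["high"]
        counts = np.zeros(n_photos, dtype=np.int64)
        counts[st == 1] = rng.integers(lo[0], lo[1] + 1, size=int((st == 1).sum()))
        counts[st == 2] = rng.integers(hi[0], hi[1] + 1, size=int((st == 2).sum()))
        columns[t] = counts

    levels = np.array(SUBSTRATE_LEVELS)
    columns[SUBSTRATE] = levels[np.repeat(sub_states, photos_per_event)]
    columns[DEPTH] = np.repeat(depths, photos_per_event)

    bg_names = [f"Rare{i + 1:02d}" for i in range(n_background)]
    for b in bg_names:
        present = rng.random(n_photos) < background_presence
        counts = np.zeros(n_photos, dtype=np.int64)
        counts[present] = rng.integers(1, 3, size=int(present.sum()))
        columns[b] = counts

    specs = (
        [VariableSpec(t, "taxon") for t in taxa]
        + [VariableSpec(b, "taxon") for b in bg_names]
        + [VariableSpec(SUBSTRATE, "categorical"),
           VariableSpec(DEPTH, "continuous")]
    )
    events = np.repeat([f"E{e + 1:02d}" for e in range(n_events)], photos_per_event)
    data = pd.DataFrame(columns, index=pd.RangeIndex(n_photos))
    grouping = pd.Series(events, index=data.index)
    table = AbundanceTable(data=data, specs=tuple(specs), grouping=grouping,
                           scale="photo")
    if return_states:
        latent = pd.DataFrame(states, index=data.index, columns=order)
        return table, latent
    return table


def recovery_metrics(consensus, gt: GroundTruth) -> RecoveryMetrics:
    """Precision/recall/F1 over undirected true edges, plus the fraction of
    recovered edges whose orientation matches the truth (mutual edges count
    as correctly directed either way)."""
    if set(consensus.nodes) != set(gt.dag.nodes):
        raise ValueError("consensus and ground truth cover different nodes")
    truth = gt.true_edges
    directed_truth = set(gt.dag.edges)
    predicted = {frozenset((e.source, e.target)) for e in consensus.edges}
    tp = len(truth & predicted)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0 else 0.0
    )
    recovered = [
        e for e in consensus.edges if frozenset((e.source, e.target)) in truth
    ]
    if recovered:
        ok = 0
        for e in recovered:
            if e.direction == "mutual":
                ok += 1
            elif e.direction == "forward":
                ok += (e.source, e.target) in directed_truth
            else:
                ok += (e.target, e.source) in directed_truth
        direction_accuracy = ok / len(recovered)
    else:
        direction_accuracy = 1.0
    return RecoveryMetrics(precision, recall, f1, direction_accuracy)
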
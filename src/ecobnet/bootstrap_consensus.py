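"""Bootstrap consensus networks with mixture-model occurrence thresholding.

Structure search on a single data set is sensitive to outliers, so the
network is learned on repeated 95% subsamples (drawn without replacement) and
only connections that recur across subsample networks are kept.  The cutoff
is not fixed a priori: the distribution of per-pair occurrence frequencies is
fit with 1- and 2-component Gaussian mixtures (EM, BIC selection), and when
it is bimodal — a low-occurrence noise mode and a high-occurrence signal
mode — the threshold is placed at the density crossing between the two
component means.  Edge direction is the majority orientation across
replicates; with no clear majority (orientation frequency between 0.4 and
0.6) the dependency is recorded as mutual.  Edge strength is the mean
influence score over the replicates containing the edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import networkx as nx
import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .discretize import DiscretizedTable
from .prefilter import ExclusionSet
from .structure_search import DAG, SearchSettings, greedy_search

__all__ = [
    "BootstrapEnsemble",
    "EdgeStats",
    "ConsensusEdge",
    "ConsensusNetwork",
    "run_bootstrap",
    "occurrence_threshold",
    "edge_stats",
    "assemble_consensus",
    "consensus_dag",
    "chain_statistics",
]

MUTUAL_LOW, MUTUAL_HIGH = 0.4, 0.6


@dataclass
class BootstrapEnsemble:
    """Per-replicate subsample index lists and learned DAGs."""

    B: int
    frac: float
    subsample_indices: list[list[int]]
    dags: list[DAG]
    seed: int

    def __post_init__(self):
        if len(self.dags) != self.B or len(self.subsample_indices) != self.B:
            raise ValueError("ensemble must hold exactly B replicates")


@dataclass
class EdgeStats:
    """Bootstrap statistics of one unordered variable pair."""

    pair: frozenset
    occurrence: float
    forward_fraction: float  # fraction oriented min(pair) -> max(pair), among hits
    is_values: list[float] = field(default_factory=list)


@dataclass
class ConsensusEdge:
    source: str
    target: str
    direction: str  # forward / backward / mutual, relative to source -> target
    occurrence: float
    mean_is: float


@dataclass
class ConsensusNetwork:
    """Thresholded consensus edges plus whole-network summary statistics."""

    nodes: list[str]
    edges: list[ConsensusEdge]
    threshold: Optional[float] = None
    summary: Optional[dict] = None

    def __post_init__(self):
        if self.threshold is not None:
            low = [e for e in self.edges if e.occurrence < self.threshold - 1e-12]
            if low:
                raise ValueError("edge below the occurrence threshold")
        for e in self.edges:
            if not -1.0 - 1e-9 <= e.mean_is <= 1.0 + 1e-9:
                raise ValueError(f"mean IS outside [-1, 1]: {e.mean_is}")
        if self.summary is None:
            self.summary = summarize(self.nodes, self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target)
        return g


def run_bootstrap(
    dtable: DiscretizedTable,
    constraint: Optional[ExclusionSet] = None,
    settings: Optional[SearchSettings] = None,
    B: int = 100,
    frac: float = 0.95,
    seed: int = 0,
) -> BootstrapEnsemble:
    """Learn one DAG per random subsample.

    Each replicate draws floor(frac * n) distinct samples without replacement
    and runs the greedy search with a replicate-specific derived seed; the
    whole ensemble is reproducible from ``seed``.
    """
    settings = settings or SearchSettings()
    n = dtable.n_samples
    m = int(np.floor(frac * n))
    if m < 10:
        raise ValueError(f"subsample size {m} < 10; too few samples to bootstrap")
    if n < 20:
        warnings.warn(f"bootstrapping only {n} samples; expect unstable networks")
    rng = np.random.default_rng(seed)
    indices, dags = [], []
    for _b in range(B):
        idx = np.sort(rng.choice(n, size=m, replace=False)).tolist()
        rep_seed = int(rng.integers(0, 2**31 - 1))
        sub = DiscretizedTable(
            states=dtable.states.iloc[idx],
            arity=dtable.arity,
            boundaries=dtable.boundaries,
            rules=dtable.rules,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dags.append(
                greedy_search(sub, constraint, replace(settings, seed=rep_seed))
            )
        indices.append(idx)
    return BootstrapEnsemble(B=B, frac=frac, subsample_indices=indices,
                             dags=dags, seed=seed)


def edge_stats(ensemble: BootstrapEnsemble,
               is_values: Optional[dict] = None) -> list[EdgeStats]:
    """Occurrence and orientation frequencies for every pair seen in any DAG.

    ``forward_fraction`` is measured among the replicates containing the
    edge, oriented from the lexicographically smaller to the larger name.
    Frequencies are invariant to replicate order.
    """
    hits: dict[frozenset, int] = {}
    fwd: dict[frozenset, int] = {}
    for dag in ensemble.dags:
        for p, c in dag.edges:
            pair = frozenset((p, c))
            hits[pair] = hits.get(pair, 0) + 1
            if p == min(pair):
                fwd[pair] = fwd.get(pair, 0) + 1
    stats = []
    for pair in sorted(hits, key=sorted):
        stats.append(
            EdgeStats(
                pair=pair,
                occurrence=hits[pair] / ensemble.B,
                forward_fraction=fwd.get(pair, 0) / hits[pair],
                is_values=list((is_values or {}).get(pair, [])),
            )
        )
    return stats


def occurrence_threshold(occurrences, max_iter: int = 500) -> float:
    """Occurrence cutoff from a 1- vs 2-component Gaussian mixture fit.

    If BIC prefers two components, the threshold is the crossing point of the
    two weighted component densities between their means (midpoint of the
    means if the densities do not cross there); otherwise 0.5, i.e. simple
    majority.  EM non-convergence also falls back to 0.5 with a warning.
    """
    x = np.asarray(list(occurrences), dtype=float).reshape(-1, 1)
    if x.size < 2:
        raise ValueError("need at least 2 occurrence frequencies")
    if np.unique(x).size < 2:
        return 0.5  # degenerate: a single mode, simple majority
    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(
            n_components=k, max_iter=max_iter, n_init=5, random_state=0,
            reg_covar=1e-6,
        )
        gm.fit(x)
        if not gm.converged_:
            warnings.warn("mixture EM did not converge; falling back to 0.5")
            return 0.5
        fits[k] = gm
    if fits[1].bic(x) <= fits[2].bic(x):
        return 0.5
    gm = fits[2]
    (m1, m2) = sorted(gm.means_.ravel())
    order = np.argsort(gm.means_.ravel())
    w = gm.weights_.ravel()[order]
    s = np.sqrt(gm.covariances_.ravel()[order])

    def diff(t):
        return w[0] * norm.pdf(t, m1, s[0]) - w[1] * norm.pdf(t, m2, s[1])

    if np.sign(diff(m1)) == np.sign(diff(m2)) or m2 - m1 < 1e-12:
        return float((m1 + m2) / 2)
    return float(brentq(diff, m1, m2))


def assemble_consensus(
    ensemble: BootstrapEnsemble,
    threshold: float,
    is_values: Optional[dict] = None,
    nodes: Optional[list[str]] = None,
) -> ConsensusNetwork:
    """Keep pairs at or above the occurrence threshold and orient them.

    Direction is forward (min -> max name) when the forward orientation holds
    in at least 60% of the containing replicates, backward when at most 40%,
    and mutual in between.  ``is_values`` (pair -> per-replicate IS list, as
    produced by :func:`ecobnet.influence.ensemble_edge_is`) supplies the mean
    influence scores.
    """
    if nodes is None:
        nodes = list(ensemble.dags[0].nodes) if ensemble.dags else []
    edges = []
    for st in edge_stats(ensemble, is_values):
        if st.occurrence < threshold:
            continue
        a, b = sorted(st.pair)
        if st.forward_fraction >= MUTUAL_HIGH:
            direction = "forward"
        elif st.forward_fraction <= MUTUAL_LOW:
            direction = "backward"
        else:
            direction = "mutual"
        mean_is = float(np.mean(st.is_values)) if st.is_values else 0.0
        edges.append(ConsensusEdge(a, b, direction, st.occurrence, mean_is))
    return ConsensusNetwork(nodes=nodes, edges=edges, threshold=threshold)


def consensus_dag(network: ConsensusNetwork, max_parents: int = 3) -> DAG:
    """A DAG consistent with the consensus edges, for CPT fitting.

    Forward/backward edges keep their majority orientation; mutual edges are
    oriented source -> target unless that breaks acyclicity or the parent
    cap, in which case the reverse is tried and, failing that, the edge is
    dropped with a warning.  Edges are processed in sorted order so the
    result is deterministic.
    """
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)

    def can_add(u, v):
        if g.in_degree(v) >= max_parents:
            return False
        return not nx.has_path(g, v, u)

    directed = []
    mutual = []
    for e in sorted(network.edges, key=lambda e: (e.source, e.target)):
        if e.direction == "forward":
            directed.append((e.source, e.target))
        elif e.direction == "backward":
            directed.append((e.target, e.source))
        else:
            mutual.append((e.source, e.target))
    for u, v in directed:
        if can_add(u, v):
            g.add_edge(u, v)
        elif can_add(v, u):
            warnings.warn(f"flipping consensus edge {u}->{v} to keep a valid DAG")
            g.add_edge(v, u)
        else:
            warnings.warn(f"dropping consensus edge {u}->{v}: no valid orientation")
    for u, v in mutual:
        if can_add(u, v):
            g.add_edge(u, v)
        elif can_add(v, u):
            g.add_edge(v, u)
        else:
            warnings.warn(f"dropping mutual edge {u}--{v}: no valid orientation")
    parents = {v: tuple(sorted(g.predecessors(v))) for v in network.nodes}
    return DAG(tuple(network.nodes), parents, max_parents)


# ---------------------------------------------------------------------------
# Network summary statistics
# ---------------------------------------------------------------------------


def chain_statistics(graph: nx.Graph) -> dict:
    """Chains of the (undirected) consensus graph.

    A chain is a maximal simple path of at least 2 edges — a path that cannot
    be extended at either end — counted once per distinct endpoint pair, with
    the longest such path setting the pair's chain length (in edges).
    """
    best: dict[frozenset, int] = {}
    nodes = sorted(graph.nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            for path in nx.all_simple_paths(graph, u, v):
                if len(path) < 3:
                    continue
                on_path = set(path)
                if set(graph[path[0]]) <= on_path and set(graph[path[-1]]) <= on_path:
                    pair = frozenset((u, v))
                    best[pair] = max(best.get(pair, 0), len(path) - 1)
    lengths = sorted(best.values())
    return {
        "n_chains": len(lengths),
        "max_chain_length": max(lengths) if lengths else 0,
        "mean_chain_length": float(np.mean(lengths)) if lengths else 0.0,
    }


def summarize(nodes: list[str], edges: list[ConsensusEdge]) -> dict:
    """Whole-network summary: connected-node count, signed dependency counts,
    connectance (edges / nodes(nodes-1) over connected nodes), link density
    (edges per connected node) and chain statistics."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        g.add_edge(e.source, e.target)
    connected = [n for n in g.nodes if g.degree(n) > 0]
    k = len(connected)
    n_e = len(edges)
    mean_is = float(np.mean([e.mean_is for e in edges])) if edges else 0.0
    return {
        "n_nodes_analysed": len(nodes),
        "n_nodes_connected": k,
        "n_edges": n_e,
        "mean_is": mean_is,
        "n_positive": sum(1 for e in edges if e.mean_is > 0),
        "n_negative": sum(1 for e in edges if e.mean_is < 0),
        "n_mutual": sum(1 for e in edges if e.direction == "mutual"),
        "connectance": n_e / (k * (k - 1)) if k > 1 else 0.0,
        "link_density": n_e / k if k else 0.0,
        **chain_statistics(g.subgraph(connected)),
    }
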
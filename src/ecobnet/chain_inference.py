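"""State-change inference propagated along dependency chains.

Forcing one node of the consensus network into a given state shifts the
state probabilities of every node connected to it.  The shift is computed
along the chain of dependencies linking the two nodes: each step applies the
conditional distribution of the next node given the current one.  For a step
that runs *along* a fitted edge (parent to child) that conditional is the
child's CPT row with any other parents marginalized out by their empirical
state frequencies; for a step *against* an edge (child to parent) the
conditional is obtained by Bayes inversion,

    P(parent = m | child = c) =
        P(child = c | parent = m) P(parent = m)
        / sum_m' P(child = c | parent = m') P(parent = m'),

which is always defined because CPTs are add-alpha smoothed.  A report
contrasts two forced source states (e.g. sponge abundance High vs Zero) and
tabulates the per-state probability change delta_p for every connected node.

A brute-force exact-enumeration conditional (:func:`exact_conditional`) is
included as an independent reference; on singly connected networks the chain
propagation reproduces it to numerical precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np

from .bootstrap_consensus import ConsensusNetwork
from .influence import CPTSet

__all__ = [
    "NoChainError",
    "DependencyChain",
    "InferenceReport",
    "find_chain",
    "propagate",
    "state_change_report",
    "substrate_contrast",
    "exact_joint",
    "exact_conditional",
]


class NoChainError(ValueError):
    """The two nodes are not connected in the consensus network."""


@dataclass
class DependencyChain:
    """An ordered node path with the orientation of each step.

    ``step_orientation[k]`` is "along" when the fitted DAG edge points
    nodes[k] -> nodes[k+1], "against" when it points the other way.
    """

    nodes: list[str]
    step_orientation: list[str]
    arities: list[int]

    def __post_init__(self):
        if len(self.nodes) < 2:
            raise ValueError("a chain needs at least 2 nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("chain revisits a node")
        if len(self.step_orientation) != len(self.nodes) - 1:
            raise ValueError("need one orientation per consecutive pair")

    @property
    def length(self) -> int:
        """Number of dependency steps (edges)."""
        return len(self.nodes) - 1


def _adjacency(network: ConsensusNetwork) -> dict[str, list[str]]:
    adj: dict[str, list[str]] = {n: [] for n in network.nodes}
    for e in network.edges:
        adj[e.source].append(e.target)
        adj[e.target].append(e.source)
    return {n: sorted(set(vs)) for n, vs in adj.items()}


def find_chain(
    network: ConsensusNetwork, source: str, target: str, cpts: CPTSet
) -> DependencyChain:
    """Shortest undirected path from source to target.

    Ties between equally short paths are broken by the lexicographically
    smallest node sequence, so the chain is deterministic.  Step orientations
    are read off the fitted structure in ``cpts``.
    """
    for n in (source, target):
        if n not in network.nodes:
            raise KeyError(f"{n!r} not in network")
    adj = _adjacency(network)
    # BFS distances to the target, then greedy lexicographic descent
    dist = {target: 0}
    frontier = [target]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    if source not in dist:
        raise NoChainError(f"no chain between {source!r} and {target!r}")
    path = [source]
    cur = source
    while cur != target:
        cur = min(v for v in adj[cur] if dist.get(v, np.inf) == dist[cur] - 1)
        path.append(cur)
    orientation = []
    for u, v in zip(path, path[1:]):
        if u in cpts.cpts[v].parents:
            orientation.append("along")
        elif v in cpts.cpts[u].parents:
            orientation.append("against")
        else:
            raise ValueError(f"no fitted edge between {u!r} and {v!r}")
    return DependencyChain(
        nodes=path,
        step_orientation=orientation,
        arities=[cpts.arity(n) for n in path],
    )


def _marginalized_conditional(cpts: CPTSet, parent: str, child: str) -> np.ndarray:
    """P(child | parent) with the child's other parents marginalized by their
    empirical state frequencies; shape (parent arity, child arity)."""
    cpt = cpts.cpts[child]
    axis = cpt.parents.index(parent)
    r_p = cpt.parent_arities[axis]
    others = [k for k in range(len(cpt.parents)) if k != axis]
    out = np.zeros((r_p, cpt.child_arity))
    for config in product(*(range(cpt.parent_arities[k]) for k in others)):
        w = 1.0
        for k, s in zip(others, config):
            w *= cpts.marginals[cpt.parents[k]][s]
        for p_state in range(r_p):
            full = [0] * len(cpt.parents)
            full[axis] = p_state
            for k, s in zip(others, config):
                full[k] = s
            out[p_state] += w * cpt.row(tuple(full))
    return out / out.sum(axis=1, keepdims=True)


def _step_matrix(cpts: CPTSet, u: str, v: str, orientation: str) -> np.ndarray:
    """Transition matrix M[s_u, s_v] = P(v = s_v | u = s_u) for one step."""
    if orientation == "along":
        return _marginalized_conditional(cpts, u, v)
    like = _marginalized_conditional(cpts, v, u)  # P(u | v), (s_v, s_u)
    prior = cpts.marginals[v]
    post = like.T * prior[np.newaxis, :]  # (s_u, s_v)
    return post / post.sum(axis=1, keepdims=True)


def propagate(
    chain: DependencyChain, cpts: CPTSet, source_state: int
) -> np.ndarray:
    """Distribution over the chain's last node given a forced source state."""
    if not 0 <= source_state < chain.arities[0]:
        raise ValueError(f"source state {source_state} out of range")
    dist = np.zeros(chain.arities[0])
    dist[source_state] = 1.0
    for u, v, orientation in zip(chain.nodes, chain.nodes[1:],
                                 chain.step_orientation):
        dist = dist @ _step_matrix(cpts, u, v, orientation)
    return dist


@dataclass
class InferenceReport:
    """Per-node probability shifts under a forced source-state contrast."""

    source: str
    from_state: int
    to_state: int
    targets: dict  # name -> {p_from, p_to, delta_p, chain}
    mean_delta_p: float

    def __post_init__(self):
        for name, t in self.targets.items():
            for key in ("p_from", "p_to"):
                vec = np.asarray(t[key], dtype=float)
                if abs(vec.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{name}: {key} does not sum to 1")
            if abs(np.sum(t["delta_p"])) > 1e-9:
                raise ValueError(f"{name}: delta_p must sum to 0")

    def export_json(self, path) -> None:
        payload = {
            "source": self.source,
            "from_state": self.from_state,
            "to_state": self.to_state,
            "mean_delta_p": self.mean_delta_p,
            "targets": {
                name: {
                    "p_from": list(map(float, t["p_from"])),
                    "p_to": list(map(float, t["p_to"])),
                    "delta_p": list(map(float, t["delta_p"])),
                    "chain": t["chain"],
                }
                for name, t in self.targets.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def export_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("target\tstate\tp_from\tp_to\tdelta_p\n")
            for name in sorted(self.targets):
                t = self.targets[name]
                for s, (a, b, d) in enumerate(
                    zip(t["p_from"], t["p_to"], t["delta_p"])
                ):
                    fh.write(f"{name}\t{s}\t{a:.6f}\t{b:.6f}\t{d:.6f}\n")


def state_change_report(
    network: ConsensusNetwork,
    cpts: CPTSet,
    source: str,
    from_state: int,
    to_state: int,
) -> InferenceReport:
    """Contrast two forced states of ``source`` for every other node.

    Connected nodes get Δp(state) = P(state | source = to_state) −
    P(state | source = from_state) along their chain; unconnected nodes are
    reported with Δp = 0 and do not enter ``mean_delta_p``, which averages
    |Δp| over every state of every connected node.
    """
    if source not in network.nodes:
        raise KeyError(f"{source!r} not in network")
    targets = {}
    abs_deltas = []
    for node in network.nodes:
        if node == source:
            continue
        try:
            chain = find_chain(network, source, node, cpts)
        except NoChainError:
            r = cpts.arity(node)
            m = cpts.marginals[node]
            targets[node] = {
                "p_from": m.copy(), "p_to": m.copy(),
                "delta_p": np.zeros(r), "chain": None,
            }
            continue
        p_from = propagate(chain, cpts, from_state)
        p_to = propagate(chain, cpts, to_state)
        delta = p_to - p_from
        targets[node] = {
            "p_from": p_from, "p_to": p_to, "delta_p": delta,
            "chain": list(chain.nodes),
        }
        abs_deltas.extend(np.abs(delta))
    mean_dp = float(np.mean(abs_deltas)) if abs_deltas else 0.0
    return InferenceReport(source, from_state, to_state, targets, mean_dp)


def substrate_contrast(
    network: ConsensusNetwork,
    cpts: CPTSet,
    substrate_var: str,
    state_a,
    state_b,
    category_map: Optional[dict] = None,
) -> float:
    """Mean |Δp| when the substrate node switches between two categories.

    States may be integers or category labels (with ``category_map`` as
    recorded by the discretizer); an unknown label is a usage error.
    """

    def resolve(s):
        if isinstance(s, (int, np.integer)):
            if not 0 <= int(s) < cpts.arity(substrate_var):
                raise ValueError(f"state {s} out of range for {substrate_var!r}")
            return int(s)
        if category_map is None or s not in category_map:
            raise ValueError(f"unknown state label {s!r} for {substrate_var!r}")
        return int(category_map[s])

    report = state_change_report(
        network, cpts, substrate_var, resolve(state_a), resolve(state_b)
    )
    return report.mean_delta_p


# ---------------------------------------------------------------------------
# Brute-force reference (exact enumeration)
# ---------------------------------------------------------------------------


def exact_joint(cpts: CPTSet) -> tuple[list[str], np.ndarray]:
    """Full joint distribution by enumeration of every state combination.

    Exponential in the node count — a reference for small networks, not the
    inference path.
    """
    nodes = cpts.nodes
    arities = [cpts.arity(n) for n in nodes]
    index = {n: i for i, n in enumerate(nodes)}
    joint = np.zeros(arities)
    for combo in product(*(range(a) for a in arities)):
        p = 1.0
        for n in nodes:
            cpt = cpts.cpts[n]
            parent_states = tuple(combo[index[q]] for q in cpt.parents)
            p *= cpt.row(parent_states)[combo[index[n]]]
        joint[combo] = p
    return nodes, joint


def exact_conditional(
    cpts: CPTSet, source: str, source_state: int, target: str
) -> np.ndarray:
    """P(target | source = source_state) from the enumerated joint."""
    nodes, joint = exact_joint(cpts)
    si, ti = nodes.index(source), nodes.index(target)
    sl = [slice(None)] * len(nodes)
    sl[si] = source_state
    sub = joint[tuple(sl)]
    axes = tuple(
        k for k in range(sub.ndim) if k != (ti if ti < si else ti - 1)
    )
    marg = sub.sum(axis=axes)
    return marg / marg.sum()
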
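"""Conditional probability tables and the signed influence score.

The influence score (IS) of an edge parent -> child summarizes in [-1, 1]
whether higher parent states shift the child's distribution toward higher
states.  For every configuration of the child's *other* parents and every
ordered pair of parent states p < p', the child CDFs F(.|p) and F(.|p') are
compared: a vote of +1 if F(.|p') lies at or below F(.|p) everywhere and
strictly below somewhere (stochastic dominance toward higher states), -1 for
the reverse dominance, and 0 if the CDFs cross.  Votes are weighted by the
probability of the other-parent configuration (product of the parents'
empirical marginals) and averaged.  +1 thus marks a strictly monotone
positive dependency (aggregation), -1 a monotone negative one (segregation),
and 0 either independence or a non-monotonic relationship.

CPTs are fit by add-alpha (default 1) smoothing so every entry is strictly
positive, which keeps the Bayes inversion used downstream well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product

import numpy as np

from .discretize import DiscretizedTable
from .structure_search import DAG

__all__ = ["CPT", "CPTSet", "fit_cpts", "influence_score", "ensemble_edge_is"]


@dataclass
class CPT:
    """Conditional distribution of one child given its ordered parents.

    ``table`` has one row per parent-state configuration (row index is the
    C-order ravel of the parent states, last parent fastest) and one column
    per child state; every row sums to 1.
    """

    child: str
    parents: tuple[str, ...]
    child_arity: int
    parent_arities: tuple[int, ...]
    table: np.ndarray
    alpha: float = 1.0

    def __post_init__(self):
        self.parents = tuple(self.parents)
        self.parent_arities = tuple(int(a) for a in self.parent_arities)
        self.table = np.asarray(self.table, dtype=float)
        q = int(np.prod(self.parent_arities)) if self.parents else 1
        if self.table.shape != (q, self.child_arity):
            raise ValueError(
                f"CPT for {self.child!r}: table shape {self.table.shape} != "
                f"({q}, {self.child_arity})"
            )
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"CPT for {self.child!r}: rows must sum to 1")

    def row(self, parent_states: tuple[int, ...]) -> np.ndarray:
        idx = int(np.ravel_multi_index(parent_states, self.parent_arities)) \
            if self.parents else 0
        return self.table[idx]


@dataclass
class CPTSet:
    """One CPT per node of a DAG plus per-node marginal state distributions."""

    cpts: dict[str, CPT]
    marginals: dict[str, np.ndarray]

    def __post_init__(self):
        for name, m in self.marginals.items():
            m = np.asarray(m, dtype=float)
            if not np.isclose(m.sum(), 1.0, atol=1e-9):
                raise ValueError(f"marginal of {name!r} does not sum to 1")
            self.marginals[name] = m
        missing = set(self.marginals) ^ set(self.cpts)
        if missing:
            raise ValueError(f"CPT/marginal mismatch for: {sorted(missing)}")

    @property
    def nodes(self) -> list[str]:
        return list(self.cpts)

    def arity(self, name: str) -> int:
        return self.cpts[name].child_arity

    def export(self, path) -> None:
        payload = {
            name: {
                "parents": list(c.parents),
                "child_arity": c.child_arity,
                "parent_arities": list(c.parent_arities),
                "table": c.table.tolist(),
                "alpha": c.alpha,
                "marginal": self.marginals[name].tolist(),
            }
            for name, c in self.cpts.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "CPTSet":
        with open(path) as fh:
            payload = json.load(fh)
        cpts, marginals = {}, {}
        for name, d in payload.items():
            cpts[name] = CPT(
                child=name,
                parents=tuple(d["parents"]),
                child_arity=d["child_arity"],
                parent_arities=tuple(d["parent_arities"]),
                table=np.array(d["table"], dtype=float),
                alpha=d.get("alpha", 1.0),
            )
            marginals[name] = np.array(d["marginal"], dtype=float)
        return cls(cpts=cpts, marginals=marginals)


def fit_cpts(dtable: DiscretizedTable, dag: DAG, alpha: float = 1.0) -> CPTSet:
    """Add-alpha-smoothed CPTs for every family of ``dag``.

    Each conditional row is (count + alpha) / (row total + alpha * arity);
    marginals are the plain empirical state frequencies.
    """
    names = dtable.variable_names
    index = {n: i for i, n in enumerate(names)}
    mat, arities = dtable.to_arrays()
    mat = mat.astype(np.int64)
    n = mat.shape[0]
    cpts, marginals = {}, {}
    for v in dag.nodes:
        r = int(arities[index[v]])
        ps = dag.parents[v]
        p_ar = tuple(int(arities[index[p]]) for p in ps)
        q = int(np.prod(p_ar)) if ps else 1
        if n:
            if ps:
                pcols = mat[:, [index[p] for p in ps]]
                rows = np.ravel_multi_index(pcols.T, p_ar)
            else:
                rows = np.zeros(n, dtype=np.int64)
            counts = np.bincount(rows * r + mat[:, index[v]], minlength=q * r)
            counts = counts.reshape(q, r).astype(float)
            marg = np.bincount(mat[:, index[v]], minlength=r).astype(float) / n
        else:
            counts = np.zeros((q, r))
            marg = np.full(r, 1.0 / r)
        table = (counts + alpha) / (counts.sum(axis=1, keepdims=True) + alpha * r)
        cpts[v] = CPT(v, tuple(ps), r, p_ar, table, alpha)
        marginals[v] = marg
    return CPTSet(cpts=cpts, marginals=marginals)


def influence_score(cptset: CPTSet, parent: str, child: str) -> float:
    """Signed monotonicity of the dependency ``parent -> child`` in [-1, 1].

    Requires the edge to be present in the fitted structure (``parent`` among
    the child CPT's parents).
    """
    cpt = cptset.cpts[child]
    if parent not in cpt.parents:
        raise ValueError(f"{parent!r} is not a parent of {child!r}")
    axis = cpt.parents.index(parent)
    r_p = cpt.parent_arities[axis]
    others = [k for k in range(len(cpt.parents)) if k != axis]
    other_arities = [cpt.parent_arities[k] for k in others]
    other_marginals = [
        np.asarray(cptset.marginals[cpt.parents[k]], dtype=float) for k in others
    ]

    num = 0.0
    den = 0.0
    for config in product(*(range(a) for a in other_arities)):
        w = 1.0
        for s, m in zip(config, other_marginals):
            w *= m[s]
        cdfs = []
        for p_state in range(r_p):
            full = [0] * len(cpt.parents)
            full[axis] = p_state
            for k, s in zip(others, config):
                full[k] = s
            cdfs.append(np.cumsum(cpt.row(tuple(full))))
        for a in range(r_p):
            for b in range(a + 1, r_p):
                d = cdfs[b] - cdfs[a]  # negative where F(.|b) below F(.|a)
                if (d <= 1e-12).all() and (d < -1e-12).any():
                    vote = 1.0
                elif (d >= -1e-12).all() and (d > 1e-12).any():
                    vote = -1.0
                else:
                    vote = 0.0
                num += w * vote
                den += w
    return num / den if den > 0 else 0.0


def ensemble_edge_is(ensemble, dtable: DiscretizedTable, alpha: float = 1.0):
    """Per-pair influence scores across a bootstrap ensemble.

    For every replicate whose learned DAG contains a pair, CPTs are fit on
    that replicate's subsample and the IS of the oriented edge is recorded.
    Returns ``{frozenset({a, b}): [is, ...]}``.
    """
    out: dict[frozenset, list[float]] = {}
    for idx, dag in zip(ensemble.subsample_indices, ensemble.dags):
        if not dag.n_edges:
            continue
        sub = DiscretizedTable(
            states=dtable.states.iloc[idx],
            arity=dtable.arity,
            boundaries=dtable.boundaries,
            rules=dtable.rules,
        )
        cpts = fit_cpts(sub, dag, alpha=alpha)
        for p, c in dag.edges:
            out.setdefault(frozenset((p, c)), []).append(
                influence_score(cpts, p, c)
            )
    return out
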
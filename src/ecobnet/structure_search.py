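"""BDeu scoring and greedy structure search for discrete Bayesian networks.

The score is the log BDeu marginal likelihood (Dirichlet-uniform parameter
prior with equivalent sample size ``ess``, uniform structure prior), which
decomposes over families (a child and its parent set):

    log P(D | G) = sum_v sum_j [ lnG(a_j) - lnG(a_j + N_j)
                   + sum_k ( lnG(a_jk + N_jk) - lnG(a_jk) ) ]

with a_j = ess / q_v, a_jk = ess / (q_v r_v), q_v the number of parent-state
configurations, r_v the child arity, N the state counts.

Search is hill climbing over single-edge moves (add / delete / reverse) with
random restarts: each proposal draws a random ordered pair, the implied move
is accepted iff it strictly improves the score and respects acyclicity, the
parent cap (default 3) and the excluded-pair constraints.  The search is
reproducible bit-for-bit from its seed, and the returned DAG never scores
below the empty network.

Internally DAGs are parent bitmasks over at most 63 variables, with a
per-family score cache, so a proposal is a couple of integer operations and
a dictionary lookup.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .discretize import DiscretizedTable
from .prefilter import ExclusionSet

__all__ = [
    "DAG",
    "SearchSettings",
    "bde_score",
    "greedy_search",
    "exhaustive_search",
    "enumerate_dags",
]

MAX_PARENTS = 3


@dataclass
class DAG:
    """Directed acyclic graph as per-node ordered parent tuples."""

    nodes: tuple[str, ...]
    parents: dict[str, tuple[str, ...]]
    max_parents: int = MAX_PARENTS

    def __post_init__(self):
        self.nodes = tuple(self.nodes)
        self.parents = {v: tuple(self.parents.get(v, ())) for v in self.nodes}
        for v, ps in self.parents.items():
            if len(ps) > self.max_parents:
                raise ValueError(f"{v!r} has {len(ps)} parents (cap {self.max_parents})")
            unknown = set(ps) - set(self.nodes)
            if unknown:
                raise ValueError(f"unknown parent(s) of {v!r}: {sorted(unknown)}")
        if self._has_cycle():
            raise ValueError("graph contains a directed cycle")

    def _has_cycle(self) -> bool:
        state = {v: 0 for v in self.nodes}  # 0 unvisited, 1 active, 2 done

        def visit(v):
            state[v] = 1
            for p in self.parents[v]:
                if state[p] == 1 or (state[p] == 0 and visit(p)):
                    return True
            state[v] = 2
            return False

        return any(state[v] == 0 and visit(v) for v in self.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """(parent, child) pairs, in node order."""
        return [(p, v) for v in self.nodes for p in self.parents[v]]

    @property
    def n_edges(self) -> int:
        return sum(len(ps) for ps in self.parents.values())

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for p, v in self.edges:
                fh.write(f"{p}\t{v}\n")


@dataclass
class SearchSettings:
    """Knobs of the greedy search.

    ``n_iterations`` is the *total* number of move proposals, split evenly
    across ``n_restarts`` random restarts; ``ess`` the BDeu equivalent sample
    size; ``init_edge_prob`` the chance each legal edge enters a restart's
    random starting DAG (repaired to acyclic).
    """

    n_iterations: int = 50_000
    n_restarts: int = 50
    ess: float = 1.0
    seed: int = 0
    max_parents: int = MAX_PARENTS
    init_edge_prob: float = 0.1

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.ess <= 0:
            raise ValueError("ess must be positive")


# ---------------------------------------------------------------------------
# Family scoring
# ---------------------------------------------------------------------------


class _Scorer:
    """Cached log BDeu family scores over a fixed state matrix."""

    def __init__(self, mat: np.ndarray, arities: np.ndarray, ess: float):
        for c in range(mat.shape[1]):
            col = mat[:, c]
            if col.size and (col.min() < 0 or col.max() >= arities[c]):
                raise ValueError(
                    f"column {c}: state outside declared arity {arities[c]}"
                )
        self.mat = np.ascontiguousarray(mat, dtype=np.int64)
        self.arities = [int(a) for a in arities]
        self.ess = float(ess)
        self.V = mat.shape[1]
        self._cols = [self.mat[:, c] for c in range(self.V)]
        self._cache: list[dict[int, float]] = [dict() for _ in range(self.V)]

    def family(self, child: int, pmask: int) -> float:
        """Log BDeu score of one family (child given the parents in pmask)."""
        cached = self._cache[child].get(pmask)
        if cached is not None:
            return cached
        r = self.arities[child]
        code = self._cols[child]
        q = 1
        m = pmask
        while m:
            p = (m & -m).bit_length() - 1
            m &= m - 1
            code = code + (q * r) * self._cols[p]
            q *= self.arities[p]
        counts = np.bincount(code, minlength=q * r).reshape(q, r)
        a_jk = self.ess / (q * r)
        a_j = self.ess / q
        nj = counts.sum(axis=1)
        score = float(
            q * gammaln(a_j)
            - gammaln(a_j + nj).sum()
            + gammaln(a_jk + counts).sum()
            - q * r * gammaln(a_jk)
        )
        self._cache[child][pmask] = score
        return score


def _scorer_for(dtable: DiscretizedTable, ess: float) -> _Scorer:
    mat, arities = dtable.to_arrays()
    return _Scorer(mat.astype(np.int64), arities, ess)


def bde_score(dtable: DiscretizedTable, dag: DAG, ess: float = 1.0) -> float:
    """Log BDeu marginal likelihood of ``dag`` on the discretized data.

    Decomposes as a sum of per-family terms; permuting data rows leaves it
    unchanged.  Structures are compared by this likelihood alone (uniform
    structure prior).
    """
    names = dtable.variable_names
    missing = set(dag.nodes) - set(names)
    if missing:
        raise ValueError(f"DAG nodes not in table: {sorted(missing)}")
    scorer = _scorer_for(dtable, ess)
    index = {n: i for i, n in enumerate(names)}
    total = 0.0
    for v in dag.nodes:
        pmask = 0
        for p in dag.parents[v]:
            pmask |= 1 << index[p]
        total += scorer.family(index[v], pmask)
    return total


# ---------------------------------------------------------------------------
# Greedy search
# ---------------------------------------------------------------------------


def _allowed_masks(names, constraint: Optional[ExclusionSet]) -> list[int]:
    V = len(names)
    full = (1 << V) - 1
    allowed = [full & ~(1 << i) for i in range(V)]
    if constraint is not None:
        for i in range(V):
            for j in range(i + 1, V):
                if constraint.blocks(names[i], names[j]):
                    allowed[i] &= ~(1 << j)
                    allowed[j] &= ~(1 << i)
    return allowed


def _reaches(ch: list[int], start: int, goal: int) -> bool:
    """True if `goal` is reachable from `start` along child links."""
    seen = 1 << start
    frontier = seen
    gbit = 1 << goal
    while frontier:
        nxt = 0
        f = frontier
        while f:
            v = (f & -f).bit_length() - 1
            f &= f - 1
            nxt |= ch[v]
        nxt &= ~seen
        if nxt & gbit:
            return True
        seen |= nxt
        frontier = nxt
    return False


def _random_start(rng, V, allowed, max_parents, edge_prob):
    """Random legal DAG: each allowed pair enters with ``edge_prob`` in a
    random direction, added in random order and dropped if it would break
    acyclicity or the parent cap."""
    pmask = [0] * V
    ch = [0] * V
    pairs = [(i, j) for i in range(V) for j in range(i + 1, V) if (allowed[i] >> j) & 1]
    if pairs:
        take = rng.random(len(pairs)) < edge_prob
        direction = rng.integers(0, 2, size=len(pairs))
        order = rng.permutation(len(pairs))
        for k in order:
            if not take[k]:
                continue
            i, j = pairs[k]
            if direction[k]:
                i, j = j, i
            # candidate edge i -> j
            if pmask[j].bit_count() >= max_parents:
                continue
            if _reaches(ch, j, i):
                continue
            pmask[j] |= 1 << i
            ch[i] |= 1 << j
    return pmask, ch


def greedy_search(
    dtable: DiscretizedTable,
    constraint: Optional[ExclusionSet] = None,
    settings: Optional[SearchSettings] = None,
) -> DAG:
    """Hill-climb with random restarts; return the best DAG visited.

    Moves are single-edge add/delete/reverse; proposals violating acyclicity,
    the parent cap, or an excluded pair are rejected, as are non-improving
    ones.  Deterministic given ``settings.seed``.  If every pair is excluded
    the empty DAG is returned.
    """
    import warnings as _w

    settings = settings or SearchSettings()
    names = dtable.variable_names
    V = len(names)
    if V < 2:
        raise ValueError("need at least 2 variables to search over")
    scorer = _scorer_for(dtable, settings.ess)
    allowed = _allowed_masks(names, constraint)
    if not any(allowed):
        _w.warn("all variable pairs excluded; returning the empty network")
        return DAG(tuple(names), {}, settings.max_parents)

    rng = np.random.default_rng(settings.seed)
    cap = settings.max_parents
    n_restarts = max(1, settings.n_restarts)
    per_restart = max(1, settings.n_iterations // n_restarts)

    empty_score = sum(scorer.family(v, 0) for v in range(V))
    best_score = empty_score
    best_pmask = [0] * V

    fam = scorer.family
    for _restart in range(n_restarts):
        pmask, ch = _random_start(rng, V, allowed, cap, settings.init_edge_prob)
        cur = [fam(v, pmask[v]) for v in range(V)]
        src = rng.integers(0, V, size=per_restart).tolist()
        dst = rng.integers(0, V, size=per_restart).tolist()
        coin = rng.integers(0, 2, size=per_restart).tolist()
        for k in range(per_restart):
            i = src[k]
            j = dst[k]
            if i == j or not (allowed[i] >> j) & 1:
                continue
            bi = 1 << i
            pj = pmask[j]
            if pj & bi:  # edge i -> j present: delete or reverse
                if coin[k]:
                    new = fam(j, pj & ~bi)
                    if new > cur[j]:
                        pmask[j] = pj & ~bi
                        ch[i] &= ~(1 << j)
                        cur[j] = new
                else:  # reverse i -> j  =>  j -> i
                    if pmask[i].bit_count() >= cap:
                        continue
                    new_j = fam(j, pj & ~bi)
                    new_i = fam(i, pmask[i] | (1 << j))
                    if new_j + new_i > cur[j] + cur[i]:
                        ch[i] &= ~(1 << j)
                        if _reaches(ch, i, j):  # other i~>j path blocks reversal
                            ch[i] |= 1 << j
                            continue
                        pmask[j] = pj & ~bi
                        pmask[i] |= 1 << j
                        ch[j] |= bi
                        cur[j] = new_j
                        cur[i] = new_i
            elif pmask[i] & (1 << j):
                continue  # opposite edge present; adding i->j would 2-cycle
            else:  # add i -> j
                if pj.bit_count() >= cap:
                    continue
                new = fam(j, pj | bi)
                if new > cur[j] and not _reaches(ch, j, i):
                    pmask[j] = pj | bi
                    ch[i] |= 1 << j
                    cur[j] = new
        total = sum(cur)
        if total > best_score:
            best_score = total
            best_pmask = list(pmask)

    parents = {
        names[v]: tuple(
            names[p] for p in range(V) if (best_pmask[v] >> p) & 1
        )
        for v in range(V)
    }
    return DAG(tuple(names), parents, settings.max_parents)


# ---------------------------------------------------------------------------
# Exhaustive reference search (small graphs only)
# ---------------------------------------------------------------------------


def enumerate_dags(n: int, max_parents: int = MAX_PARENTS):
    """Yield every labelled DAG on ``n`` nodes as a parent-bitmask list.

    Brute force over all 2^(n(n-1)) directed graphs — only sensible for
    n <= 4 (25 DAGs at n = 3, 543 at n = 4).
    """
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    for include in product((False, True), repeat=len(pairs)):
        pmask = [0] * n
        ch = [0] * n
        ok = True
        for (i, j), take in zip(pairs, include):
            if take:
                pmask[j] |= 1 << i
                ch[i] |= 1 << j
        if any(m.bit_count() > max_parents for m in pmask):
            continue
        # acyclicity by repeated leaf stripping
        indeg = [m.bit_count() for m in pmask]
        stack = [v for v in range(n) if indeg[v] == 0]
        seen = 0
        while stack:
            v = stack.pop()
            seen += 1
            m = ch[v]
            while m:
                w = (m & -m).bit_length() - 1
                m &= m - 1
                indeg[w] -= 1
                if indeg[w] == 0:
                    stack.append(w)
        if seen == n:
            yield pmask


def exhaustive_search(
    dtable: DiscretizedTable,
    constraint: Optional[ExclusionSet] = None,
    ess: float = 1.0,
    max_parents: int = MAX_PARENTS,
) -> tuple[DAG, float]:
    """Globally optimal DAG by scoring every structure (n <= 4 nodes)."""
    names = dtable.variable_names
    V = len(names)
    if V > 4:
        raise ValueError("exhaustive search is limited to 4 variables")
    scorer = _scorer_for(dtable, ess)
    allowed = _allowed_masks(names, constraint)
    best, best_pm = -np.inf, [0] * V
    for pmask in enumerate_dags(V, max_parents):
        if any(pmask[v] & ~allowed[v] for v in range(V)):
            continue
        s = sum(scorer.family(v, pmask[v]) for v in range(V))
        if s > best:
            best, best_pm = s, pmask
    parents = {
        names[v]: tuple(names[p] for p in range(V) if (best_pm[v] >> p) & 1)
        for v in range(V)
    }
    return DAG(tuple(names), parents, max_parents), best
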
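import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ecobnet import (
    DAG,
    BootstrapEnsemble,
    DiscretizedTable,
    SearchSettings,
    assemble_consensus,
    consensus_dag,
    contingency_exclusions,
    discretize_table,
    edge_stats,
    ensemble_edge_is,
    exclude_rare,
    occurrence_threshold,
    recovery_metrics,
    run_bootstrap,
    sample_community,
    simulate_ground_truth,
)
from ecobnet.bootstrap_consensus import (
    ConsensusEdge,
    ConsensusNetwork,
    chain_statistics,
    summarize,
)


def _dtable(n=60, k=3, seed=0):
    rng = np.random.default_rng(seed)
    cols = {f"v{i}": rng.integers(0, 3, n) for i in range(k)}
    df = pd.DataFrame({k_: np.asarray(v, dtype=np.int64) for k_, v in cols.items()})
    return DiscretizedTable(states=df, arity={c: 3 for c in df},
                            boundaries={c: 0.0 for c in df},
                            rules={c: "zero_low_high" for c in df})


SMALL = SearchSettings(n_iterations=600, n_restarts=2, seed=0)


class TestRunBootstrap:
    def test_subsample_sizes(self):
        dt = _dtable(n=40)
        ens = run_bootstrap(dt, None, SMALL, B=5, frac=0.95, seed=1)
        for idx in ens.subsample_indices:
            assert len(idx) == int(np.floor(0.95 * 40)) == 38
            assert len(set(idx)) == 38  # without replacement

    def test_frac_one_uses_every_sample(self):
        dt = _dtable(n=30)
        ens = run_bootstrap(dt, None, SMALL, B=3, frac=1.0, seed=2)
        for idx in ens.subsample_indices:
            assert idx == list(range(30))

    def test_same_seed_identical_ensembles(self):
        dt = _dtable(n=40)
        e1 = run_bootstrap(dt, None, SMALL, B=4, frac=0.9, seed=3)
        e2 = run_bootstrap(dt, None, SMALL, B=4, frac=0.9, seed=3)
        assert e1.subsample_indices == e2.subsample_indices
        assert [d.parents for d in e1.dags] == [d.parents for d in e2.dags]

    def test_too_few_samples_refused(self):
        dt = _dtable(n=9)
        with pytest.raises(ValueError, match="too few"):
            run_bootstrap(dt, None, SMALL, B=2, frac=0.95, seed=4)

    def test_occurrences_invariant_to_replicate_order(self):
        dt = _dtable(n=50, seed=5)
        ens = run_bootstrap(dt, None, SMALL, B=6, frac=0.9, seed=5)
        shuffled = BootstrapEnsemble(
            B=ens.B, frac=ens.frac,
            subsample_indices=list(reversed(ens.subsample_indices)),
            dags=list(reversed(ens.dags)), seed=ens.seed,
        )
        occ1 = {s.pair: s.occurrence for s in edge_stats(ens)}
        occ2 = {s.pair: s.occurrence for s in edge_stats(shuffled)}
        assert occ1 == occ2


class TestOccurrenceThreshold:
    @staticmethod
    def _em_oracle(x, iters=2000):
        """Independent 1-D two-component EM, initialized from the data split."""
        x = np.asarray(x, float)
        lo, hi = x < np.median(x), x >= np.median(x)
        w = np.array([lo.mean(), hi.mean()])
        mu = np.array([x[lo].mean(), x[hi].mean()])
        var = np.array([max(x[lo].var(), 1e-6), max(x[hi].var(), 1e-6)])
        for _ in range(iters):
            pdf = np.stack([
                w[k] * np.exp(-0.5 * (x - mu[k]) ** 2 / var[k])
                / np.sqrt(2 * np.pi * var[k])
                for k in range(2)
            ])
            resp = pdf / pdf.sum(axis=0)
            w = resp.mean(axis=1)
            mu = (resp * x).sum(axis=1) / resp.sum(axis=1)
            var = (resp * (x - mu[:, None]) ** 2).sum(axis=1) / resp.sum(axis=1)
            var = np.maximum(var, 1e-6)
        # density crossing between the means
        grid = np.linspace(mu.min(), mu.max(), 20001)
        d = (w[0] * np.exp(-0.5 * (grid - mu[0]) ** 2 / var[0]) / np.sqrt(var[0])
             - w[1] * np.exp(-0.5 * (grid - mu[1]) ** 2 / var[1]) / np.sqrt(var[1]))
        s = np.where(np.diff(np.sign(d)) != 0)[0]
        return grid[s[0]] if len(s) else float(mu.mean())

    def test_bimodal_mixture_threshold_matches_em_oracle(self):
        rng = np.random.default_rng(9)
        occ = np.clip(np.concatenate([
            rng.normal(0.10, 0.03, 30), rng.normal(0.90, 0.03, 10)
        ]), 0.01, 1.0)
        thr = occurrence_threshold(occ)
        oracle = self._em_oracle(occ)
        assert abs(thr - oracle) < 0.05
        assert 0.2 < thr < 0.8  # well between the two modes

    def test_all_equal_falls_back_to_majority(self):
        assert occurrence_threshold([0.4] * 10) == 0.5

    def test_unimodal_data_prefers_single_component(self):
        rng = np.random.default_rng(10)
        occ = np.clip(rng.normal(0.5, 0.05, 60), 0, 1)
        assert occurrence_threshold(occ) == 0.5


class TestAssembleConsensus:
    @staticmethod
    def _ensemble_with(pair_count, forward_count, B=100):
        """Ensemble of 2-node DAGs: `pair_count` contain the edge, of which
        `forward_count` orient it a -> b."""
        dags = []
        for k in range(B):
            if k < forward_count:
                dags.append(DAG(("a", "b"), {"b": ("a",)}))
            elif k < pair_count:
                dags.append(DAG(("a", "b"), {"a": ("b",)}))
            else:
                dags.append(DAG(("a", "b"), {}))
        idx = [list(range(20))] * B
        return BootstrapEnsemble(B=B, frac=1.0, subsample_indices=idx,
                                 dags=dags, seed=0)

    def test_majority_forward_direction(self):
        net = assemble_consensus(self._ensemble_with(70, 65), threshold=0.5)
        (e,) = net.edges
        assert e.occurrence == pytest.approx(0.70)
        assert e.direction == "forward"

    def test_even_split_is_mutual(self):
        net = assemble_consensus(self._ensemble_with(80, 40), threshold=0.5)
        assert net.edges[0].direction == "mutual"

    def test_below_threshold_dropped(self):
        net = assemble_consensus(self._ensemble_with(30, 30), threshold=0.5)
        assert net.edges == []

    def test_link_density_and_connectance(self):
        nodes = [f"n{i}" for i in range(8)]
        pairs = list(itertools.combinations(nodes, 2))[:10]
        edges = [ConsensusEdge(a, b, "forward", 1.0, 0.1) for a, b in pairs]
        summary = summarize(nodes, edges)
        assert summary["link_density"] == pytest.approx(10 / 8)  # 1.25
        assert summary["connectance"] == pytest.approx(10 / (8 * 7))

    def test_mean_is_only_over_containing_replicates(self):
        ens = self._ensemble_with(50, 50)
        isv = {frozenset(("a", "b")): [0.5] * 50}
        net = assemble_consensus(ens, 0.4, isv)
        assert net.edges[0].mean_is == pytest.approx(0.5)


class TestChainStatistics:
    @staticmethod
    def _oracle(graph):
        """Brute-force maximal-simple-path enumeration via permutations."""
        nodes = list(graph.nodes)
        best = {}
        for r in range(3, len(nodes) + 1):
            for perm in itertools.permutations(nodes, r):
                if any(not graph.has_edge(a, b) for a, b in zip(perm, perm[1:])):
                    continue
                if any(graph.has_edge(x, perm[0]) and x not in perm
                       for x in graph.nodes):
                    continue
                if any(graph.has_edge(x, perm[-1]) and x not in perm
                       for x in graph.nodes):
                    continue
                pair = frozenset((perm[0], perm[-1]))
                best[pair] = max(best.get(pair, 0), r - 1)
        lengths = sorted(best.values())
        return {
            "n_chains": len(lengths),
            "max_chain_length": max(lengths) if lengths else 0,
            "mean_chain_length": float(np.mean(lengths)) if lengths else 0.0,
        }

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n = int(rng.integers(3, 8))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1 << 30)))
            assert chain_statistics(g) == self._oracle(g)

    def test_line_graph_single_chain(self):
        g = nx.path_graph(4)
        stats = chain_statistics(g)
        assert stats == {"n_chains": 1, "max_chain_length": 3,
                         "mean_chain_length": 3.0}


class TestConsensusDag:
    def test_orientations_respected_and_acyclic(self):
        edges = [
            ConsensusEdge("a", "b", "forward", 1.0, 0.1),
            ConsensusEdge("b", "c", "backward", 1.0, 0.1),
            ConsensusEdge("a", "c", "mutual", 1.0, 0.1),
        ]
        net = ConsensusNetwork(nodes=["a", "b", "c"], edges=edges)
        dag = consensus_dag(net)
        assert "a" in dag.parents["b"]  # forward kept
        assert "c" in dag.parents["b"]  # backward flipped
        assert dag.n_edges == 3


class TestEndToEndRecovery:
    def test_strong_signal_network_recovered(self):
        # scaled-down recovery check; the full-strength version runs in the
        # acceptance suite
        f1s = []
        for seed in (0, 1, 2):
            gt = simulate_ground_truth(n_taxa=5, n_edges=5, lam=0.9, seed=seed)
            table = sample_community(gt, n_photos=500, photos_per_event=25,
                                     seed=seed + 100)
            kept, rare = exclude_rare(table)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dt = discretize_table(table, keep=kept)
                excl = rare.merged_with(contingency_exclusions(dt))
                ens = run_bootstrap(
                    dt, excl,
                    SearchSettings(n_iterations=10000, n_restarts=5,
                                   seed=seed + 200),
                    B=30, frac=0.95, seed=seed + 300,
                )
            isv = ensemble_edge_is(ens, dt)
            occ = [s.occurrence for s in edge_stats(ens, isv)]
            try:
                thr = occurrence_threshold(occ)
            except ValueError:
                thr = 0.5
            net = assemble_consensus(ens, thr, isv, nodes=dt.variable_names)
            f1s.append(recovery_metrics(net, gt).f1)
        assert np.mean(f1s) >= 0.7
        assert max(f1s) >= 0.8

    def test_excluded_pairs_have_zero_occurrence(self):
        dt = _dtable(n=80, seed=12)
        excl = contingency_exclusions(dt, threshold=0.0)  # bar everything > 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ens = run_bootstrap(dt, excl, SMALL, B=5, frac=0.9, seed=13)
        barred = set(excl.excluded_pairs)
        for s in edge_stats(ens):
            assert s.pair not in barred
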
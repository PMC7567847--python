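import numpy as np
import pytest

from ecobnet import (
    NoChainError,
    exact_conditional,
    exact_joint,
    find_chain,
    propagate,
    state_change_report,
    substrate_contrast,
)
from ecobnet.bootstrap_consensus import ConsensusEdge, ConsensusNetwork
from ecobnet.influence import CPT, CPTSet

from conftest import chain_cptset, line_network


def random_polytree_cptset(rng, n_nodes, arity=3):
    """Random directed tree (each non-root has one parent) with Dirichlet
    CPTs and exact marginals, plus its consensus graph."""
    names = [f"N{i}" for i in range(n_nodes)]
    parent = {0: None}
    for v in range(1, n_nodes):
        parent[v] = int(rng.integers(0, v))
    cpts = {}
    for v, name in enumerate(names):
        if parent[v] is None:
            cpts[name] = CPT(name, (), arity, (),
                             rng.dirichlet(np.ones(arity))[np.newaxis, :])
        else:
            cpts[name] = CPT(name, (names[parent[v]],), arity, (arity,),
                             rng.dirichlet(np.ones(arity), size=arity))
    cs = CPTSet(cpts=cpts,
                marginals={n: np.full(arity, 1 / arity) for n in names})
    nodes, joint = exact_joint(cs)
    for i, n in enumerate(nodes):
        axes = tuple(k for k in range(n_nodes) if k != i)
        cs.marginals[n] = joint.sum(axis=axes)
    edges = [
        ConsensusEdge(*sorted((names[parent[v]], names[v])), "forward", 1.0, 0.0)
        for v in range(1, n_nodes)
    ]
    net = ConsensusNetwork(nodes=names, edges=edges)
    return cs, net


class TestFindChain:
    def _net(self, pairs, nodes):
        edges = [ConsensusEdge(*sorted(p), "forward", 1.0, 0.0) for p in pairs]
        return ConsensusNetwork(nodes=nodes, edges=edges)

    def _cpts(self, edges, nodes, arity=2):
        cpts = {}
        for n in nodes:
            parents = tuple(p for p, c in edges if c == n)
            if parents:
                tbl = np.full((arity ** len(parents), arity), 1 / arity)
                cpts[n] = CPT(n, parents, arity, (arity,) * len(parents), tbl)
            else:
                cpts[n] = CPT(n, (), arity, (), np.full((1, arity), 1 / arity))
        return CPTSet(cpts=cpts,
                      marginals={n: np.full(arity, 1 / arity) for n in nodes})

    def test_direct_edge(self):
        net = self._net([("A", "B")], ["A", "B"])
        cs = self._cpts([("A", "B")], ["A", "B"])
        chain = find_chain(net, "A", "B", cs)
        assert chain.nodes == ["A", "B"]
        assert chain.length == 1
        assert chain.step_orientation == ["along"]

    def test_unique_two_step_path(self):
        net = self._net([("A", "C"), ("B", "C")], ["A", "B", "C"])
        cs = self._cpts([("A", "C"), ("C", "B")], ["A", "B", "C"])
        chain = find_chain(net, "A", "B", cs)
        assert chain.nodes == ["A", "C", "B"]
        assert chain.step_orientation == ["along", "along"]

    def test_equal_length_tie_lexicographic(self):
        net = self._net([("A", "C"), ("C", "B"), ("A", "D"), ("D", "B")],
                        ["A", "B", "C", "D"])
        cs = self._cpts([("A", "C"), ("C", "B"), ("A", "D"), ("D", "B")],
                        ["A", "B", "C", "D"])
        chain = find_chain(net, "A", "B", cs)
        assert chain.nodes == ["A", "C", "B"]

    def test_disconnected_pair_raises(self):
        net = self._net([], ["A", "B"])
        cs = self._cpts([], ["A", "B"])
        with pytest.raises(NoChainError):
            find_chain(net, "A", "B", cs)


class TestPropagate:
    def test_single_along_step_returns_cpt_row(self):
        tbl = np.array([[0.9, 0.1], [0.2, 0.8]])
        cs = chain_cptset([tbl])
        chain = find_chain(line_network(2), "N0", "N1", cs)
        for s in (0, 1):
            assert np.allclose(propagate(chain, cs, s), tbl[s])

    def test_against_step_is_bayes_inversion(self):
        # P(child | parent) rows [[0.9, 0.1], [0.2, 0.8]], parent marginal
        # (0.5, 0.5); forcing child = 1 gives P(parent=1 | child=1) = 8/9
        tbl = np.array([[0.9, 0.1], [0.2, 0.8]])
        cs = chain_cptset([tbl], marginals={"N0": [0.5, 0.5]})
        chain = find_chain(line_network(2), "N1", "N0", cs)
        assert chain.step_orientation == ["against"]
        out = propagate(chain, cs, 1)
        assert out[1] == pytest.approx(8 / 9, abs=1e-12)

    def test_three_node_chain_matches_enumeration(self):
        rng = np.random.default_rng(20)
        t1 = rng.dirichlet(np.ones(3), size=3)
        t2 = rng.dirichlet(np.ones(3), size=3)
        cs = chain_cptset([t1, t2])
        nodes, joint = exact_joint(cs)
        for i, n in enumerate(nodes):
            cs.marginals[n] = joint.sum(axis=tuple(k for k in range(3) if k != i))
        chain = find_chain(line_network(3), "N0", "N2", cs)
        for s in range(3):
            direct = propagate(chain, cs, s)
            exact = exact_conditional(cs, "N0", s, "N2")
            assert np.abs(direct - exact).max() < 1e-10

    def test_output_is_a_distribution(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            cs, net = random_polytree_cptset(rng, 5)
            chain = find_chain(net, "N4", "N0", cs)
            for s in range(3):
                out = propagate(chain, cs, s)
                assert out.min() >= 0
                assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_polytree_propagation_matches_enumeration(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            cs, net = random_polytree_cptset(rng, n)
            src, tgt = rng.choice(n, size=2, replace=False)
            chain = find_chain(net, f"N{src}", f"N{tgt}", cs)
            s = int(rng.integers(0, 3))
            direct = propagate(chain, cs, s)
            exact = exact_conditional(cs, f"N{src}", s, f"N{tgt}")
            assert np.abs(direct - exact).max() < 1e-10


class TestStateChangeReport:
    def test_two_node_contrast_hand_computed(self):
        # forcing the child from 1 to 0, parent prior (0.5, 0.5):
        # P(p=1 | c=1) = 0.8*0.5 / (0.1*0.5 + 0.8*0.5) = 8/9
        # P(p=1 | c=0) = 0.2*0.5 / (0.9*0.5 + 0.2*0.5) = 2/11
        # delta_p(parent=1) = 2/11 - 8/9 = -0.7071
        tbl = np.array([[0.9, 0.1], [0.2, 0.8]])
        cs = chain_cptset([tbl], marginals={"N0": [0.5, 0.5]})
        report = state_change_report(line_network(2), cs, "N1", 1, 0)
        delta = report.targets["N0"]["delta_p"]
        assert delta[1] == pytest.approx(2 / 11 - 8 / 9, abs=1e-12)

    def test_delta_p_sums_to_zero(self):
        rng = np.random.default_rng(23)
        cs, net = random_polytree_cptset(rng, 6)
        report = state_change_report(net, cs, "N0", 2, 0)
        for t in report.targets.values():
            assert abs(np.sum(t["delta_p"])) < 1e-9

    def test_unconnected_node_reports_zero_delta(self):
        nodes = ["A", "B", "C"]
        edges = [ConsensusEdge("A", "B", "forward", 1.0, 0.0)]
        net = ConsensusNetwork(nodes=nodes, edges=edges)
        tbl = np.array([[0.9, 0.1], [0.2, 0.8]])
        cpts = {
            "A": CPT("A", (), 2, (), np.array([[0.5, 0.5]])),
            "B": CPT("B", ("A",), 2, (2,), tbl),
            "C": CPT("C", (), 2, (), np.array([[0.4, 0.6]])),
        }
        cs = CPTSet(cpts=cpts, marginals={"A": np.array([0.5, 0.5]),
                                          "B": tbl.T @ np.array([0.5, 0.5]),
                                          "C": np.array([0.4, 0.6])})
        report = state_change_report(net, cs, "A", 1, 0)
        assert np.allclose(report.targets["C"]["delta_p"], 0.0)
        # unconnected nodes do not enter the mean
        connected_only = np.abs(report.targets["B"]["delta_p"]).mean()
        assert report.mean_delta_p == pytest.approx(connected_only)

    def test_attenuation_along_noisy_copy_chain(self):
        # the forced-state effect shrinks with distance from the source
        noisy_copy = np.array([[0.8, 0.15, 0.05],
                               [0.1, 0.8, 0.1],
                               [0.05, 0.15, 0.8]])
        cs = chain_cptset([noisy_copy] * 4)
        nodes, joint = exact_joint(cs)
        for i, n in enumerate(nodes):
            cs.marginals[n] = joint.sum(axis=tuple(k for k in range(5) if k != i))
        report = state_change_report(line_network(5), cs, "N0", 2, 0)
        effects = [np.abs(report.targets[f"N{k}"]["delta_p"]).max()
                   for k in range(1, 5)]
        assert all(a >= b - 1e-12 for a, b in zip(effects, effects[1:]))


class TestSubstrateContrast:
    def _setup(self):
        tbl = np.array([[0.7, 0.2, 0.1], [0.3, 0.4, 0.3], [0.1, 0.2, 0.7]])
        cpts = {
            "Substrate": CPT("Substrate", (), 3, (),
                             np.array([[0.3, 0.25, 0.45]])),
            "Porifera": CPT("Porifera", ("Substrate",), 3, (3,), tbl),
        }
        cs = CPTSet(cpts=cpts, marginals={
            "Substrate": np.array([0.3, 0.25, 0.45]),
            "Porifera": tbl.T @ np.array([0.3, 0.25, 0.45]),
        })
        net = ConsensusNetwork(
            nodes=["Substrate", "Porifera"],
            edges=[ConsensusEdge("Porifera", "Substrate", "backward", 1.0, 0.6)],
        )
        return net, cs

    def test_symmetric_in_state_order(self):
        net, cs = self._setup()
        ab = substrate_contrast(net, cs, "Substrate", 0, 2)
        ba = substrate_contrast(net, cs, "Substrate", 2, 0)
        assert ab == pytest.approx(ba)

    def test_category_labels_resolved(self):
        net, cs = self._setup()
        cmap = {"Gravel": 0, "Rocky": 1, "Silt": 2}
        by_label = substrate_contrast(net, cs, "Substrate", "Silt", "Rocky",
                                      category_map=cmap)
        by_state = substrate_contrast(net, cs, "Substrate", 2, 1)
        assert by_label == pytest.approx(by_state)

    def test_unknown_label_is_usage_error(self):
        net, cs = self._setup()
        with pytest.raises(ValueError, match="unknown state label"):
            substrate_contrast(net, cs, "Substrate", "Mud", "Silt",
                               category_map={"Silt": 2})

    def test_unconnected_substrate_contrast_is_zero(self):
        _, cs = self._setup()
        net = ConsensusNetwork(nodes=["Substrate", "Porifera"], edges=[])
        assert substrate_contrast(net, cs, "Substrate", 0, 2) == 0.0
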
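import numpy as np
import pandas as pd
import pytest

from ecobnet import AbundanceTable, VariableSpec
from ecobnet.bootstrap_consensus import ConsensusEdge, ConsensusNetwork
from ecobnet.influence import CPT, CPTSet


@pytest.fixture
def tiny_table():
    """Three photographs, one taxon and one continuous variable."""
    specs = (VariableSpec("Porifera", "taxon"), VariableSpec("Depth", "continuous"))
    data = pd.DataFrame(
        {"Porifera": [0, 2, 5], "Depth": [500.0, 750.0, 1000.0]},
        index=["p1", "p2", "p3"],
    )
    return AbundanceTable(data=data, specs=specs)


def random_network(rng, n_nodes=6, n_edges=5):
    """A valid random consensus network for round-trip tests."""
    nodes = [f"N{i:02d}" for i in range(n_nodes)]
    pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
    take = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    edges = []
    for k in take:
        a, b = pairs[k]
        edges.append(
            ConsensusEdge(
                source=a,
                target=b,
                direction=["forward", "backward", "mutual"][rng.integers(3)],
                occurrence=round(float(rng.uniform(0.2, 1.0)), 6),
                mean_is=round(float(rng.uniform(-1, 1)), 6),
            )
        )
    return ConsensusNetwork(nodes=nodes, edges=edges, threshold=0.1)


def chain_cptset(tables, marginals=None):
    """CPTSet for a simple chain N0 -> N1 -> ... given per-step row tables."""
    cpts = {}
    margs = {}
    r0 = tables[0].shape[0] if tables else 2
    cpts["N0"] = CPT("N0", (), r0, (), np.full((1, r0), 1.0 / r0))
    margs["N0"] = np.full(r0, 1.0 / r0)
    for k, tbl in enumerate(tables, 1):
        name, parent = f"N{k}", f"N{k - 1}"
        r_p, r_c = tbl.shape
        cpts[name] = CPT(name, (parent,), r_c, (r_p,), tbl)
        margs[name] = np.full(r_c, 1.0 / r_c)
    cs = CPTSet(cpts=cpts, marginals=margs)
    if marginals:
        cs.marginals.update({k: np.asarray(v, float) for k, v in marginals.items()})
    return cs


def line_network(n):
    """Consensus network N0 - N1 - ... - N(n-1) as forward edges."""
    nodes = [f"N{k}" for k in range(n)]
    edges = [
        ConsensusEdge(f"N{k}", f"N{k + 1}", "forward", 1.0, 0.0)
        for k in range(n - 1)
    ]
    return ConsensusNetwork(nodes=nodes, edges=edges)
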
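import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dnbsle.dataset import ExpressionDataset
from dnbsle.network import TemplateNetwork


@pytest.fixture
def path_network() -> TemplateNetwork:
    """A - B - C path."""
    return TemplateNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star_network() -> TemplateNetwork:
    """Star centred on X with leaves a, b, c."""
    return TemplateNetwork.from_edges([("X", "a"), ("X", "b"), ("X", "c")])


def random_instance(rng, n_genes=None, n_ref=None, p_edge=0.45):
    """Random small network + expression for oracle comparisons."""
    import networkx as nx

    n_genes = n_genes or int(rng.integers(4, 13))
    n_ref = n_ref or int(rng.integers(3, 7))
    while True:
        g = nx.gnp_random_graph(n_genes, p_edge, seed=int(rng.integers(2**31)))
        if any(d >= 2 for _, d in g.degree):
            break
    names = [f"g{i}" for i in range(n_genes)]
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    net = TemplateNetwork(g)
    ref = pd.DataFrame(
        rng.normal(0, 1, size=(n_genes, n_ref)),
        index=names,
        columns=[f"r{j}" for j in range(n_ref)],
    )
    case = pd.Series(rng.normal(0, 1, size=n_genes), index=names)
    return net, ref, case


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """Two time points, 4 genes, 3 reference + 2 case samples per time."""
    rng = np.random.default_rng(42)
    genes = ["A", "B", "C", "D"]
    cols, rows = {}, []
    for t in ("t0", "t1"):
        for grp, n in (("reference", 3), ("case", 2)):
            for i in range(n):
                sid = f"{t}_{grp}_{i}"
                cols[sid] = rng.normal(10, 1, size=4)
                rows.append({"sample_id": sid, "time": t, "group": grp})
    values = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(rows).set_index("sample_id")[["time", "group"]]
    return ExpressionDataset(values, meta)
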
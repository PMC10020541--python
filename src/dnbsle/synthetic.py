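"""Seeded synthetic time courses with a planted DNB module and tipping time.

The generator draws a scale-free (or Erdos-Renyi) template network, plants a
connected module of m genes (additionally wired into a clique so module
locals contain module neighbours), and simulates expression from a linear
two-factor Gaussian model:

    module gene i:     x = mu_i + a * z + b(t) * w + eps
    non-module gene j: x = mu_j + b_base * w + eps

with z ~ N(0, sigma_z(t)^2) shared by module genes within a sample,
w ~ N(0, 1) shared by all genes within a sample, and independent gene noise
eps ~ N(0, sigma_eps^2).  At the planted tipping time t* the module factor SD
jumps (sigma_z_base -> sigma_z_peak) while the module's loading on the
global background drops (b_base -> b_peak), so within-module SD and
correlation rise while module-to-outside correlation falls — exactly the
three DNB conditions.  Reference samples always use off-peak parameters
(untreated cells never transition).  The pairwise within-module correlation
has the closed form (a^2 sigma_z^2 + b^2) / (a^2 sigma_z^2 + b^2 +
sigma_eps^2), used for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from dnbsle.core_genes import AnnotationTables
from dnbsle.dataset import CASE, REFERENCE, ExpressionDataset
from dnbsle.network import TemplateNetwork


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults define the study conditions."""

    K: int = 60                 # total genes
    m: int = 10                 # planted module size
    T: int = 5                  # time points
    t_star: int = 3             # planted critical index (0-based)
    n_ref: int = 4              # reference samples per time
    n_case: int = 4             # case samples per time
    a: float = 1.0              # module factor loading
    sigma_z_base: float = 0.3   # module factor SD off-peak
    sigma_z_peak: float = 2.0   # module factor SD at t*
    sigma_eps: float = 1.0      # independent gene noise SD
    b_base: float = 0.8         # background loading off-peak
    b_peak: float = 0.1         # background loading of module genes at t*
    network_model: str = "barabasi_albert"
    seed: int = 7

    def __post_init__(self) -> None:
        if not (2 <= self.m < self.K):
            raise SyntheticError("need 2 <= m < K")
        if not (0 <= self.t_star < self.T):
            raise SyntheticError("need 0 <= t_star < T")
        # equality allowed so the null (no planted peak) configuration exists
        if not (self.sigma_z_peak >= self.sigma_z_base > 0):
            raise SyntheticError("need sigma_z_peak >= sigma_z_base > 0")
        if self.sigma_eps <= 0:
            raise SyntheticError("sigma_eps must be > 0")
        if min(self.n_ref, self.n_case) < 3:
            raise SyntheticError("need n_ref, n_case >= 3")
        if self.network_model not in ("barabasi_albert", "erdos_renyi"):
            raise SyntheticError(f"unknown network model {self.network_model!r}")

    @property
    def time_labels(self) -> list[str]:
        return [f"t{i}" for i in range(self.T)]

    @property
    def t_star_label(self) -> str:
        return f"t{self.t_star}"


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    module_genes: set[str]
    t_star: str
    expected_pcc_at_peak: float
    expected_pcc_off_peak: float


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def expected_module_pcc(a: float, sigma_z: float, b: float, sigma_eps: float) -> float:
    """Exact pairwise correlation between two module genes in the factor model."""
    shared = a * a * sigma_z * sigma_z + b * b
    return shared / (shared + sigma_eps * sigma_eps)


def generate_network(config: SyntheticConfig) -> tuple[TemplateNetwork, set[str]]:
    """Seeded template network with a planted connected m-gene module.

    The module is grown by BFS from a random node and then wired into a
    clique so that every module gene's local network contains other module
    genes.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.K - 1))
    names = [_gene_name(i, width) for i in range(config.K)]
    graph_seed = int(rng.integers(0, 2**31 - 1))
    if config.network_model == "barabasi_albert":
        g = nx.barabasi_albert_graph(config.K, 2, seed=graph_seed)
    else:
        g = nx.erdos_renyi_graph(config.K, 4.0 / config.K, seed=graph_seed)
    g = nx.relabel_nodes(g, dict(enumerate(names)))

    module: set[str] = set()
    for _ in range(50):
        start = names[int(rng.integers(config.K))]
        bfs = [start]
        seen = {start}
        queue = [start]
        while queue and len(bfs) < config.m:
            node = queue.pop(0)
            for nb in sorted(g.neighbors(node)):
                if nb not in seen:
                    seen.add(nb)
                    bfs.append(nb)
                    queue.append(nb)
                    if len(bfs) == config.m:
                        break
        if len(bfs) == config.m:
            module = set(bfs)
            break
    if not module:
        raise SyntheticError(
            f"could not grow a connected {config.m}-gene module in 50 attempts"
        )
    module_sorted = sorted(module)
    for i, u in enumerate(module_sorted):
        for v in module_sorted[i + 1 :]:
            g.add_edge(u, v)
    return TemplateNetwork(g), module


def simulate_timecourse(
    network: TemplateNetwork,
    module: set[str],
    config: SyntheticConfig,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate the two-factor time course over the planted network."""
    rng = np.random.default_rng(config.seed + 1)
    genes = sorted(network.nodes)
    missing = module - set(genes)
    if missing:
        raise SyntheticError(f"module genes not in network: {sorted(missing)[:5]}")
    K = len(genes)
    is_module = np.array([g in module for g in genes])
    mu = rng.normal(10.0, 2.0, size=K)  # per-gene baseline, log-scale-like

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for ti, t in enumerate(config.time_labels):
        for group, n in ((REFERENCE, config.n_ref), (CASE, config.n_case)):
            at_peak = group == CASE and ti == config.t_star
            sigma_z = config.sigma_z_peak if at_peak else config.sigma_z_base
            b_mod = config.b_peak if at_peak else config.b_base
            for s in range(n):
                z = rng.normal(0.0, sigma_z)
                w = rng.normal(0.0, 1.0)
                eps = rng.normal(0.0, config.sigma_eps, size=K)
                x = mu + config.b_base * w + eps
                x[is_module] = (
                    mu[is_module] + config.a * z + b_mod * w + eps[is_module]
                )
                sid = f"{t}_{group}_{s}"
                columns[sid] = x
                meta_rows.append({"sample_id": sid, "time": t, "group": group})

    values = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")[["time", "group"]]
    data = ExpressionDataset(values, meta)
    truth = GroundTruth(
        module_genes=set(module),
        t_star=config.t_star_label,
        expected_pcc_at_peak=expected_module_pcc(
            config.a, config.sigma_z_peak, config.b_peak, config.sigma_eps
        ),
        expected_pcc_off_peak=expected_module_pcc(
            config.a, config.sigma_z_base, config.b_base, config.sigma_eps
        ),
    )
    return data, truth


def make_annotation_fixture(
    genes: list[str],
    module: set[str],
    seed: int = 0,
    p_tf_module: float = 0.5,
    p_tf_background: float = 0.1,
    p_deg_module: float = 0.7,
    p_deg_background: float = 0.2,
    n_pathways: int = 3,
) -> AnnotationTables:
    """Seeded TF/DEG flags and synthetic pathways for end-to-end testing.

    Module genes are enriched for TF identity (P = 0.5 vs 0.1 in the
    background) and DEG status (0.7 vs 0.2); pathways sample module genes
    preferentially and all but the last pathway are flagged significant.
    """
    rng = np.random.default_rng(seed)
    tables = AnnotationTables()
    for g in genes:
        p_tf = p_tf_module if g in module else p_tf_background
        p_deg = p_deg_module if g in module else p_deg_background
        if rng.random() < p_tf:
            tables.tf_genes.add(g)
        if rng.random() < p_deg:
            tables.deg_genes.add(g)
    for i in range(n_pathways):
        pid = f"path{i:02d}"
        members = {
            g
            for g in genes
            if rng.random() < (0.6 if g in module else 0.15)
        }
        tables.pathway_membership[pid] = members
        tables.pathway_significant[pid] = i < max(n_pathways - 1, 1)
    return tables
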
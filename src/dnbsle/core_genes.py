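"""Five-criterion DNB core-gene screen.

DNB members are prioritised by (1) transcription-factor identity, (2) hub
rank within the DNB-member interaction subgraph, (3) pathway involvement of
the gene's DNB neighbourhood, (4) differential-expression status and (5) a
DEG-rich first-order neighbourhood.  The count-based criteria are reported
after natural-log processing, ln(1 + count), so zero-count genes stay
finite.  TF flags, DEG flags and pathway membership (with per-pathway
significance) are consumed as precomputed annotation tables; no database
retrieval or enrichment testing happens here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from dnbsle.dnb import DNBResult
from dnbsle.network import TemplateNetwork, first_order_neighbors, topological_rank

logger = logging.getLogger(__name__)


class CoreGeneError(ValueError):
    pass


@dataclass
class AnnotationTables:
    """Precomputed annotation inputs for the core-gene screen.

    ``pathway_membership`` maps pathway id -> gene set; ``pathway_significant``
    flags which pathways passed upstream enrichment (p.adj < 0.05 upstream).
    """

    tf_genes: set[str] = field(default_factory=set)
    deg_genes: set[str] = field(default_factory=set)
    pathway_membership: dict[str, set[str]] = field(default_factory=dict)
    pathway_significant: dict[str, bool] = field(default_factory=dict)

    def significant_pathways(self) -> list[str]:
        return sorted(
            p for p in self.pathway_membership if self.pathway_significant.get(p, False)
        )

    @classmethod
    def read(
        cls,
        tf_path: str | Path | None = None,
        deg_path: str | Path | None = None,
        pathway_path: str | Path | None = None,
    ) -> "AnnotationTables":
        """Read gene-list TSVs and a pathway table (pathway_id, gene, significant)."""
        from dnbsle.network import read_gene_list

        tables = cls()
        if tf_path is not None:
            tables.tf_genes = read_gene_list(tf_path)
        if deg_path is not None:
            tables.deg_genes = read_gene_list(deg_path)
        if pathway_path is not None:
            df = pd.read_csv(pathway_path, sep="\t", dtype=str, comment="#")
            required = {"pathway_id", "gene", "significant"}
            if not required.issubset(df.columns):
                raise CoreGeneError(f"pathway table must have columns {sorted(required)}")
            for pid, grp in df.groupby("pathway_id"):
                tables.pathway_membership[pid] = set(grp["gene"])
                tables.pathway_significant[pid] = (
                    grp["significant"].astype(str).str.lower().isin({"1", "true", "yes"}).any()
                )
        return tables

    def write(self, tf_path: str | Path, deg_path: str | Path, pathway_path: str | Path) -> None:
        from dnbsle.network import write_gene_list

        write_gene_list(self.tf_genes, tf_path)
        write_gene_list(self.deg_genes, deg_path)
        rows = []
        for pid in sorted(self.pathway_membership):
            sig = "1" if self.pathway_significant.get(pid, False) else "0"
            for g in sorted(self.pathway_membership[pid]):
                rows.append({"pathway_id": pid, "gene": g, "significant": sig})
        pd.DataFrame(rows, columns=["pathway_id", "gene", "significant"]).to_csv(
            pathway_path, sep="\t", index=False
        )


@dataclass(frozen=True)
class CoreGeneScore:
    """Per-gene record of the five screening criteria."""

    gene: str
    is_tf: bool
    in_ppi_topk: bool
    kegg_score: float        # ln(1 + pathway-involvement count of the neighbourhood)
    is_deg: bool
    deg_neighbor_score: float  # ln(1 + number of DEGs among first-order neighbours)


def score_core_genes(
    dnb: DNBResult,
    network: TemplateNetwork,
    tables: AnnotationTables,
    topk: int = 100,
    rank_method: str = "degree",
) -> list[CoreGeneScore]:
    """Score every DNB member on the five core-gene criteria.

    The hub criterion ranks members on their induced interaction subgraph and
    flags the ``topk`` highest.  The pathway count c3 for a gene sums, over
    significant pathways, the members of the gene's DNB neighbourhood
    ({gene} plus its first-order neighbours, restricted to DNB members and
    their neighbours) appearing in the pathway.
    """
    if not dnb.members:
        raise CoreGeneError("empty DNB member list")
    members = set(dnb.genes)
    in_network = members & network.nodes
    dropped = members - in_network
    if dropped:
        logger.info("%d DNB members absent from network", len(dropped))

    ranked = topological_rank(network, in_network, method=rank_method) if in_network else []
    topk_set = {g for g, _ in ranked[:topk]}

    dnb_and_neighbors = members | first_order_neighbors(network, members)
    sig_pathways = [tables.pathway_membership[p] for p in tables.significant_pathways()]

    out = []
    for gene in dnb.genes:
        neigh = set(network.neighbors(gene)) if gene in network.nodes else set()
        nbhd = ({gene} | neigh) & dnb_and_neighbors
        c3 = sum(len(nbhd & pw) for pw in sig_pathways)
        c5 = len(neigh & tables.deg_genes)
        out.append(
            CoreGeneScore(
                gene=gene,
                is_tf=gene in tables.tf_genes,
                in_ppi_topk=gene in topk_set,
                kegg_score=math.log1p(c3),
                is_deg=gene in tables.deg_genes,
                deg_neighbor_score=math.log1p(c5),
            )
        )
    return out


def _minmax(values: list[float]) -> list[float]:
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def composite_rank(
    scores: list[CoreGeneScore],
    weights: dict[str, float] | None = None,
    select: int = 8,
) -> list[str]:
    """Combine the five criteria into one ranking and return the top genes.

    Booleans map to {0, 1}; the two ln-count scores are min-max normalised
    across the list; the composite is the weighted sum (default weights all
    1).  Ties go to the higher kegg_score, then lexicographic order.
    """
    if not scores:
        raise CoreGeneError("no scores to rank")
    if select < 1:
        raise CoreGeneError("select must be >= 1")
    w = {"tf": 1.0, "ppi": 1.0, "kegg": 1.0, "deg": 1.0, "deg_neighbor": 1.0}
    if weights:
        unknown = set(weights) - set(w)
        if unknown:
            raise CoreGeneError(f"unknown weight keys: {sorted(unknown)}")
        w.update(weights)
    kegg_n = _minmax([s.kegg_score for s in scores])
    degn_n = _minmax([s.deg_neighbor_score for s in scores])
    composites = [
        w["tf"] * s.is_tf
        + w["ppi"] * s.in_ppi_topk
        + w["kegg"] * kegg_n[i]
        + w["deg"] * s.is_deg
        + w["deg_neighbor"] * degn_n[i]
        for i, s in enumerate(scores)
    ]
    if all(c == 0.0 for c in composites):
        logger.warning("all composite scores are zero; returning lexicographic order")
    order = sorted(
        range(len(scores)),
        key=lambda i: (-composites[i], -scores[i].kegg_score, scores[i].gene),
    )
    return [scores[i].gene for i in order[:select]]


def scores_to_frame(scores: list[CoreGeneScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene,
                "is_tf": s.is_tf,
                "in_ppi_topk": s.in_ppi_topk,
                "kegg_score": s.kegg_score,
                "is_deg": s.is_deg,
                "deg_neighbor_score": s.deg_neighbor_score,
            }
            for s in scores
        ]
    )
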
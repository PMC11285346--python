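"""Detection of coordinately spliced node blocks.

A node block is a run of consecutive splicing nodes that are included (or
excluded) together across pools of some cell type -- a node-level proxy for
an isoform switch.  Detection proceeds gene by gene:

1. *Seed and extend* (5'->3' scan): a run starts at a core-exon (CE) node
   and absorbs the next node while its mean and SD of PSI each stay within
   ``sim_tol`` (default 0.1) of the running block aggregate; a node that
   breaks the rule closes the run, and the scan re-seeds at the next CE.
2. *Enrichment*: each run of length >= 2 is tested for joint inclusion
   (all nodes above) and joint exclusion (all nodes below) separately with
   the hypergeometric cell-type test.
3. *Exon collapsing*: node ids are mapped to exon ids (several nodes can
   belong to one exon); only blocks spanning >= 3 distinct exons are
   proposed.  A block is high confidence when the joint pattern is found in
   strictly more than half of a significant cell type's pools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .ef_index import CompressedIndex
from .query import ABOVE, BELOW, PatternQuery, hyper_query_cell_types

__all__ = [
    "BlockCellType",
    "NodeBlock",
    "ExonMap",
    "read_exon_map",
    "seed_and_extend_blocks",
    "detect_blocks",
]


@dataclass(frozen=True)
class BlockCellType:
    cell_type: str
    p_value: float
    fraction_of_pools_matching: float


@dataclass
class NodeBlock:
    gene: str
    nodes: list[str]  # ordered node labels
    node_ids: list[int]
    exons: list[str]  # distinct exon ids covered, in node order
    direction: str  # "above" | "below"
    significant_cell_types: list[BlockCellType]
    high_confidence: bool


class ExonMap:
    """(gene, node_id) -> exon id; missing entries fall back to one-exon-per-node."""

    def __init__(self, mapping: dict[tuple[str, int], str] | None = None):
        self._map = dict(mapping or {})

    def exon_of(self, gene: str, node_id: int) -> str:
        return self._map.get((gene, node_id), f"{gene}:node{node_id}")

    def __len__(self) -> int:
        return len(self._map)

    def validate_against(self, index: CompressedIndex) -> None:
        known = {(n.gene, n.node_id) for n in index.nodes}
        stray = [k for k in self._map if k not in known]
        if stray:
            warnings.warn(f"{len(stray)} exon-map entries reference unknown nodes; ignored")
            for k in stray:
                del self._map[k]


def read_exon_map(path) -> ExonMap:
    """Read a node-to-exon mapping TSV with columns gene, node_id, exon_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene", "node_id", "exon_id"}.issubset(df.columns):
        raise ValueError("exon map requires columns gene, node_id, exon_id")
    return ExonMap({(r.gene, int(r.node_id)): r.exon_id for r in df.itertuples(index=False)})


def seed_and_extend_blocks(
    index: CompressedIndex,
    gene: str,
    sim_tol: float = 0.1,
    seed_node_types: tuple[str, ...] = ("CE",),
    compare_to: str = "aggregate",
) -> list[list[int]]:
    """Candidate node runs of a gene under the similarity scan rule.

    The scan walks the gene's nodes in 5'->3' id order.  A run opens at a
    node whose type is in ``seed_node_types`` and absorbs the next node iff
    its mean and SD of PSI are each within ``sim_tol`` of the current block's
    member average (``compare_to="aggregate"``, default) or of the last
    member alone (``compare_to="last"``).  Runs of length >= 2 are returned
    as lists of node indices into the index.
    """
    gene_nodes = index.genes().get(gene)
    if gene_nodes is None:
        raise KeyError(f"gene {gene!r} not in index")
    if compare_to not in ("aggregate", "last"):
        raise ValueError("compare_to must be 'aggregate' or 'last'")

    runs: list[list[int]] = []
    current: list[int] = []

    def close() -> None:
        if len(current) >= 2:
            runs.append(list(current))
        current.clear()

    for j in gene_nodes:
        st = index.stats[j]
        if current:
            if compare_to == "aggregate":
                ref_mean = sum(index.stats[i].mean_psi for i in current) / len(current)
                ref_sd = sum(index.stats[i].sd_psi for i in current) / len(current)
            else:
                ref_mean = index.stats[current[-1]].mean_psi
                ref_sd = index.stats[current[-1]].sd_psi
            if abs(st.mean_psi - ref_mean) <= sim_tol and abs(st.sd_psi - ref_sd) <= sim_tol:
                current.append(j)
                continue
            close()
        # a run can only (re)start at a seed-type node
        if index.nodes[j].node_type in seed_node_types:
            current.append(j)
    close()
    return runs


def detect_blocks(
    index: CompressedIndex,
    exon_map: ExonMap | None = None,
    alpha: float = 0.05,
    min_exons: int = 3,
    min_pool_fraction: float = 0.5,
    sim_tol: float = 0.1,
    seed_node_types: tuple[str, ...] = ("CE",),
) -> list[NodeBlock]:
    """Find cell type-specific coordinately spliced node blocks.

    Every candidate run is tested separately for joint inclusion (AND over
    all nodes above) and joint exclusion (all nodes below); runs enriched in
    at least one cell type and spanning at least ``min_exons`` distinct
    exons are reported.  High confidence requires the matching fraction to
    exceed ``min_pool_fraction`` strictly in some significant cell type.
    """
    if exon_map is None:
        exon_map = ExonMap()
        warnings.warn(
            "no node-to-exon mapping supplied; treating every node as its own exon"
        )
    else:
        exon_map.validate_against(index)

    blocks: list[NodeBlock] = []
    for gene in sorted(index.genes()):
        for run in seed_and_extend_blocks(
            index, gene, sim_tol=sim_tol, seed_node_types=seed_node_types
        ):
            labels = [index.nodes[j].label for j in run]
            node_ids = [index.nodes[j].node_id for j in run]
            exons = list(dict.fromkeys(exon_map.exon_of(gene, nid) for nid in node_ids))
            if len(exons) < min_exons:
                continue
            for direction in (ABOVE, BELOW):
                query = PatternQuery(tuple((lab, direction) for lab in labels))
                enriched = [
                    r
                    for r in hyper_query_cell_types(index, query, alpha=alpha)
                    if r.significant
                ]
                if not enriched:
                    continue
                sig = [
                    BlockCellType(
                        cell_type=r.cell_type,
                        p_value=r.p_value,
                        fraction_of_pools_matching=r.k / r.n,
                    )
                    for r in enriched
                ]
                blocks.append(
                    NodeBlock(
                        gene=gene,
                        nodes=labels,
                        node_ids=node_ids,
                        exons=exons,
                        direction=direction,
                        significant_cell_types=sig,
                        high_confidence=any(
                            s.fraction_of_pools_matching > min_pool_fraction for s in sig
                        ),
                    )
                )
    return blocks
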
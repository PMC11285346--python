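"""Synthetic PSI datasets with planted splicing patterns and recorded truth.

The generator emulates the statistical shape of pooled single-cell splicing
quantification: genes carrying ordered, numbered splicing nodes (mostly core
exons, with alternative acceptors/donors and retained introns mixed in),
cell types with a configurable number of pools, per-node baseline inclusion
drawn from a Beta so node means show the bimodality typical of alternative
exons, truncated-Gaussian pool-level noise, independent missingness, and a
read-support column in which a configurable fraction of entries falls below
the confident-quantification cutoff.

Three pattern families can be planted, with ground truth recorded:

* *markers* -- one node shifted by ``delta`` in one cell type;
* *MXE pairs* -- two adjacent nodes generated complementary
  (psi_a + psi_b ~= 1 in every pool) with the roles swapped only in the
  target cell type;
* *blocks* -- a run of consecutive core-exon nodes sharing baseline mean/SD
  (within the scan rule's tolerance) and jointly shifted in one cell type.

Entries of planted nodes are always confidently quantified: the generator
guarantees that planted truth is recoverable in principle, so that recovery
failures indicate detection defects rather than unlucky thinning.  The
missingness pathology is carried by the background nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .psi_data import (
    CellAnnotation,
    PoolAssignment,
    PsiMatrix,
    SplicingNode,
    pool_cells,
)

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "SimResult",
    "simulate_dataset",
    "write_fixture",
    "random_psi_matrix",
]


@dataclass
class SimConfig:
    """Generator parameters; defaults give a small but realistic dataset."""

    n_genes: int = 50
    nodes_per_gene: tuple[int, int] = (8, 12)  # inclusive range
    n_cell_types: int = 10
    pools_per_type: tuple[int, int] = (8, 8)  # inclusive range
    pool_size: int = 5
    baseline_beta: tuple[float, float] = (2.0, 2.0)
    noise_sd: float = 0.05
    na_rate: float = 0.05
    low_read_frac: float = 0.05  # entries drawn below the read cutoff
    read_depth_mean: float = 25.0  # Poisson mean added on top of min_reads
    min_reads: int = 10
    ce_fraction: float = 0.7  # interior nodes; first/last node are always CE
    # plants: (cell_type_index, delta, direction) etc.; resolved to labels at run time
    planted_markers: list[tuple[int, float, str]] = field(default_factory=list)
    planted_mxe: list[tuple[int, float, float]] = field(default_factory=list)  # (type, psi_high, psi_low)
    planted_blocks: list[tuple[int, int, float, str]] = field(default_factory=list)  # (type, len, delta, direction)
    seed: int = 0


@dataclass
class PlantedTruth:
    """Ground truth of planted patterns, in index-facing labels."""

    markers: list[dict] = field(default_factory=list)  # node, cell_type, direction
    mxe_pairs: list[dict] = field(default_factory=list)  # node_a, node_b, cell_type, orientation
    blocks: list[dict] = field(default_factory=list)  # gene, node_ids, cell_type, direction


@dataclass
class SimResult:
    psi_table: pd.DataFrame  # Whippet-style rows: Sample Gene Node Coord Strand Type Psi Total_Reads
    annotations: pd.DataFrame  # cell_id, cell_type
    exon_map: pd.DataFrame  # gene, node_id, exon_id
    truth: PlantedTruth
    pools: list[PoolAssignment]
    nodes: list[SplicingNode]
    true_psi: np.ndarray  # pools x nodes, pre-thinning, NaN only where never generated


def _cell_type_name(i: int) -> str:
    return f"T{i:02d}"


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate the full dataset deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_plants = len(config.planted_markers) + len(config.planted_mxe) + len(config.planted_blocks)
    if n_plants > config.n_genes:
        raise ValueError(f"{n_plants} plants exceed {config.n_genes} genes")
    for t, *_ in config.planted_markers + [(t,) for t, *_ in config.planted_mxe] + [
        (t,) for t, *_ in config.planted_blocks
    ]:
        if not 0 <= t < config.n_cell_types:
            raise ValueError(f"planted cell type index {t} out of range")

    # --- cells, pools -----------------------------------------------------
    cell_types = [_cell_type_name(i) for i in range(config.n_cell_types)]
    annotations: list[CellAnnotation] = []
    for ct in cell_types:
        n_pools_t = int(rng.integers(config.pools_per_type[0], config.pools_per_type[1] + 1))
        for c in range(n_pools_t * config.pool_size):
            annotations.append(CellAnnotation(cell_id=f"{ct}_c{c:04d}", cell_type=ct))
    pools = pool_cells(annotations, pool_size=config.pool_size, seed=config.seed)
    pool_types = np.array([p.cell_type for p in pools])
    n_pools = len(pools)

    # --- gene/node structure ---------------------------------------------
    nodes: list[SplicingNode] = []
    gene_nodes: list[list[int]] = []
    for g in range(config.n_genes):
        n_nodes = int(rng.integers(config.nodes_per_gene[0], config.nodes_per_gene[1] + 1))
        idxs = []
        pos = 1 + 100_000 * g
        for i in range(n_nodes):
            if i == 0 or i == n_nodes - 1:
                ntype = "CE"
            else:
                ntype = "CE" if rng.random() < config.ce_fraction else str(
                    rng.choice(["AA", "AD", "RI"])
                )
            length = int(rng.integers(80, 300))
            idxs.append(len(nodes))
            nodes.append(
                SplicingNode(
                    gene=f"G{g:03d}",
                    node_id=i + 1,
                    chrom=f"chr{g % 5 + 1}",
                    start=pos,
                    end=pos + length,
                    strand="+" if g % 2 == 0 else "-",
                    node_type=ntype,
                )
            )
            pos += length + int(rng.integers(500, 2000))
        gene_nodes.append(idxs)
    n_nodes_total = len(nodes)

    baseline = np.clip(
        rng.beta(config.baseline_beta[0], config.baseline_beta[1], size=n_nodes_total),
        0.05,
        0.95,
    )

    # --- plant patterns ---------------------------------------------------
    truth = PlantedTruth()
    shift = np.zeros((config.n_cell_types, n_nodes_total))  # additive shift per (type, node)
    mxe_partner: dict[int, tuple[int, int, float, float]] = {}  # a-> (b, type, hi, lo)
    protected = np.zeros(n_nodes_total, dtype=bool)  # exempt from thinning
    next_gene = 0

    def _force_ce(j: int) -> None:
        if nodes[j].node_type != "CE":
            nodes[j] = SplicingNode(
                gene=nodes[j].gene, node_id=nodes[j].node_id, chrom=nodes[j].chrom,
                start=nodes[j].start, end=nodes[j].end, strand=nodes[j].strand,
                node_type="CE",
            )

    for t_idx, delta, direction in config.planted_markers:
        idxs = gene_nodes[next_gene]
        j = idxs[len(idxs) // 2]
        _force_ce(j)
        sgn = 1.0 if direction == "inclusion" else -1.0
        baseline[j] = 0.5 - sgn * delta / 2
        shift[t_idx, j] = sgn * delta
        protected[j] = True
        truth.markers.append(
            {"node": nodes[j].label, "cell_type": cell_types[t_idx], "direction": direction}
        )
        next_gene += 1

    for t_idx, psi_high, psi_low in config.planted_mxe:
        if not psi_high - psi_low >= 0.5:
            raise ValueError("planted MXE needs psi_high - psi_low >= 0.5")
        idxs = gene_nodes[next_gene]
        if len(idxs) < 2:
            raise ValueError("gene too short for an MXE pair")
        mid = len(idxs) // 2 - 1
        a, b = idxs[mid], idxs[mid + 1]
        _force_ce(a)
        _force_ce(b)
        baseline[a] = baseline[b] = 0.5
        mxe_partner[a] = (b, t_idx, psi_high, psi_low)
        protected[a] = protected[b] = True
        truth.mxe_pairs.append(
            {
                "node_a": nodes[a].label,
                "node_b": nodes[b].label,
                "cell_type": cell_types[t_idx],
                "orientation": "a_in_b_out",
            }
        )
        next_gene += 1

    for t_idx, block_len, delta, direction in config.planted_blocks:
        idxs = gene_nodes[next_gene]
        if block_len + 2 > len(idxs):
            raise ValueError(
                f"planted block of {block_len} nodes does not fit a gene of {len(idxs)} nodes"
            )
        start = (len(idxs) - block_len) // 2
        run = idxs[start : start + block_len]
        sgn = 1.0 if direction == "above" else -1.0
        block_base = 0.5 - sgn * delta / 2
        for j in run:
            _force_ce(j)
            baseline[j] = block_base
            shift[t_idx, j] = sgn * delta
            protected[j] = True
        # flanking nodes must break the similarity scan at the block edges
        for j in (idxs[start - 1], idxs[start + block_len]) if start > 0 else (idxs[start + block_len],):
            far = block_base + 0.3 if block_base <= 0.5 else block_base - 0.3
            baseline[j] = np.clip(far, 0.05, 0.95)
        truth.blocks.append(
            {
                "gene": nodes[run[0]].gene,
                "node_ids": [nodes[j].node_id for j in run],
                "cell_type": cell_types[t_idx],
                "direction": direction,
            }
        )
        next_gene += 1

    # --- pool-level PSI ---------------------------------------------------
    type_index = {ct: i for i, ct in enumerate(cell_types)}
    pool_t = np.array([type_index[t] for t in pool_types])

    psi = np.clip(
        baseline[None, :]
        + shift[pool_t, :]
        + rng.normal(0.0, config.noise_sd, size=(n_pools, n_nodes_total)),
        0.0,
        1.0,
    )
    # complementary MXE partners: psi_b tracks 1 - psi_a with small jitter
    for a, (b, t_idx, psi_high, psi_low) in mxe_partner.items():
        base_a = np.where(pool_t == t_idx, psi_high, 0.5)
        psi[:, a] = np.clip(base_a + rng.normal(0.0, config.noise_sd, n_pools), 0.0, 1.0)
        psi[:, b] = np.clip(1.0 - psi[:, a] + rng.normal(0.0, 0.01, n_pools), 0.0, 1.0)

    # planted MXE pairs must satisfy the candidate screen by construction
    for a, (b, *_rest) in mxe_partner.items():
        mean_sum = psi[:, a].mean() + psi[:, b].mean()
        sd_diff = abs(psi[:, a].std() - psi[:, b].std())
        assert 0.9 <= mean_sum <= 1.1 and sd_diff < 0.1, "planted MXE violates candidate filters"

    # --- thinning: missingness and read support --------------------------
    na = (rng.random((n_pools, n_nodes_total)) < config.na_rate) & ~protected[None, :]
    low = (rng.random((n_pools, n_nodes_total)) < config.low_read_frac) & ~protected[None, :]
    reads = config.min_reads + rng.poisson(config.read_depth_mean, size=(n_pools, n_nodes_total))
    reads[low] = rng.integers(0, config.min_reads, size=int(low.sum()))
    reads[na] = rng.poisson(2.0, size=int(na.sum()))

    # --- tables -----------------------------------------------------------
    pool_ids = [p.pool_id for p in pools]
    rows = {
        "Sample": np.repeat(pool_ids, n_nodes_total),
        "Gene": np.tile([n.gene for n in nodes], n_pools),
        "Node": np.tile([n.node_id for n in nodes], n_pools),
        "Coord": np.tile([f"{n.chrom}:{n.start}-{n.end}" for n in nodes], n_pools),
        "Strand": np.tile([n.strand for n in nodes], n_pools),
        "Type": np.tile([n.node_type for n in nodes], n_pools),
        "Psi": np.where(na.ravel(), "NA", np.char.mod("%.4f", psi.ravel())),
        "Total_Reads": reads.ravel(),
    }
    psi_table = pd.DataFrame(rows)

    annotations_df = pd.DataFrame(
        {"cell_id": [a.cell_id for a in annotations], "cell_type": [a.cell_type for a in annotations]}
    )
    exon_map = pd.DataFrame(
        {
            "gene": [n.gene for n in nodes],
            "node_id": [n.node_id for n in nodes],
            "exon_id": [f"{n.chrom}:{n.start}-{n.end}" for n in nodes],
        }
    )
    true_psi = psi.copy()
    true_psi[na] = np.nan
    return SimResult(
        psi_table=psi_table,
        annotations=annotations_df,
        exon_map=exon_map,
        truth=truth,
        pools=pools,
        nodes=nodes,
        true_psi=true_psi,
    )


def write_fixture(result: SimResult, outdir) -> dict[str, Path]:
    """Write the dataset as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "psi": outdir / "psi.tsv",
        "annotations": outdir / "cells.tsv",
        "exon_map": outdir / "exon_map.tsv",
        "truth": outdir / "truth.json",
    }
    result.psi_table.to_csv(paths["psi"], sep="\t", index=False)
    result.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    result.exon_map.to_csv(paths["exon_map"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(asdict(result.truth), indent=1) + "\n")
    return paths


def index_from_simulation(result: SimResult, min_reads: int = 10, tau: float = 0.2, bits: int = 2):
    """Run the simulated table through the standard ingest path and build an index."""
    from .ef_index import build_index
    from .psi_data import PsiRecord, assemble_psi_matrix

    node_lookup = {(n.gene, n.node_id): n for n in result.nodes}
    t = result.psi_table
    records = [
        PsiRecord(
            node=node_lookup[(gene, int(node_id))],
            pool_id=sample,
            psi=None if psi == "NA" else float(psi),
            total_reads=int(reads),
        )
        for sample, gene, node_id, psi, reads in zip(
            t["Sample"], t["Gene"], t["Node"], t["Psi"], t["Total_Reads"]
        )
    ]
    matrix, _ = assemble_psi_matrix(records, result.pools, min_reads=min_reads)
    return build_index(matrix, tau=tau, bits=bits, min_reads=min_reads)


def random_psi_matrix(
    n_pools: int,
    n_nodes: int,
    n_cell_types: int = 4,
    na_rate: float = 0.2,
    rng: np.random.Generator | None = None,
) -> PsiMatrix:
    """A quick unstructured PSI matrix for codec/query stress tests."""
    rng = rng or np.random.default_rng(0)
    values = rng.random((n_pools, n_nodes))
    values[rng.random((n_pools, n_nodes)) < na_rate] = np.nan
    # every node keeps at least one quantified pool
    for j in np.flatnonzero(np.all(np.isnan(values), axis=0)):
        values[int(rng.integers(n_pools)), j] = rng.random()
    pools = [
        PoolAssignment(
            pool_id=f"p{i:03d}",
            cell_type=_cell_type_name(i % n_cell_types),
            member_cells=frozenset({f"p{i:03d}_cell"}),
            pool_size_param=1,
        )
        for i in range(n_pools)
    ]
    nodes = [
        SplicingNode(gene=f"G{j // 10:03d}", node_id=j % 10 + 1, start=1, end=2)
        for j in range(n_nodes)
    ]
    return PsiMatrix(pools=pools, nodes=nodes, values=values)
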
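"""Ingest of node-level PSI tables and cell annotations into a pool x node matrix.

Splicing quantifiers such as Whippet report, per sample, a percent-spliced-in
(PSI) value for every *splicing node* -- a non-overlapping exonic region of a
gene, numbered 5'->3'.  Single cells rarely yield enough junction-spanning
reads to quantify a node, so same-cell-type cells are combined into small
*pools* (default 5 cells) before quantification.  This module reads the
per-pool PSI tables, applies the confident-quantification read filter
(default: at least 10 reads) and assembles the pools x nodes PSI matrix that
the index is built from.
"""

from __future__ import annotations

import gzip
import io
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SplicingNode",
    "CellAnnotation",
    "PoolAssignment",
    "PsiRecord",
    "PsiMatrix",
    "PsiParseError",
    "read_psi_table",
    "read_annotations",
    "pool_cells",
    "read_pools",
    "write_pools",
    "assemble_psi_matrix",
    "save_matrix",
    "load_matrix",
]

NODE_TYPES = ("CE", "AA", "AD", "RI", "other")

_COORD_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


class PsiParseError(ValueError):
    """Raised when a PSI table row cannot be parsed or violates an invariant."""


@dataclass(frozen=True)
class SplicingNode:
    """One annotated splicing unit of a gene.

    ``node_id`` is the 5'->3' ordinal of the node within its gene, as
    assigned by the upstream quantifier's annotation.  Coordinates are
    1-based inclusive genomic positions, used only for reporting and for
    node-to-exon mapping.
    """

    gene: str
    node_id: int
    chrom: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    node_type: str = "CE"

    def __post_init__(self) -> None:
        if self.node_id < 1:
            raise PsiParseError(f"node_id must be a positive ordinal, got {self.node_id}")
        if self.start > self.end:
            raise PsiParseError(
                f"node {self.gene}_{self.node_id}: start {self.start} > end {self.end}"
            )

    @property
    def label(self) -> str:
        """Node label in the conventional ``<gene>_<node_id>`` form (e.g. Gria2_28)."""
        return f"{self.gene}_{self.node_id}"


@dataclass(frozen=True)
class CellAnnotation:
    cell_id: str
    cell_type: str


@dataclass
class PoolAssignment:
    """A pool of same-cell-type cells; pools partition the annotated cells."""

    pool_id: str
    cell_type: str
    member_cells: frozenset[str]
    pool_size_param: int

    def __post_init__(self) -> None:
        if len(self.member_cells) > self.pool_size_param:
            raise ValueError(
                f"pool {self.pool_id}: {len(self.member_cells)} members exceed "
                f"pool size parameter {self.pool_size_param}"
            )


@dataclass(frozen=True)
class PsiRecord:
    """PSI of one node in one pool; ``psi is None`` means unquantified."""

    node: SplicingNode
    pool_id: str
    psi: float | None
    total_reads: int

    def __post_init__(self) -> None:
        if self.psi is not None and not (0.0 <= self.psi <= 1.0):
            raise PsiParseError(
                f"PSI {self.psi} outside [0, 1] for {self.node.label} / {self.pool_id}"
            )
        if self.total_reads < 0:
            raise PsiParseError(f"negative read count for {self.node.label}")


@dataclass
class PsiMatrix:
    """Pools x nodes PSI matrix with explicit missingness (NaN).

    ``values[i, j]`` is the PSI of ``nodes[j]`` in ``pools[i]``; entries that
    were unquantified or failed the read filter are NaN.
    """

    pools: list[PoolAssignment]
    nodes: list[SplicingNode]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.pools), len(self.nodes)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.pools)} pools x {len(self.nodes)} nodes"
            )
        present = self.values[~np.isnan(self.values)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValueError("PSI values outside [0, 1]")

    @property
    def pool_ids(self) -> list[str]:
        return [p.pool_id for p in self.pools]

    @property
    def cell_types(self) -> list[str]:
        return [p.cell_type for p in self.pools]

    @property
    def node_labels(self) -> list[str]:
        return [n.label for n in self.nodes]


def _parse_coord(coord: str, line_no: int | None = None) -> tuple[str, int, int]:
    m = _COORD_RE.match(coord)
    where = "" if line_no is None else f" (line {line_no})"
    if not m:
        raise PsiParseError(f"malformed coordinate string {coord!r}{where}")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start > end:
        raise PsiParseError(f"coordinate start > end in {coord!r}{where}")
    return chrom, start, end


_REQUIRED_COLUMNS = ("Gene", "Node", "Coord", "Strand", "Type", "Psi", "Total_Reads")


def read_psi_table(path, sample: str | None = None) -> list[PsiRecord]:
    """Read a Whippet-style node PSI table (TSV, plain or gzip).

    Requires columns Gene, Node, Coord ("chr:start-end"), Strand, Type, Psi
    and Total_Reads; extra columns are ignored.  A "Sample" column, when
    present, supplies the pool id of each row; otherwise every row is
    attributed to ``sample`` (Whippet writes one table per sample).
    "NA" or empty Psi is parsed as unquantified.
    """
    opener = gzip.open if str(path).endswith(".gz") else io.open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PsiParseError(f"PSI table {path} lacks required columns: {missing}")
    has_sample = "Sample" in df.columns

    records: list[PsiRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        chrom, start, end = _parse_coord(str(row["Coord"]), line_no=i)
        node_type = str(row["Type"])
        node = SplicingNode(
            gene=str(row["Gene"]),
            node_id=int(row["Node"]),
            chrom=chrom,
            start=start,
            end=end,
            strand=str(row["Strand"]),
            node_type=node_type if node_type in NODE_TYPES else "other",
        )
        raw_psi = row["Psi"]
        psi = None if raw_psi is None or pd.isna(raw_psi) or str(raw_psi).upper() == "NA" or str(raw_psi) == "" else float(raw_psi)
        pool_id = str(row["Sample"]) if has_sample else (sample if sample is not None else "")
        records.append(
            PsiRecord(node=node, pool_id=pool_id, psi=psi, total_reads=int(float(row["Total_Reads"])))
        )
    return records


def read_annotations(path) -> list[CellAnnotation]:
    """Read a two-column TSV of ``cell_id`` and ``cell_type``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"cell_id", "cell_type"}.issubset(df.columns):
        raise PsiParseError("annotation table requires columns cell_id, cell_type")
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise PsiParseError(f"duplicate cell ids in annotation: {dups[:5]}")
    return [CellAnnotation(r.cell_id, r.cell_type) for r in df.itertuples(index=False)]


def pool_cells(
    annotations: list[CellAnnotation], pool_size: int = 5, seed: int = 0
) -> list[PoolAssignment]:
    """Partition cells into same-cell-type pools of at most ``pool_size`` cells.

    Within each cell type, cells are shuffled with a seeded RNG and chopped
    into consecutive groups; a non-empty remainder becomes its own smaller
    pool so that rare cell types are never silently discarded.  Deterministic
    for a fixed seed.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    rng = np.random.default_rng(seed)
    by_type: dict[str, list[str]] = {}
    for ann in annotations:
        by_type.setdefault(ann.cell_type, []).append(ann.cell_id)

    pools: list[PoolAssignment] = []
    for cell_type in sorted(by_type):
        cells = sorted(by_type[cell_type])
        if not cells:  # pragma: no cover - empty lists never enter by_type
            warnings.warn(f"cell type {cell_type!r} has no cells; excluded")
            continue
        order = rng.permutation(len(cells))
        shuffled = [cells[i] for i in order]
        for k, lo in enumerate(range(0, len(shuffled), pool_size)):
            members = shuffled[lo : lo + pool_size]
            pools.append(
                PoolAssignment(
                    pool_id=f"{cell_type}.p{k}",
                    cell_type=cell_type,
                    member_cells=frozenset(members),
                    pool_size_param=pool_size,
                )
            )
    return pools


def write_pools(pools: list[PoolAssignment], path, header_lines: list[str] | None = None) -> None:
    """Write pools as TSV: pool_id, cell_type, comma-joined member cells."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("pool_id\tcell_type\tcells\tpool_size_param\n")
        for p in pools:
            cells = ",".join(sorted(p.member_cells))
            fh.write(f"{p.pool_id}\t{p.cell_type}\t{cells}\t{p.pool_size_param}\n")


def read_pools(path) -> list[PoolAssignment]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [
        PoolAssignment(
            pool_id=r.pool_id,
            cell_type=r.cell_type,
            member_cells=frozenset(str(r.cells).split(",")),
            pool_size_param=int(r.pool_size_param),
        )
        for r in df.itertuples(index=False)
    ]


def assemble_psi_matrix(
    records: list[PsiRecord],
    pools: list[PoolAssignment],
    min_reads: int = 10,
) -> tuple[PsiMatrix, list[SplicingNode]]:
    """Assemble the pools x nodes PSI matrix, applying the read-support filter.

    An entry is present iff its PSI is quantified AND its read support is at
    least ``min_reads`` (inclusive boundary).  Nodes left with no present
    entry are dropped and returned alongside the matrix.  Duplicate
    (node, pool) rows indicate a corrupted upstream merge and are an error.

    Returns ``(matrix, dropped_nodes)``.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    pool_index = {p.pool_id: i for i, p in enumerate(pools)}

    nodes: list[SplicingNode] = []
    node_index: dict[tuple[str, int], int] = {}
    for rec in records:
        key = (rec.node.gene, rec.node.node_id)
        if key not in node_index:
            node_index[key] = len(nodes)
            nodes.append(rec.node)
    # stable node order: gene, then 5'->3' ordinal
    order = sorted(range(len(nodes)), key=lambda j: (nodes[j].gene, nodes[j].node_id))
    nodes = [nodes[j] for j in order]
    node_index = {(n.gene, n.node_id): j for j, n in enumerate(nodes)}

    values = np.full((len(pools), len(nodes)), np.nan)
    seen: set[tuple[str, int, str]] = set()
    duplicates: list[tuple[str, str]] = []
    for rec in records:
        if rec.pool_id not in pool_index:
            continue  # pools not in the assignment (e.g. filtered cell types)
        key = (rec.node.gene, rec.node.node_id, rec.pool_id)
        if key in seen:
            duplicates.append((rec.node.label, rec.pool_id))
            continue
        seen.add(key)
        if rec.psi is not None and rec.total_reads >= min_reads:
            values[pool_index[rec.pool_id], node_index[(rec.node.gene, rec.node.node_id)]] = rec.psi
    if duplicates:
        raise PsiParseError(f"duplicate (node, pool) rows: {duplicates[:10]}")

    keep = ~np.all(np.isnan(values), axis=0)
    dropped = [n for n, k in zip(nodes, keep) if not k]
    if dropped:
        warnings.warn(
            f"{len(dropped)} node(s) had no confidently quantified entry and were dropped"
        )
    matrix = PsiMatrix(
        pools=list(pools),
        nodes=[n for n, k in zip(nodes, keep) if k],
        values=values[:, keep],
    )
    return matrix, dropped


def save_matrix(matrix: PsiMatrix, path) -> None:
    """Store a PSI matrix (values + pool and node metadata) in one HDF5 file."""
    import h5py

    str_dt = h5py.string_dtype("utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=matrix.values, compression="gzip")
        g = f.create_group("pools")
        g.create_dataset("pool_id", data=matrix.pool_ids, dtype=str_dt)
        g.create_dataset("cell_type", data=matrix.cell_types, dtype=str_dt)
        g.create_dataset(
            "members",
            data=[",".join(sorted(p.member_cells)) for p in matrix.pools],
            dtype=str_dt,
        )
        g.create_dataset("pool_size_param", data=[p.pool_size_param for p in matrix.pools])
        g = f.create_group("nodes")
        for name, data, dt in (
            ("gene", [n.gene for n in matrix.nodes], str_dt),
            ("node_id", [n.node_id for n in matrix.nodes], np.int64),
            ("chrom", [n.chrom for n in matrix.nodes], str_dt),
            ("start", [n.start for n in matrix.nodes], np.int64),
            ("end", [n.end for n in matrix.nodes], np.int64),
            ("strand", [n.strand for n in matrix.nodes], str_dt),
            ("node_type", [n.node_type for n in matrix.nodes], str_dt),
        ):
            g.create_dataset(name, data=data, dtype=dt)


def load_matrix(path) -> PsiMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        values = f["values"][()]
        g = f["pools"]
        pools = [
            PoolAssignment(
                pool_id=pid.decode(),
                cell_type=ct.decode(),
                member_cells=frozenset(mem.decode().split(",")) if mem else frozenset(),
                pool_size_param=int(sz),
            )
            for pid, ct, mem, sz in zip(
                g["pool_id"][()], g["cell_type"][()], g["members"][()], g["pool_size_param"][()]
            )
        ]
        g = f["nodes"]
        nodes = [
            SplicingNode(
                gene=gene.decode(), node_id=int(nid), chrom=chrom.decode(),
                start=int(s), end=int(e), strand=strand.decode(), node_type=nt.decode(),
            )
            for gene, nid, chrom, s, e, strand, nt in zip(
                g["gene"][()], g["node_id"][()], g["chrom"][()], g["start"][()],
                g["end"][()], g["strand"][()], g["node_type"][()],
            )
        ]
    return PsiMatrix(pools=pools, nodes=nodes, values=values)
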
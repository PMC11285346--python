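"""The two-sided compressed differential-PSI index.

The index stores, for every splicing node, which cell pools deviate from the
node's dataset-wide mean PSI and by how much.  Four structures are kept:

1. *Above/below position sets.*  Per node, the pools whose PSI exceeds the
   mean by more than ``tau`` ("above", differential inclusion) or falls more
   than ``tau`` below it ("below", differential exclusion).  Pool positions
   are monotone integer sequences and are stored with the Elias-Fano succinct
   encoding -- exactly lossless.
2. *Quantized deviation magnitudes.*  The per-pool deviation |dPSI|, scaled
   to (0, 100], is stored as a b-bit quantile code of a log-normal fitted to
   the node-side's values (default 2 bits) -- lossy, with the bin medians
   kept as representatives for reconstruction.
3. *Per-node mean and SD* of PSI over quantified pools.
4. *NA mask.*  Pools that were quantified but near the mean, as opposed to
   unquantified: required to reconstruct approximate PSI values.

The deviation threshold ``tau`` defaults to 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .psi_data import PoolAssignment, PsiMatrix, SplicingNode

__all__ = [
    "EliasFano",
    "ef_encode",
    "ef_decode",
    "quantize_values",
    "dequantize",
    "NodeStats",
    "EncodedNodeSide",
    "CompressedIndex",
    "center_and_split",
    "build_index",
    "save_index",
    "load_index",
]

FORMAT_VERSION = "spliceindex-1"


# ---------------------------------------------------------------------------
# Elias-Fano position codec (lossless)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EliasFano:
    """A monotone integer sequence in Elias-Fano form.

    The sequence of ``m`` strictly increasing positions in ``[0, universe)``
    is split into low and high bit halves: each position keeps its
    ``l = max(0, floor(log2(U/m)))`` low bits verbatim (concatenated,
    LSB-first), while the high parts are stored as a unary-coded sequence of
    gaps.  Both halves are packed into one byte payload, low half first,
    each padded to a byte boundary.
    """

    m: int
    universe: int
    payload: bytes

    @property
    def low_bits(self) -> int:
        return _low_bits(self.m, self.universe)

    def bit_length(self) -> int:
        """Exact number of meaningful bits (before byte padding)."""
        if self.m == 0:
            return 0
        high = ef_decode(self)[-1] >> self.low_bits
        return self.m * self.low_bits + self.m + int(high)


def _low_bits(m: int, universe: int) -> int:
    if m == 0:
        return 0
    # floor(log2(U/m)) == floor(log2(U // m)) for U >= m >= 1
    q = universe // m
    return max(0, q.bit_length() - 1) if q >= 1 else 0


def ef_encode(positions, universe: int) -> EliasFano:
    """Encode strictly increasing integer positions < ``universe``."""
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size == 0:
        return EliasFano(m=0, universe=int(universe), payload=b"")
    if pos.min() < 0 or pos.max() >= universe:
        raise ValueError(f"positions outside [0, {universe})")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")

    m = int(pos.size)
    l = _low_bits(m, universe)

    if l > 0:
        low = pos & ((1 << l) - 1)
        # bit i*l + j of the low stream is bit j of low[i]
        bits = ((low[:, None] >> np.arange(l)) & 1).astype(np.uint8).ravel()
        low_bytes = np.packbits(bits, bitorder="little").tobytes()
    else:
        low_bytes = b""

    high = pos >> l
    n_high_bits = m + int(high[-1])
    high_stream = np.zeros(n_high_bits, dtype=np.uint8)
    high_stream[high + np.arange(m)] = 1
    high_bytes = np.packbits(high_stream, bitorder="little").tobytes()

    return EliasFano(m=m, universe=int(universe), payload=low_bytes + high_bytes)


def ef_decode(ef: EliasFano) -> np.ndarray:
    """Decode back to the exact original positions."""
    if ef.m == 0:
        return np.zeros(0, dtype=np.int64)
    m, l = ef.m, ef.low_bits
    n_low_bytes = (m * l + 7) // 8
    buf = np.frombuffer(ef.payload, dtype=np.uint8)
    if buf.size < n_low_bytes + 1:
        raise ValueError("truncated Elias-Fano stream")

    if l > 0:
        low_bits = np.unpackbits(buf[:n_low_bytes], bitorder="little")[: m * l]
        low = low_bits.reshape(m, l).astype(np.int64) @ (1 << np.arange(l, dtype=np.int64))
    else:
        low = np.zeros(m, dtype=np.int64)

    high_bits = np.unpackbits(buf[n_low_bytes:], bitorder="little")
    ones = np.flatnonzero(high_bits)
    if ones.size < m:
        raise ValueError("truncated Elias-Fano stream: missing unary terminators")
    high = ones[:m] - np.arange(m)

    pos = (high << l) | low
    if pos.max() >= ef.universe or np.any(np.diff(pos) <= 0):
        raise ValueError("corrupt Elias-Fano stream")
    return pos


# ---------------------------------------------------------------------------
# Lossy value quantization (log-normal quantile bins)
# ---------------------------------------------------------------------------

def quantize_values(values, bits: int = 2):
    """Quantize positive deviation magnitudes into ``2**bits`` quantile bins.

    A log-normal is fitted by moments of ``ln(values)``; the fitted
    distribution's quantiles at k/2^bits (k = 1 .. 2^bits - 1) are the bin
    cut points.  A value's bin index is the number of cut points <= value.
    Each bin's representative is the median of the original values in it; an
    empty bin falls back to the fitted distribution's median of its quantile
    band, so dequantization is total.

    Returns ``(bin_indices, log_mu, log_sigma, bin_reps)``.
    """
    if not 1 <= bits <= 8:
        raise ValueError("bits must be in [1, 8]")
    vals = np.asarray(values, dtype=np.float64)
    if vals.size == 0:
        return np.zeros(0, dtype=np.uint8), 0.0, 0.0, np.zeros(2**bits)
    if vals.min() <= 0:
        raise ValueError("quantizer requires strictly positive values")

    logs = np.log(vals)
    log_mu = float(logs.mean())
    log_sigma = float(logs.std())  # population SD; 0 allowed for constants

    n_bins = 2**bits
    qs = np.arange(1, n_bins) / n_bins
    cuts = _lognorm_ppf(qs, log_mu, log_sigma)
    idx = np.searchsorted(cuts, vals, side="right").astype(np.uint8)

    reps = np.empty(n_bins)
    band_edges = np.arange(n_bins + 1) / n_bins  # quantile bands [k/2^b, (k+1)/2^b]
    for k in range(n_bins):
        in_bin = vals[idx == k]
        if in_bin.size:
            reps[k] = float(np.median(in_bin))
        else:
            reps[k] = _lognorm_ppf((band_edges[k] + band_edges[k + 1]) / 2, log_mu, log_sigma)
    reps = np.maximum.accumulate(reps)  # guard monotonicity under empty-bin fallbacks
    return idx, log_mu, log_sigma, reps


def _lognorm_ppf(q, mu: float, sigma: float):
    from scipy.special import ndtri

    if sigma == 0.0:
        return np.exp(mu) * np.ones_like(np.asarray(q, dtype=float))
    return np.exp(mu + sigma * ndtri(q))


def dequantize(bin_indices, bin_reps) -> np.ndarray:
    return np.asarray(bin_reps, dtype=np.float64)[np.asarray(bin_indices, dtype=np.int64)]


# ---------------------------------------------------------------------------
# Index structures
# ---------------------------------------------------------------------------

@dataclass
class NodeStats:
    """Mean/SD of PSI over the quantified pools of one node."""

    mean_psi: float
    sd_psi: float
    n_quantified: int


@dataclass
class EncodedNodeSide:
    """One side (above or below) of one node's encoded deviations."""

    side: str  # "above" | "below"
    ef: EliasFano
    value_bins: np.ndarray  # b-bit bin index per position
    log_mu: float
    log_sigma: float
    bin_reps: np.ndarray  # 2^bits representatives, non-decreasing
    _positions: np.ndarray | None = field(default=None, repr=False)

    @property
    def positions(self) -> np.ndarray:
        if self._positions is None:
            object.__setattr__(self, "_positions", ef_decode(self.ef))
        return self._positions

    @property
    def values(self) -> np.ndarray:
        """Dequantized deviation magnitudes on the 0-100 scale."""
        return dequantize(self.value_bins, self.bin_reps)


@dataclass
class CompressedIndex:
    """The queryable artifact: compressed two-sided dPSI index + metadata."""

    pools: list[PoolAssignment]
    nodes: list[SplicingNode]
    stats: list[NodeStats]
    above: list[EncodedNodeSide]
    below: list[EncodedNodeSide]
    mask: list[EliasFano]  # quantified-but-near-mean pool positions per node
    tau: float = 0.2
    bits: int = 2
    min_reads: int = 10

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if not (len(self.stats) == len(self.above) == len(self.below) == len(self.mask) == n):
            raise ValueError("per-node structure lengths inconsistent")
        self._node_lookup = {node.label: j for j, node in enumerate(self.nodes)}
        self._mask_cache: dict[int, np.ndarray] = {}

    # -- lookups ----------------------------------------------------------
    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def pool_ids(self) -> list[str]:
        return [p.pool_id for p in self.pools]

    @property
    def cell_types(self) -> list[str]:
        return [p.cell_type for p in self.pools]

    def node_index(self, node) -> int:
        """Resolve a node given as label, (gene, node_id) pair or SplicingNode."""
        if isinstance(node, SplicingNode):
            node = node.label
        elif isinstance(node, tuple):
            node = f"{node[0]}_{node[1]}"
        try:
            return self._node_lookup[node]
        except KeyError:
            raise KeyError(f"node {node!r} not in index") from None

    def mask_positions(self, j: int) -> np.ndarray:
        if j not in self._mask_cache:
            self._mask_cache[j] = ef_decode(self.mask[j])
        return self._mask_cache[j]

    def genes(self) -> dict[str, list[int]]:
        """Gene -> node indices, each list in 5'->3' node-id order."""
        out: dict[str, list[int]] = {}
        for j, node in enumerate(self.nodes):
            out.setdefault(node.gene, []).append(j)
        for gene, idxs in out.items():
            idxs.sort(key=lambda j: self.nodes[j].node_id)
        return out

    def encoded_node_count(self) -> int:
        """Nodes with a deviation encoded on at least one side."""
        return sum(
            1 for a, b in zip(self.above, self.below) if a.ef.m > 0 or b.ef.m > 0
        )


# ---------------------------------------------------------------------------
# Build
# ---------------------------------------------------------------------------

def center_and_split(matrix: PsiMatrix, tau: float = 0.2):
    """Per node: mean-center PSI and split pools into above / below / mask.

    dPSI = psi - mean_psi per quantified pool.  Pools with dPSI > tau go to
    the "above" side with value 100*dPSI, pools with dPSI < -tau to "below"
    with value 100*|dPSI|; the rest (|dPSI| <= tau, ties at the threshold
    included) form the near-mean mask.  Nodes whose column is all-missing
    are dropped with a warning.

    Returns parallel lists ``(kept_node_indices, stats, above_pos, above_val,
    below_pos, below_val, mask_pos)``.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    values = matrix.values
    kept: list[int] = []
    stats: list[NodeStats] = []
    above_pos: list[np.ndarray] = []
    above_val: list[np.ndarray] = []
    below_pos: list[np.ndarray] = []
    below_val: list[np.ndarray] = []
    mask_pos: list[np.ndarray] = []

    for j in range(values.shape[1]):
        col = values[:, j]
        quant = np.flatnonzero(~np.isnan(col))
        if quant.size == 0:
            warnings.warn(f"node {matrix.nodes[j].label} has no quantified pool; dropped")
            continue
        psi = col[quant]
        mean = float(psi.mean())
        sd = float(psi.std())
        dpsi = psi - mean
        up = dpsi > tau
        down = dpsi < -tau
        near = ~(up | down)
        kept.append(j)
        stats.append(NodeStats(mean_psi=mean, sd_psi=sd, n_quantified=int(quant.size)))
        above_pos.append(quant[up])
        above_val.append(100.0 * dpsi[up])
        below_pos.append(quant[down])
        below_val.append(100.0 * -dpsi[down])
        mask_pos.append(quant[near])

    return kept, stats, above_pos, above_val, below_pos, below_val, mask_pos


def _encode_side(side: str, positions, values100, n_pools: int, bits: int) -> EncodedNodeSide:
    if len(positions) == 0:
        bins = np.zeros(0, dtype=np.uint8)
        log_mu = log_sigma = 0.0
        reps = np.zeros(2**bits)
    else:
        bins, log_mu, log_sigma, reps = quantize_values(values100, bits=bits)
    return EncodedNodeSide(
        side=side,
        ef=ef_encode(positions, n_pools),
        value_bins=bins,
        log_mu=log_mu,
        log_sigma=log_sigma,
        bin_reps=reps,
        _positions=np.asarray(positions, dtype=np.int64),
    )


def build_index(
    matrix: PsiMatrix, tau: float = 0.2, bits: int = 2, min_reads: int = 10
) -> CompressedIndex:
    """Build the compressed two-sided index from a PSI matrix.

    A pure function of ``(matrix, tau, bits)``.  Nodes with no deviating pool
    are retained with stats and mask only (their sides stay empty).
    ``min_reads`` is recorded as provenance of the matrix filter.
    """
    kept, stats, apos, aval, bpos, bval, mpos = center_and_split(matrix, tau=tau)
    n_pools = len(matrix.pools)
    above = [_encode_side("above", p, v, n_pools, bits) for p, v in zip(apos, aval)]
    below = [_encode_side("below", p, v, n_pools, bits) for p, v in zip(bpos, bval)]
    mask = [ef_encode(p, n_pools) for p in mpos]
    return CompressedIndex(
        pools=list(matrix.pools),
        nodes=[matrix.nodes[j] for j in kept],
        stats=stats,
        above=above,
        below=below,
        mask=mask,
        tau=tau,
        bits=bits,
        min_reads=min_reads,
    )


# ---------------------------------------------------------------------------
# Serialization (single HDF5 container)
# ---------------------------------------------------------------------------
# All per-node byte payloads are concatenated into flat arrays with offset
# tables: thousands of tiny HDF5 datasets would cost more in metadata than
# the payloads themselves.

def _concat_payloads(items: list[bytes]):
    offsets = np.zeros(len(items) + 1, dtype=np.int64)
    for i, b in enumerate(items):
        offsets[i + 1] = offsets[i] + len(b)
    payload = b"".join(items)
    return np.frombuffer(payload, dtype=np.uint8), offsets


def _pack_bins(sides: list[EncodedNodeSide], bits: int) -> np.ndarray:
    """Pack all nodes' b-bit bin indices into one little-endian bitstream.

    Per-node counts equal the Elias-Fano m of the side (one value per
    position), so no separate count table is stored.
    """
    all_bits = [
        ((s.value_bins[:, None] >> np.arange(bits)) & 1).astype(np.uint8).ravel()
        for s in sides
        if s.value_bins.size
    ]
    if all_bits:
        return np.packbits(np.concatenate(all_bits), bitorder="little")
    return np.zeros(0, dtype=np.uint8)


def _unpack_bins(stream: np.ndarray, counts: np.ndarray, bits: int) -> list[np.ndarray]:
    total = int(counts.sum())
    bit_arr = np.unpackbits(stream, bitorder="little")[: total * bits]
    vals = bit_arr.reshape(total, bits).astype(np.uint8) @ (1 << np.arange(bits, dtype=np.uint8))
    out, at = [], 0
    for c in counts:
        out.append(vals[at : at + c].astype(np.uint8))
        at += int(c)
    return out


def _packed(grp: h5py.Group, name: str, data, dtype=None) -> None:
    grp.create_dataset(name, data=np.asarray(data, dtype=dtype), compression="gzip", shuffle=True)


def _write_side_group(grp: h5py.Group, sides: list[EncodedNodeSide], bits: int) -> None:
    payload, offsets = _concat_payloads([s.ef.payload for s in sides])
    _packed(grp, "ef_payload", payload)
    _packed(grp, "ef_offsets", offsets)
    _packed(grp, "ef_m", [s.ef.m for s in sides], np.int64)
    _packed(grp, "bin_stream", _pack_bins(sides, bits))
    _packed(grp, "log_mu", [s.log_mu for s in sides])
    _packed(grp, "log_sigma", [s.log_sigma for s in sides])
    _packed(
        grp,
        "bin_reps",
        np.stack([s.bin_reps for s in sides]) if sides else np.zeros((0, 2**bits)),
    )


def _read_side_group(grp: h5py.Group, side: str, n_pools: int, bits: int) -> list[EncodedNodeSide]:
    payload = bytes(grp["ef_payload"][()].tobytes()) if grp["ef_payload"].size else b""
    offsets = grp["ef_offsets"][()]
    ms = grp["ef_m"][()]
    bins = _unpack_bins(grp["bin_stream"][()], ms, bits)
    log_mu = grp["log_mu"][()]
    log_sigma = grp["log_sigma"][()]
    bin_reps = grp["bin_reps"][()]
    sides = []
    for i in range(len(ms)):
        ef = EliasFano(
            m=int(ms[i]),
            universe=n_pools,
            payload=payload[offsets[i] : offsets[i + 1]],
        )
        sides.append(
            EncodedNodeSide(
                side=side,
                ef=ef,
                value_bins=bins[i],
                log_mu=float(log_mu[i]),
                log_sigma=float(log_sigma[i]),
                bin_reps=bin_reps[i],
            )
        )
    return sides


def save_index(index: CompressedIndex, path) -> None:
    """Serialize the index into a single HDF5 container."""
    str_dt = h5py.string_dtype("utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["tau"] = index.tau
        f.attrs["bits"] = index.bits
        f.attrs["min_reads"] = index.min_reads

        g = f.create_group("pools")
        g.create_dataset("pool_id", data=[p.pool_id for p in index.pools], dtype=str_dt)
        g.create_dataset("cell_type", data=[p.cell_type for p in index.pools], dtype=str_dt)
        g.create_dataset(
            "members",
            data=[",".join(sorted(p.member_cells)) for p in index.pools],
            dtype=str_dt,
            compression="gzip",
        )
        g.create_dataset(
            "pool_size_param", data=[p.pool_size_param for p in index.pools], dtype=np.int64
        )

        g = f.create_group("nodes")
        g.create_dataset("gene", data=[n.gene for n in index.nodes], dtype=str_dt, compression="gzip")
        _packed(g, "node_id", [n.node_id for n in index.nodes], np.int64)
        g.create_dataset("chrom", data=[n.chrom for n in index.nodes], dtype=str_dt, compression="gzip")
        _packed(g, "start", [n.start for n in index.nodes], np.int64)
        _packed(g, "end", [n.end for n in index.nodes], np.int64)
        g.create_dataset("strand", data=[n.strand for n in index.nodes], dtype=str_dt, compression="gzip")
        g.create_dataset("node_type", data=[n.node_type for n in index.nodes], dtype=str_dt, compression="gzip")

        g = f.create_group("stats")
        _packed(g, "mean_psi", [s.mean_psi for s in index.stats])
        _packed(g, "sd_psi", [s.sd_psi for s in index.stats])
        _packed(g, "n_quantified", [s.n_quantified for s in index.stats], np.int64)

        _write_side_group(f.create_group("above"), index.above, index.bits)
        _write_side_group(f.create_group("below"), index.below, index.bits)

        g = f.create_group("mask")
        payload, offsets = _concat_payloads([ef.payload for ef in index.mask])
        _packed(g, "ef_payload", payload)
        _packed(g, "ef_offsets", offsets)
        _packed(g, "ef_m", [ef.m for ef in index.mask], np.int64)


def load_index(path) -> CompressedIndex:
    """Load an index container; errors on format-version mismatch."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version", "<missing>")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"index container version {version!r} incompatible with reader {FORMAT_VERSION!r}"
            )
        tau = float(f.attrs["tau"])
        bits = int(f.attrs["bits"])
        min_reads = int(f.attrs["min_reads"])

        g = f["pools"]
        pool_ids = [s.decode() for s in g["pool_id"][()]]
        cell_types = [s.decode() for s in g["cell_type"][()]]
        members = [s.decode() for s in g["members"][()]]
        sizes = g["pool_size_param"][()]
        pools = [
            PoolAssignment(
                pool_id=pid,
                cell_type=ct,
                member_cells=frozenset(mem.split(",")) if mem else frozenset(),
                pool_size_param=int(sz),
            )
            for pid, ct, mem, sz in zip(pool_ids, cell_types, members, sizes)
        ]
        n_pools = len(pools)

        g = f["nodes"]
        nodes = [
            SplicingNode(
                gene=gene.decode(),
                node_id=int(nid),
                chrom=chrom.decode(),
                start=int(start),
                end=int(end),
                strand=strand.decode(),
                node_type=ntype.decode(),
            )
            for gene, nid, chrom, start, end, strand, ntype in zip(
                g["gene"][()], g["node_id"][()], g["chrom"][()],
                g["start"][()], g["end"][()], g["strand"][()], g["node_type"][()],
            )
        ]

        g = f["stats"]
        stats = [
            NodeStats(mean_psi=float(m), sd_psi=float(s), n_quantified=int(n))
            for m, s, n in zip(g["mean_psi"][()], g["sd_psi"][()], g["n_quantified"][()])
        ]

        above = _read_side_group(f["above"], "above", n_pools, bits)
        below = _read_side_group(f["below"], "below", n_pools, bits)

        g = f["mask"]
        payload = bytes(g["ef_payload"][()].tobytes()) if g["ef_payload"].size else b""
        offsets = g["ef_offsets"][()]
        ms = g["ef_m"][()]
        mask = [
            EliasFano(
                m=int(ms[i]),
                universe=n_pools,
                payload=payload[offsets[i] : offsets[i + 1]],
            )
            for i in range(len(ms))
        ]

    return CompressedIndex(
        pools=pools, nodes=nodes, stats=stats, above=above, below=below,
        mask=mask, tau=tau, bits=bits, min_reads=min_reads,
    )
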
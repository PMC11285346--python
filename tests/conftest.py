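import numpy as np
import pytest

from spliceindex.psi_data import PoolAssignment, PsiMatrix, SplicingNode
from spliceindex.ef_index import build_index
from spliceindex.synthetic import SimConfig, simulate_dataset, random_psi_matrix


def make_pools(cell_types):
    """One single-cell pool per entry of ``cell_types``."""
    return [
        PoolAssignment(
            pool_id=f"p{i}", cell_type=ct, member_cells=frozenset({f"c{i}"}), pool_size_param=1
        )
        for i, ct in enumerate(cell_types)
    ]


def make_nodes(n, gene="G1", node_type="CE"):
    return [
        SplicingNode(gene=gene, node_id=i + 1, chrom="chr1", start=100 * i + 1,
                     end=100 * i + 50, strand="+", node_type=node_type)
        for i in range(n)
    ]


def matrix_from(values, cell_types=None, nodes=None):
    values = np.asarray(values, dtype=float)
    cell_types = cell_types or ["A"] * values.shape[0]
    nodes = nodes or make_nodes(values.shape[1])
    return PsiMatrix(pools=make_pools(cell_types), nodes=nodes, values=values)


def naive_tripartition(matrix, tau=0.2):
    """Independent dense scan: per node -> (above, below, mask) pool-index sets."""
    out = {}
    for j, node in enumerate(matrix.nodes):
        col = matrix.values[:, j]
        quant = np.flatnonzero(~np.isnan(col))
        if quant.size == 0:
            continue
        mean = col[quant].mean()
        above = {int(i) for i in quant if col[i] - mean > tau}
        below = {int(i) for i in quant if col[i] - mean < -tau}
        mask = {int(i) for i in quant} - above - below
        out[node.label] = (above, below, mask)
    return out


@pytest.fixture(scope="session")
def toy_matrix():
    """3 pools x 3 nodes: node 1 has one above + one below pool, node 2 stays
    within tau of its mean, node 3 has one missing entry."""
    values = [
        [0.1, 0.50, np.nan],
        [0.5, 0.55, 0.2],
        [0.9, 0.60, 0.9],
    ]
    return matrix_from(values, cell_types=["A", "B", "B"])


@pytest.fixture(scope="session")
def toy_index(toy_matrix):
    return build_index(toy_matrix, tau=0.2, bits=2)


@pytest.fixture(scope="session")
def random_matrix():
    return random_psi_matrix(50, 200, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def random_index(random_matrix):
    return build_index(random_matrix)


@pytest.fixture(scope="session")
def planted_sim():
    """Small dataset with one planted marker, MXE pair and block."""
    cfg = SimConfig(
        n_genes=12,
        n_cell_types=5,
        pools_per_type=(6, 6),
        planted_markers=[(0, 0.4, "inclusion")],
        planted_mxe=[(1, 0.9, 0.1)],
        planted_blocks=[(2, 4, 0.4, "above")],
        seed=3,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_index(planted_sim):
    from spliceindex.synthetic import index_from_simulation

    return index_from_simulation(planted_sim)
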
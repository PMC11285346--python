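"""Queries against the compressed index.

A pattern is a conjunction (AND) or disjunction (OR) of per-node terms, each
asking for differential inclusion ("above": PSI more than tau above the
node's mean) or differential exclusion ("below").  Matching reduces to set
algebra on the decoded Elias-Fano position sets; pools where a node is
unquantified simply never match a term -- no imputation is involved.

Cell-type enrichment of a pattern uses the hypergeometric upper tail:
with N total pools, K of them matching the pattern, and n pools of a given
cell type of which k match, the p-value is P(X >= k) for
X ~ Hypergeometric(N, K, n).  A cell type with p <= 0.05 is called
significant (raw p-values, matching common practice for this screen;
Benjamini-Hochberg correction is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .ef_index import CompressedIndex

__all__ = [
    "PatternQuery",
    "EnrichmentResult",
    "pools_matching",
    "recover_psi",
    "hypergeom_pvalue",
    "hyper_query_cell_types",
]

ABOVE = "above"
BELOW = "below"


@dataclass(frozen=True)
class PatternQuery:
    """Terms are (node label, direction) with direction "above" or "below"."""

    terms: tuple[tuple[str, str], ...]
    combinator: str = "AND"

    def __post_init__(self) -> None:
        if len(self.terms) == 0:
            raise ValueError("a pattern needs at least one term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate (node, direction) terms")
        if self.combinator not in ("AND", "OR"):
            raise ValueError(f"combinator must be AND or OR, got {self.combinator!r}")
        for _, d in self.terms:
            if d not in (ABOVE, BELOW):
                raise ValueError(f"direction must be {ABOVE!r} or {BELOW!r}, got {d!r}")

    @classmethod
    def include(cls, *nodes: str) -> "PatternQuery":
        """AND-pattern requiring all given nodes to be differentially included."""
        return cls(tuple((n, ABOVE) for n in nodes))

    @classmethod
    def exclude(cls, *nodes: str) -> "PatternQuery":
        return cls(tuple((n, BELOW) for n in nodes))


@dataclass(frozen=True)
class EnrichmentResult:
    cell_type: str
    k: int  # pools of this type matching the pattern
    n: int  # pools of this type
    K: int  # matching pools overall
    N: int  # pools overall
    p_value: float
    significant: bool


def _term_positions(index: CompressedIndex, node: str, direction: str) -> np.ndarray:
    j = index.node_index(node)
    side = index.above[j] if direction == ABOVE else index.below[j]
    return side.positions


def matching_positions(index: CompressedIndex, query: PatternQuery) -> np.ndarray:
    """Pool positions (0-based, sorted) matching the pattern."""
    sets = [set(_term_positions(index, n, d).tolist()) for n, d in query.terms]
    if query.combinator == "AND":
        out = set.intersection(*sets)
    else:
        out = set.union(*sets)
    return np.array(sorted(out), dtype=np.int64)


def pools_matching(index: CompressedIndex, query: PatternQuery) -> list[str]:
    """Pool ids matching the pattern, in index pool order."""
    return [index.pools[i].pool_id for i in matching_positions(index, query)]


def recover_psi(index: CompressedIndex, node) -> np.ndarray:
    """Approximate per-pool PSI of a node, NaN where unquantified.

    Above pools reconstruct as mean + representative/100, below pools as
    mean - representative/100 (clamped to [0, 1]); near-mean mask pools
    reconstruct as the mean exactly.
    """
    j = index.node_index(node)
    mean = index.stats[j].mean_psi
    out = np.full(index.n_pools, np.nan)
    out[index.mask_positions(j)] = mean
    a = index.above[j]
    if a.ef.m:
        out[a.positions] = np.clip(mean + a.values / 100.0, 0.0, 1.0)
    b = index.below[j]
    if b.ef.m:
        out[b.positions] = np.clip(mean - b.values / 100.0, 0.0, 1.0)
    return out


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k), k inclusive.

    X counts pattern-matching pools among the n pools of a cell type when
    K of the N pools match overall.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"infeasible counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy's hypergeom is exact and stable here
    return float(_sps.hypergeom.sf(k - 1, N, K, n))


def hyper_query_cell_types(
    index: CompressedIndex,
    query: PatternQuery,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of a pattern in every cell type.

    Returns one result per cell type with at least one pool, sorted by
    p-value ascending (ties broken by cell type name).  Significance is
    ``p <= alpha`` on raw p-values by default; ``bh_correct=True`` applies
    Benjamini-Hochberg across cell types first.
    """
    match = matching_positions(index, query)
    N = index.n_pools
    K = int(match.size)
    types = np.asarray(index.cell_types)
    in_match = np.zeros(N, dtype=bool)
    in_match[match] = True

    results = []
    for ct in sorted({str(t) for t in types}):
        of_type = types == ct
        n = int(of_type.sum())
        k = int((of_type & in_match).sum())
        p = hypergeom_pvalue(k, n, K, N)
        results.append([ct, k, n, K, N, p])

    pvals = np.array([r[5] for r in results])
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        sig = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        sig = pvals <= alpha

    out = [
        EnrichmentResult(ct, k, n, K, N, p, bool(s))
        for (ct, k, n, K, N, p), s in zip(results, sig)
    ]
    out.sort(key=lambda r: (r.p_value, r.cell_type))
    return out
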
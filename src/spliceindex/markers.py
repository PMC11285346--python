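"""Exhaustive search for cell type marker splicing nodes.

A node is a good marker for a cell type when its differential inclusion (or
exclusion) pattern singles out that type's pools.  Detection is pool-level:
a true positive is a pool of the target type found on the node's side
(above for the inclusion direction, below for exclusion); a false positive
is a pool of any other type on that side; a false negative is a pool of the
target type NOT detected on that side -- which deliberately counts pools
where the node was unquantified or near the mean, since sparse splicing
quantification is exactly what degrades recall in practice.

Markers are ranked by F1 = 2pr/(p+r), ties broken by precision then node
label; both directions compete in one pooled ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ef_index import CompressedIndex

__all__ = ["MarkerScore", "evaluate_marker", "find_markers"]

INCLUSION = "inclusion"
EXCLUSION = "exclusion"


@dataclass(frozen=True)
class MarkerScore:
    node: str
    gene: str
    cell_type: str
    direction: str  # "inclusion" | "exclusion"
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def _score(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def evaluate_marker(
    index: CompressedIndex,
    node,
    cell_type: str,
    direction: str,
    near_mean_as_fn: bool = True,
) -> MarkerScore:
    """Precision/recall/F1 of one node as a marker of one cell type.

    ``near_mean_as_fn`` controls whether target-type pools that were
    quantified but near the node's mean count as false negatives (default)
    or are excluded from the denominator entirely; unquantified pools always
    count as FN.
    """
    if direction not in (INCLUSION, EXCLUSION):
        raise ValueError(f"direction must be {INCLUSION!r} or {EXCLUSION!r}")
    j = index.node_index(node)
    side = index.above[j] if direction == INCLUSION else index.below[j]
    types = np.asarray(index.cell_types)
    if cell_type not in types:
        raise KeyError(f"cell type {cell_type!r} not in index")
    of_type = types == cell_type
    n_type = int(of_type.sum())
    pos = side.positions
    tp = int(of_type[pos].sum())
    fp = int(pos.size) - tp
    fn = n_type - tp
    if not near_mean_as_fn:
        fn -= int(of_type[index.mask_positions(j)].sum())
    precision, recall, f1 = _score(tp, fp, fn)
    return MarkerScore(
        node=index.nodes[j].label,
        gene=index.nodes[j].gene,
        cell_type=cell_type,
        direction=direction,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
    )


def find_markers(
    index: CompressedIndex,
    cell_type: str,
    top_n: int = 20,
    min_f1: float = 0.0,
    near_mean_as_fn: bool = True,
) -> list[MarkerScore]:
    """Rank every (node, direction) pair as a marker of ``cell_type``.

    Returns the ``top_n`` scores with F1 above ``min_f1`` (strict when
    ``min_f1 > 0``), sorted by F1 descending, then precision descending,
    then node label.
    """
    types = np.asarray(index.cell_types)
    if cell_type not in types:
        raise KeyError(f"cell type {cell_type!r} not in index")
    of_type = types == cell_type
    n_type = int(of_type.sum())

    scores: list[MarkerScore] = []
    for j, node in enumerate(index.nodes):
        for direction, side in ((INCLUSION, index.above[j]), (EXCLUSION, index.below[j])):
            pos = side.positions
            tp = int(of_type[pos].sum())
            fp = int(pos.size) - tp
            fn = n_type - tp
            if not near_mean_as_fn:
                fn -= int(of_type[index.mask_positions(j)].sum())
            precision, recall, f1 = _score(tp, fp, fn)
            if f1 >= min_f1:
                scores.append(
                    MarkerScore(
                        node=node.label,
                        gene=node.gene,
                        cell_type=cell_type,
                        direction=direction,
                        tp=tp,
                        fp=fp,
                        fn=fn,
                        precision=precision,
                        recall=recall,
                        f1=f1,
                    )
                )
    scores.sort(key=lambda s: (-s.f1, -s.precision, s.node))
    return scores[:top_n]
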
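"""The four MI-based inference algorithms: C3NET, RN, ARACNE, MRNET.

All four map a symmetric MI matrix (plus significance information) to an
undirected network:

* RN keeps every pair whose MI exceeds a threshold I0.
* C3NET first eliminates non-significant pairs, then keeps for each gene only
  the single remaining pair with that gene's maximal MI — so it can never
  infer more edges than there are genes.
* ARACNE starts from the RN edge set and applies the data processing
  inequality: within each fully connected gene triple, the weakest edge is
  removed if it is smaller than both others minus an (additive) tolerance.
* MRNET grows, per target gene, a regulator set by maximum-relevance /
  minimum-redundancy: at each step it adds the gene maximizing
  relevance I(X;Y) minus the mean redundancy with the genes already chosen,
  stopping when the best score drops to the threshold s0.

Ties at a gene's maximum are broken toward the partner earliest in gene
order, which keeps every algorithm deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .mi import MIMatrix, SignificanceMask, mi_matrix, significance_mask
from .simulate import ExpressionMatrix

Pair = tuple[str, str]


@dataclass
class InferredNetwork:
    """Undirected inference result, MI-weighted.

    Edges are stored as gene-order-sorted pairs; ``weights`` maps each pair to
    the MI value it was selected from.
    """

    gene_ids: list[str]
    edges: set[Pair]
    weights: dict[Pair, float] = field(default_factory=dict)
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        canon = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-edge on {u!r}")
            canon.add((u, v) if idx[u] < idx[v] else (v, u))
        self.edges = canon

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}


def _ordered_pair(i: int, j: int, gene_ids: list[str]) -> Pair:
    a, b = (i, j) if i < j else (j, i)
    return (gene_ids[a], gene_ids[b])


def infer_c3net(mim: MIMatrix, mask: SignificanceMask) -> InferredNetwork:
    """Core C3NET selection: each gene contributes (at most) its maximal
    significant MI pair; duplicates collapse, so |edges| <= |genes|."""
    if list(mim.gene_ids) != list(mask.gene_ids):
        raise ValueError("MI matrix and significance mask gene ids differ")
    m, b = mim.values, mask.mask
    edges: set[Pair] = set()
    weights: dict[Pair, float] = {}
    for i in range(len(mim.gene_ids)):
        js = np.flatnonzero(b[i])
        if js.size == 0:
            continue
        best = int(js[np.argmax(m[i, js])])  # argmax keeps the earliest on ties
        pair = _ordered_pair(i, best, mim.gene_ids)
        edges.add(pair)
        weights[pair] = float(m[i, best])
    return InferredNetwork(list(mim.gene_ids), edges, weights, "c3net", dict(mask.params))


def infer_rn(mim: MIMatrix, i0: float) -> InferredNetwork:
    """Relevance network: every pair with MI strictly above I0."""
    m = mim.values
    iu, ju = np.triu_indices(len(mim.gene_ids), k=1)
    keep = m[iu, ju] > i0
    edges, weights = set(), {}
    for i, j in zip(iu[keep], ju[keep]):
        pair = _ordered_pair(int(i), int(j), mim.gene_ids)
        edges.add(pair)
        weights[pair] = float(m[i, j])
    return InferredNetwork(list(mim.gene_ids), edges, weights, "rn", {"i0": i0})


def infer_aracne(mim: MIMatrix, i0: float, tolerance: float = 0.1) -> InferredNetwork:
    """RN thresholding followed by DPI triple elimination.

    For every gene triple whose three pairwise MI values all survive the I0
    threshold, the minimum edge is marked for removal when it is smaller than
    both other edges minus ``tolerance``; all marked edges are removed
    simultaneously, so removal order cannot influence the result.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    base = infer_rn(mim, i0)
    m = mim.values
    idx = {g: i for i, g in enumerate(mim.gene_ids)}
    adj = np.zeros((len(mim.gene_ids),) * 2, dtype=bool)
    for u, v in base.edges:
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = True
    marked: set[Pair] = set()
    n = len(mim.gene_ids)
    for i, j, k in itertools.combinations(range(n), 3):
        if not (adj[i, j] and adj[i, k] and adj[j, k]):
            continue
        trip = [((i, j), m[i, j]), ((i, k), m[i, k]), ((j, k), m[j, k])]
        for (a, b), w in trip:
            others = [x for (e, x) in trip if e != (a, b)]
            if w < min(others) - tolerance:
                marked.add(_ordered_pair(a, b, mim.gene_ids))
    edges = base.edges - marked
    weights = {e: base.weights[e] for e in edges}
    return InferredNetwork(
        list(mim.gene_ids), edges, weights, "aracne", {"i0": i0, "tolerance": tolerance}
    )


def infer_mrnet(mim: MIMatrix, s0: float) -> InferredNetwork:
    """Per-target greedy maximum-relevance / minimum-redundancy selection.

    For target Y the score of a candidate X_j is I(X_j;Y) minus the mean MI
    between X_j and the regulators already selected (raw relevance for the
    first pick). Selection stops when the best score is <= s0; the union of
    the resulting target-regulator pairs over all targets is returned.
    """
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    m = mim.values
    n = len(mim.gene_ids)
    edges, weights = set(), {}
    for y in range(n):
        selected: list[int] = []
        candidates = [j for j in range(n) if j != y]
        while candidates:
            best_j, best_score = None, -np.inf
            for j in candidates:  # ascending order => earliest gene wins ties
                redundancy = float(np.mean(m[j, selected])) if selected else 0.0
                score = m[j, y] - redundancy
                if score > best_score:
                    best_j, best_score = j, score
            if best_score <= s0:
                break
            selected.append(best_j)
            candidates.remove(best_j)
            pair = _ordered_pair(y, best_j, mim.gene_ids)
            edges.add(pair)
            weights[pair] = float(m[y, best_j])
    return InferredNetwork(list(mim.gene_ids), edges, weights, "mrnet", {"s0": s0})


def c3net_pipeline(
    data: ExpressionMatrix,
    alpha: float = 0.01,
    methodstep1: str = "cutoff",
    cutoff_mi: float = 0.0,
    mtc_method: str = "BH",
    itnum: int = 5,
    seed: int | None = None,
) -> InferredNetwork:
    """All-in-one C3NET run mirroring the reference interface defaults
    (alpha=0.01, methodstep1="cutoff", cutoff_mi=0, mtc_method="BH", itnum=5):
    estimate the MI matrix, build the step-1 significance mask, select edges.
    """
    mim = mi_matrix(data)
    mask = significance_mask(
        mim,
        methodstep1,
        alpha=alpha,
        cutoff_mi=cutoff_mi,
        mtc_method=mtc_method,
        itnum=itnum,
        seed=seed,
        data=data,
    )
    return infer_c3net(mim, mask)
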
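"""Independent brute-force oracles: literal transcriptions of each
algorithm's definition, kept free of the package's code paths."""

from __future__ import annotations

import itertools
import math


def rn_oracle(mi: list[list[float]], i0: float) -> set[frozenset]:
    n = len(mi)
    return {
        frozenset((i, j))
        for i in range(n)
        for j in range(i + 1, n)
        if mi[i][j] > i0
    }


def c3net_oracle(mi: list[list[float]], mask: list[list[bool]]) -> set[frozenset]:
    n = len(mi)
    edges = set()
    for i in range(n):
        best_j, best_v = None, -math.inf
        for j in range(n):
            if j != i and mask[i][j] and mi[i][j] > best_v:
                best_j, best_v = j, mi[i][j]
        if best_j is not None:
            edges.add(frozenset((i, best_j)))
    return edges


def aracne_oracle(mi: list[list[float]], i0: float, tol: float) -> set[frozenset]:
    edges = rn_oracle(mi, i0)
    marked = set()
    n = len(mi)
    for i, j, k in itertools.combinations(range(n), 3):
        trio = [frozenset((i, j)), frozenset((i, k)), frozenset((j, k))]
        if not all(e in edges for e in trio):
            continue
        vals = {frozenset((a, b)): mi[a][b] for a, b in [(i, j), (i, k), (j, k)]}
        for e, w in vals.items():
            others = [v for e2, v in vals.items() if e2 != e]
            if w < min(others) - tol:
                marked.add(e)
    return edges - marked


def mrnet_oracle(mi: list[list[float]], s0: float) -> set[frozenset]:
    n = len(mi)
    edges = set()
    for y in range(n):
        selected: list[int] = []
        candidates = [j for j in range(n) if j != y]
        while candidates:
            scores = []
            for j in candidates:
                red = sum(mi[j][k] for k in selected) / len(selected) if selected else 0.0
                scores.append((mi[j][y] - red, -j))
            best_score, neg_j = max(scores)
            if best_score <= s0:
                break
            j = -neg_j
            selected.append(j)
            candidates.remove(j)
            edges.add(frozenset((y, j)))
    return edges


# -- motifs -----------------------------------------------------------------

_TEMPLATES = {
    "chain": {(0, 1), (1, 2)},
    "collider": {(0, 2), (1, 2)},
    "fork": {(0, 1), (0, 2)},
}


def classify_motif_oracle(nodes, edges) -> str:
    """Template matching under all relabelings of the triple."""
    nodes = list(nodes)
    pairs = {frozenset(e) for e in edges}
    if len(pairs) == 3:
        return "triangle"
    if len(edges) != 2 or len(pairs) != 2:
        return "none"
    for perm in itertools.permutations(range(3)):
        relabeled = {
            (perm[nodes.index(u)], perm[nodes.index(v)]) for u, v in edges
        }
        for name, template in _TEMPLATES.items():
            if relabeled == template:
                return name
    return "none"


def enumerate_motifs_oracle(nodes, edges) -> dict[tuple, str]:
    """type per classifying triple, brute force over all C(n,3) subsets."""
    out = {}
    for trip in itertools.combinations(nodes, 3):
        induced = [(u, v) for u, v in edges if u in trip and v in trip]
        mtype = classify_motif_oracle(trip, induced)
        if mtype != "none":
            out[trip] = mtype
    return out


def edge_tpr_oracle(true_edges, run_pair_sets) -> dict:
    return {
        e: sum(frozenset(e) in s for s in run_pair_sets) / len(run_pair_sets)
        for e in true_edges
    }


def trr_oracle(trip, true_edges, run_pair_sets) -> float:
    """Mean over the triple's 3 pairs of TPR (connected) / TNR (absent)."""
    skel = {frozenset(e) for e in true_edges}
    rates = []
    for pair in itertools.combinations(trip, 2):
        p = frozenset(pair)
        f = sum(p in s for s in run_pair_sets) / len(run_pair_sets)
        rates.append(f if p in skel else 1.0 - f)
    return sum(rates) / len(rates)
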
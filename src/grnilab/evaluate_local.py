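"""Local network-based performance metrics over dataset ensembles.

Where global F-scores average over the whole network, these metrics zoom in
on individual structures of the true network:

* per-edge true positive rate (TPR) — the fraction of ensemble runs in which
  a specific true edge is recovered;
* activator vs repressor comparison — a two-sample Kolmogorov-Smirnov test on
  the TPR distributions of the two edge sign classes;
* Ds degree-sum analysis — Ds(i->j) = out-degree(i) + in-degree(j) on the
  true network, with a one-way ANOVA of TPR across Ds levels;
* three-node motif classification (chain, collider, fork, triangle) with a
  per-motif true reconstruction rate (TRR);
* TPR color categories (black/blue/green/red) and leaf-edge reporting.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, ks_2samp

from .inference import InferredNetwork
from .networks import DirectedNetwork, Edge, undirected_skeleton

MOTIF_TYPES = ("chain", "collider", "fork", "triangle")

#: Fig-style color bins; each boundary belongs to the *lower* bin
#: (tpr 0.75 -> blue, 0.5 -> green, 0.25 -> red).
CATEGORY_BINS = (("black", 0.75), ("blue", 0.5), ("green", 0.25), ("red", -1.0))


@dataclass
class EdgeStat:
    """Per-true-edge summary over an ensemble of inferred networks."""

    edge: Edge
    sign: str | None
    tpr: float
    ds: int
    category: str


@dataclass
class MotifRecord:
    nodes: tuple[str, str, str]
    type: str
    pairs_present: tuple[frozenset, ...]
    pairs_absent: tuple[frozenset, ...]


@dataclass
class MotifTypeSummary:
    count: int
    mean_trr: float
    sd_trr: float


def _pair_frequency(inferred_list: Sequence[InferredNetwork]) -> dict[frozenset, float]:
    if not inferred_list:
        raise ValueError("ensemble of inferred networks is empty")
    freq: Counter = Counter()
    for net in inferred_list:
        freq.update(net.pairs())
    n = len(inferred_list)
    return {pair: c / n for pair, c in freq.items()}


def edge_tpr(
    truth: DirectedNetwork, inferred_list: Sequence[InferredNetwork]
) -> dict[Edge, float]:
    """TPR of each directed true edge: the fraction of runs whose (undirected)
    edge set contains the corresponding unordered pair."""
    freq = _pair_frequency(inferred_list)
    return {e: freq.get(frozenset(e), 0.0) for e in truth.sorted_edges()}


def categorize_tpr(tpr: float) -> str:
    if not 0.0 <= tpr <= 1.0:
        raise ValueError(f"tpr {tpr} outside [0, 1]")
    for name, lower in CATEGORY_BINS:
        if tpr > lower:
            return name
    return "red"  # pragma: no cover - tpr == 0 handled by lower=-1 bin


def ds_value(truth: DirectedNetwork, edge: Edge) -> int:
    """Degree-sum covariate Ds(i->j) = out-degree(i) + in-degree(j).

    The edge itself contributes one to each term, so Ds >= 2."""
    edge = tuple(edge)
    if edge not in truth.edges:
        raise ValueError(f"edge {edge!r} is not in the true network")
    return truth.out_degree()[edge[0]] + truth.in_degree()[edge[1]]


def edge_stats(
    truth: DirectedNetwork, inferred_list: Sequence[InferredNetwork]
) -> list[EdgeStat]:
    """One EdgeStat per directed true edge (sign, TPR, Ds, color category)."""
    tprs = edge_tpr(truth, inferred_list)
    out_deg, in_deg = truth.out_degree(), truth.in_degree()
    return [
        EdgeStat(
            edge=e,
            sign=truth.signs.get(e),
            tpr=t,
            ds=out_deg[e[0]] + in_deg[e[1]],
            category=categorize_tpr(t),
        )
        for e, t in tprs.items()
    ]


def edge_sign_ks_test(stats: Iterable[EdgeStat]):
    """Two-sided two-sample KS test comparing activator and repressor TPRs.

    Uses the asymptotic Kolmogorov distribution for the p-value. Returns
    (D, p, samples) where samples maps sign -> TPR list.
    """
    samples = {"activator": [], "repressor": []}
    for s in stats:
        if s.sign in samples:
            samples[s.sign].append(s.tpr)
    for name, vals in samples.items():
        if not vals:
            raise ValueError(f"no edges of sign class {name!r}")
    res = ks_2samp(samples["activator"], samples["repressor"], method="asymp")
    return float(res.statistic), float(res.pvalue), samples


def tpr_by_ds_anova(stats: Sequence[EdgeStat]):
    """One-way ANOVA of edge TPR grouped by Ds level.

    Levels holding a single edge are excluded from the test (no within-group
    variance) but kept in the returned group-mean table. Returns
    (F, p, table) where the table has columns (ds, n_edges, mean_tpr).
    """
    groups: dict[int, list[float]] = {}
    for s in stats:
        groups.setdefault(s.ds, []).append(s.tpr)
    table = pd.DataFrame(
        [
            {"ds": ds, "n_edges": len(v), "mean_tpr": float(np.mean(v))}
            for ds, v in sorted(groups.items())
        ],
        columns=["ds", "n_edges", "mean_tpr"],
    )
    testable = [v for _, v in sorted(groups.items()) if len(v) >= 2]
    if len(testable) < 2:
        raise ValueError("ANOVA requires >= 2 Ds levels with >= 2 edges each")
    f_stat, p = f_oneway(*testable)
    return float(f_stat), float(p), table


def classify_motif(nodes: Sequence[str], induced_edges: Iterable[Edge]) -> str:
    """Classify the induced directed edge set of a 3-node subset.

    chain: two edges meeting head-to-tail; collider: two edges sharing the
    target; fork: two edges sharing the source; triangle: all three unordered
    pairs connected (any orientation pattern). Anything else — including a
    lone reciprocal pair — is "none".
    """
    nodes = tuple(nodes)
    if len(set(nodes)) != 3:
        raise ValueError("classify_motif requires exactly 3 distinct nodes")
    edges = [tuple(e) for e in induced_edges]
    for u, v in edges:
        if u not in nodes or v not in nodes:
            raise ValueError(f"edge ({u!r}, {v!r}) is not within the triple")
    pairs = {frozenset(e) for e in edges}
    if len(pairs) == 3:
        return "triangle"
    if len(edges) == 2 and len(pairs) == 2:
        (a1, b1), (a2, b2) = edges
        if b1 == a2 or b2 == a1:
            return "chain"
        if b1 == b2:
            return "collider"
        if a1 == a2:
            return "fork"
    return "none"


def enumerate_motifs(truth: DirectedNetwork) -> list[MotifRecord]:
    """Exhaustive classification of all C(n,3) node triples; only triples
    matching one of the four motif types yield a record."""
    records = []
    edges_by_pair: dict[frozenset, list[Edge]] = {}
    for e in truth.sorted_edges():
        edges_by_pair.setdefault(frozenset(e), []).append(e)
    for trip in itertools.combinations(truth.nodes, 3):
        all_pairs = [frozenset(p) for p in itertools.combinations(trip, 2)]
        induced = [e for p in all_pairs for e in edges_by_pair.get(p, [])]
        mtype = classify_motif(trip, induced)
        if mtype == "none":
            continue
        present = tuple(p for p in all_pairs if edges_by_pair.get(p))
        absent = tuple(p for p in all_pairs if not edges_by_pair.get(p))
        records.append(MotifRecord(trip, mtype, present, absent))
    return records


def motif_trr(
    motifs: Sequence[MotifRecord],
    truth: DirectedNetwork,
    inferred_list: Sequence[InferredNetwork],
) -> dict[str, MotifTypeSummary]:
    """True reconstruction rate per motif, summarized per motif type.

    A motif's TRR averages, over its three unordered pairs, the TPR of pairs
    connected in the truth and the true-negative rate (fraction of runs *not*
    inferring the pair) of absent pairs. Per type the count #m, the mean TRR
    and its standard deviation (ddof=1; 0 for a single motif) are reported.
    """
    freq = _pair_frequency(inferred_list)
    skel = undirected_skeleton(truth)
    per_type: dict[str, list[float]] = {t: [] for t in MOTIF_TYPES}
    for rec in motifs:
        rates = []
        for pair in rec.pairs_present + rec.pairs_absent:
            f = freq.get(pair, 0.0)
            rates.append(f if pair in skel else 1.0 - f)
        per_type[rec.type].append(float(np.mean(rates)))
    summary = {}
    for t, vals in per_type.items():
        if vals:
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            summary[t] = MotifTypeSummary(len(vals), float(np.mean(vals)), sd)
        else:
            summary[t] = MotifTypeSummary(0, float("nan"), float("nan"))
    return summary


def categorize_edges(stats: Sequence[EdgeStat]):
    """Color category per edge plus per-category counts."""
    categories = {s.edge: categorize_tpr(s.tpr) for s in stats}
    return categories, Counter(categories.values())


def leaf_edge_report(
    truth: DirectedNetwork, stats: Sequence[EdgeStat]
) -> dict[str, float | None]:
    """Mean TPR of leaf vs internal edges.

    A leaf edge targets a leaf node: in-degree 1, out-degree 0. An empty class
    is reported as None."""
    in_deg, out_deg = truth.in_degree(), truth.out_degree()
    leaf, internal = [], []
    for s in stats:
        target = s.edge[1]
        if in_deg[target] == 1 and out_deg[target] == 0:
            leaf.append(s.tpr)
        else:
            internal.append(s.tpr)
    return {
        "leaf": float(np.mean(leaf)) if leaf else None,
        "internal": float(np.mean(internal)) if internal else None,
    }


def edge_stats_frame(stats: Sequence[EdgeStat]) -> pd.DataFrame:
    """EdgeStat list as a tidy table (source, target, sign, tpr, ds, category)."""
    return pd.DataFrame(
        [
            {
                "source": s.edge[0],
                "target": s.edge[1],
                "sign": s.sign or "",
                "tpr": s.tpr,
                "ds": s.ds,
                "category": s.category,
            }
            for s in stats
        ],
        columns=["source", "target", "sign", "tpr", "ds", "category"],
    )


def motif_summary_frame(summary: dict[str, MotifTypeSummary]) -> pd.DataFrame:
    """Motif summary as a table (#m, mean TRR, sd TRR per type)."""
    return pd.DataFrame(
        [
            {
                "motif": t,
                "count": summary[t].count,
                "mean_trr": summary[t].mean_trr,
                "sd_trr": summary[t].sd_trr,
            }
            for t in MOTIF_TYPES
        ],
        columns=["motif", "count", "mean_trr", "sd_trr"],
    )
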
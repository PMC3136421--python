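"""Global performance metrics: confusion counts, precision/recall/F, the
six-value check report, optimal-cutoff search and the F-vs-cutoff curve.

Because the inference output is undirected, all comparisons run on the
undirected skeleton of the true network: a reciprocal true pair counts as a
single skeleton edge and true negatives live on the C(n,2) unordered pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .inference import (
    InferredNetwork,
    infer_aracne,
    infer_c3net,
    infer_mrnet,
    infer_rn,
)
from .mi import MIMatrix, mi_matrix, significance_mask
from .networks import DirectedNetwork, undirected_skeleton
from .simulate import ExpressionMatrix

logger = logging.getLogger(__name__)

METHODS = ("c3net", "rn", "aracne", "mrnet")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class PerformanceScores:
    precision: float
    recall: float
    fscore: float


class CheckReport(NamedTuple):
    """The six-value report, in the reference order."""

    precision: float
    fscore: float
    recall: float
    tp: int
    fp: int
    fn: int


def confusion_counts(inferred: InferredNetwork, truth: DirectedNetwork) -> ConfusionCounts:
    """Edge-set confusion counts on the undirected skeleton of ``truth``."""
    if set(inferred.gene_ids) != set(truth.nodes):
        diff = sorted(set(inferred.gene_ids) ^ set(truth.nodes))
        raise ValueError(f"gene universes differ; symmetric difference: {diff}")
    skel = undirected_skeleton(truth)
    inf = inferred.pairs()
    tp = len(skel & inf)
    fp = len(inf - skel)
    fn = len(skel - inf)
    n = len(truth.nodes)
    tn = n * (n - 1) // 2 - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def precision_recall_f(c: ConfusionCounts) -> PerformanceScores:
    """p = TP/(TP+FP), r = TP/(TP+FN), F = 2pr/(p+r); zero-denominator cases
    return 0 by convention (logged)."""
    if c.tp + c.fp == 0:
        logger.info("precision denominator is zero; reporting 0")
        p = 0.0
    else:
        p = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        logger.info("recall denominator is zero; reporting 0")
        r = 0.0
    else:
        r = c.tp / (c.tp + c.fn)
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return PerformanceScores(p, r, f)


def scores_from_counts(tp: int, fp: int, fn: int) -> PerformanceScores:
    """Scores straight from confusion counts (TN plays no role)."""
    return precision_recall_f(ConfusionCounts(tp, fp, fn, 0))


def check_network(inferred: InferredNetwork, truth: DirectedNetwork) -> CheckReport:
    """Six-value validation report: (precision, F-score, recall, TP, FP, FN)."""
    c = confusion_counts(inferred, truth)
    s = precision_recall_f(c)
    return CheckReport(s.precision, s.fscore, s.recall, c.tp, c.fp, c.fn)


def infer_at_cutoff(
    mim: MIMatrix, method: str, i0: float, tolerance: float = 0.1
) -> InferredNetwork:
    """Run one algorithm with its threshold parameter set to ``i0``
    (C3NET in cutoff mode; MRNET with s0 = i0)."""
    if method == "c3net":
        return infer_c3net(mim, significance_mask(mim, "cutoff", cutoff_mi=i0))
    if method == "rn":
        return infer_rn(mim, i0)
    if method == "aracne":
        return infer_aracne(mim, i0, tolerance)
    if method == "mrnet":
        return infer_mrnet(mim, i0)
    raise ValueError(f"unknown method {method!r}; options: {METHODS}")


def default_grid(mim: MIMatrix, size: int = 100) -> np.ndarray:
    """Equally spaced cutoffs from 0 to the observed maximum MI."""
    return np.linspace(0.0, float(mim.values.max()), size)


def optimal_cutoff(
    data: ExpressionMatrix | MIMatrix,
    truth: DirectedNetwork,
    method: str,
    grid: Sequence[float],
    tolerance: float = 0.1,
) -> tuple[float, float]:
    """Grid point maximizing the F-score against the known truth.

    Returns (I0*, F*); ties resolve to the smallest I0. Since it peeks at the
    truth, F* is an upper bound for any data-driven threshold choice.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("cutoff grid must be nonempty")
    mim = data if isinstance(data, MIMatrix) else mi_matrix(data)
    best_i0, best_f = None, -1.0
    for i0 in sorted(grid):
        report = check_network(infer_at_cutoff(mim, method, i0, tolerance), truth)
        if report.fscore > best_f:
            best_i0, best_f = i0, report.fscore
    return float(best_i0), float(best_f)


def fscore_vs_cutoff(
    data: ExpressionMatrix | MIMatrix,
    truth: DirectedNetwork,
    methods: Sequence[str] = ("c3net", "rn"),
    grid: Sequence[float] | None = None,
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """F-score of each method over a shared cutoff grid, on one MI matrix.

    Returns a table with columns (cutoff, method, fscore), one row per
    (method, grid point).
    """
    mim = data if isinstance(data, MIMatrix) else mi_matrix(data)
    if grid is None:
        grid = default_grid(mim)
    rows = []
    for method in methods:
        for i0 in grid:
            report = check_network(infer_at_cutoff(mim, method, float(i0), tolerance), truth)
            rows.append({"cutoff": float(i0), "method": method, "fscore": report.fscore})
    return pd.DataFrame(rows, columns=["cutoff", "method", "fscore"])
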
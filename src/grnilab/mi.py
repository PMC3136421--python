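"""Pairwise mutual-information estimation and significance elimination.

Expression profiles are first copula-transformed — each gene's samples are
replaced by their ranks scaled to (0,1) — which makes all downstream
estimates invariant to strictly monotone distortions of the marginals. MI is
then estimated with the nonparametric Gaussian estimator in its pairwise
closed form

    I(X;Y) = -1/2 * ln(1 - rho^2)    [nats],

where rho is the Pearson correlation of the copula-transformed profiles.

Significance elimination (the first step shared by all the inference
algorithms here) supports three modes mirroring the reference interface:

* ``cutoff`` — keep MI values strictly above a fixed threshold I0,
* ``justp`` — keep pairs whose permutation p-value is below alpha,
* ``MTC``   — like justp but on multiplicity-adjusted p-values.

The permutation null shuffles every gene's samples independently (destroying
all inter-gene dependence while preserving margins) and pools all pairwise MI
values over ``itnum`` iterations into one shared null distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .simulate import ExpressionMatrix

logger = logging.getLogger(__name__)

#: |rho| is clipped here so duplicated genes get a large finite MI (~13.5 nats)
#: instead of infinity; max-selection downstream must be total.
MAX_ABS_RHO = 1.0 - 1e-12

MODES = ("cutoff", "justp", "mtc")

_MTC_METHODS = {
    "BH": "fdr_bh",
    "bonferroni": "bonferroni",
    "BY": "fdr_by",
    "hochberg": "simes-hochberg",
    "holm": "holm",
}


@dataclass
class MIMatrix:
    """Symmetric matrix of pairwise MI estimates in nats, zero diagonal."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("MI matrix shape does not match gene count")


@dataclass
class NullModel:
    """Sorted pool of MI values computed from permuted data."""

    null_values: np.ndarray
    itnum: int
    seed: int

    def __post_init__(self) -> None:
        self.null_values = np.sort(np.asarray(self.null_values, dtype=float))
        if self.null_values.size == 0:
            raise ValueError("null distribution is empty")


@dataclass
class SignificanceMask:
    """Symmetric boolean grid marking which gene pairs survived step 1."""

    gene_ids: list[str]
    mask: np.ndarray
    mode: str
    params: dict

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        np.fill_diagonal(self.mask, False)


def _as_values(data) -> np.ndarray:
    if isinstance(data, ExpressionMatrix):
        return data.values
    return np.asarray(data, dtype=float)


def copula_transform(data) -> np.ndarray:
    """Per-gene rank transform to (0,1): rank/(m+1), average ranks for ties."""
    vals = _as_values(data)
    if vals.ndim != 2 or vals.shape[1] < 2:
        raise ValueError("copula transform requires a genes x samples grid with >= 2 samples")
    m = vals.shape[1]
    return rankdata(vals, axis=1, method="average") / (m + 1)


def _mi_from_copula(u: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(u)
    rho = np.nan_to_num(rho, nan=0.0)  # constant genes have no dependence signal
    rho = np.clip(rho, -MAX_ABS_RHO, MAX_ABS_RHO)
    mi = -0.5 * np.log1p(-rho * rho)
    mi = np.maximum(mi, 0.0)
    np.fill_diagonal(mi, 0.0)
    return mi


def mi_gaussian(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian-copula MI of two sample vectors, in nats."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 2:
        raise ValueError("at least 2 samples are required")
    u = copula_transform(np.vstack([x, y]))
    return float(_mi_from_copula(u)[0, 1])


def mi_matrix(data) -> MIMatrix:
    """All-pairs MI on one shared copula transform of the data."""
    if isinstance(data, ExpressionMatrix):
        gene_ids = list(data.gene_ids)
    else:
        data = np.asarray(data, dtype=float)
        gene_ids = [f"G{i + 1}" for i in range(data.shape[0])]
    vals = _as_values(data)
    if vals.shape[0] < 2:
        raise ValueError("MI matrix requires at least 2 genes")
    return MIMatrix(gene_ids, _mi_from_copula(copula_transform(vals)))


def build_null(data, itnum: int, seed: int) -> NullModel:
    """Pooled permutation null: per iteration, permute each gene's samples
    independently, recompute the full MI matrix and collect all pairs."""
    if itnum < 1:
        raise ValueError("itnum must be >= 1")
    vals = _as_values(data)
    rng = np.random.default_rng(seed)
    logger.info("building permutation null: itnum=%d seed=%d", itnum, seed)
    iu = np.triu_indices(vals.shape[0], k=1)
    pools = []
    for _ in range(itnum):
        perm = rng.permuted(vals, axis=1)
        pools.append(_mi_from_copula(copula_transform(perm))[iu])
    return NullModel(np.concatenate(pools), itnum, seed)


def mi_pvalues(mim: MIMatrix, null: NullModel) -> np.ndarray:
    """Empirical p-values with add-one smoothing:
    p = (1 + #{null >= observed}) / (|null| + 1), so p is always > 0."""
    null_sorted = null.null_values
    n_null = null_sorted.size
    counts = n_null - np.searchsorted(null_sorted, mim.values, side="left")
    p = (1.0 + counts) / (n_null + 1.0)
    np.fill_diagonal(p, 1.0)
    return p


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    Supported: BH, bonferroni, BY, hochberg, holm. "hommel" is accepted as an
    alias resolving to hochberg (with a warning).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "hommel":
        warnings.warn(
            "'hommel' is resolved to the hochberg step-up procedure",
            stacklevel=2,
        )
        method = "hochberg"
    if method not in _MTC_METHODS:
        raise ValueError(
            f"unknown MTC method {method!r}; options: "
            f"{sorted(_MTC_METHODS)} (+ 'hommel' alias)"
        )
    if p.size == 0:
        return p.copy()
    return multipletests(p, method=_MTC_METHODS[method])[1]


def significance_mask(
    mim: MIMatrix,
    mode: str = "cutoff",
    *,
    alpha: float = 0.01,
    cutoff_mi: float = 0.0,
    mtc_method: str | None = "BH",
    itnum: int = 5,
    seed: int | None = None,
    data=None,
) -> SignificanceMask:
    """Step-1 elimination of non-significant gene pairs.

    ``cutoff`` keeps MI > cutoff_mi; ``justp`` keeps permutation p < alpha;
    ``MTC`` keeps adjusted p < alpha. The permutation modes need the original
    ``data`` plus ``seed``.
    """
    mode_norm = mode.lower()
    if mode_norm not in MODES:
        raise ValueError(f"unknown mode {mode!r}; options: cutoff, justp, MTC")
    params = {"mode": mode_norm, "alpha": alpha}
    if mode_norm == "cutoff":
        if cutoff_mi is None:
            raise ValueError("mode 'cutoff' requires the dependent parameter 'cutoff_mi'")
        params["cutoff_mi"] = cutoff_mi
        mask = mim.values > cutoff_mi
    else:
        if data is None:
            raise ValueError(f"mode {mode!r} requires the dependent parameter 'data'")
        if seed is None:
            raise ValueError(f"mode {mode!r} requires the dependent parameter 'seed'")
        null = build_null(data, itnum, seed)
        p = mi_pvalues(mim, null)
        params.update(itnum=itnum, seed=seed)
        if mode_norm == "justp":
            mask = p < alpha
        else:
            if mtc_method is None:
                raise ValueError("mode 'MTC' requires the dependent parameter 'mtc_method'")
            params["mtc_method"] = mtc_method
            iu = np.triu_indices(len(mim.gene_ids), k=1)
            adj = adjust_pvalues(p[iu], mtc_method)
            mask = np.zeros_like(p, dtype=bool)
            mask[iu] = adj < alpha
            mask = mask | mask.T
    mask = mask & mask.T  # cutoff/justp grids are already symmetric; keep it explicit
    return SignificanceMask(list(mim.gene_ids), mask, mode_norm, params)
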
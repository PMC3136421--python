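"""Steady-state expression simulator with Hill kinetics and lognormal noise.

Given a signed directed network, each sample draws independent activation
levels for the input genes (in-degree zero) and propagates them through
Hill-type regulation functions: activators multiply the target's output by a
saturating increasing term, repressors by the complementary decreasing term.
Acyclic networks are evaluated exactly in topological order; cyclic ones by a
damped fixed-point iteration. Multiplicative lognormal noise — Gaussian on
the log scale — is applied to every value, preserving positivity.

Kinetic parameters (interaction strength, Hill cooperativity, basal level)
are redrawn per dataset so that an ensemble of datasets mimics the biological
variability of a population of similar organisms regulated by one network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .networks import ACTIVATOR, DirectedNetwork, Edge, NetworkError

logger = logging.getLogger(__name__)

# Documented kinetic-parameter ranges (uniform draws).
STRENGTH_RANGE = (1.0, 5.0)      # interaction strength s; half-saturation K = 1/(1+s)
COOPERATIVITY_RANGE = (1.0, 3.0)  # Hill coefficient
BASAL_RANGE = (0.05, 0.2)         # basal expression level
DEFAULT_NOISE_SD = 0.1            # sd of the Gaussian on the log scale


class SimulationError(RuntimeError):
    """Raised when the cyclic fixed-point iteration fails to converge."""


@dataclass
class KineticModel:
    """One draw of the kinetic parameters governing a network's dynamics."""

    strength: dict[Edge, float]
    cooperativity: dict[Edge, float]
    basal: dict[str, float]
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ExpressionMatrix:
    """Genes x samples grid of strictly positive expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 2:
            raise ValueError("at least 2 samples are required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values <= 0):
            raise ValueError("expression values must be strictly positive")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class Ensemble:
    """A collection of datasets simulated from one network under resampled
    kinetics; the unit of the population-level performance analysis."""

    datasets: list[ExpressionMatrix]
    network: DirectedNetwork
    seeds: list[tuple[int, int]]
    kinetics: list[KineticModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("ensemble must contain at least one dataset")
        ref = self.datasets[0]
        for d in self.datasets:
            if d.gene_ids != ref.gene_ids or d.n_samples != ref.n_samples:
                raise ValueError("ensemble datasets must share genes and sample count")


def _require_signed(net: DirectedNetwork) -> None:
    if not net.is_signed:
        raise NetworkError(
            "network edges are unsigned; run assign_edge_signs before simulating"
        )


def draw_kinetics(
    net: DirectedNetwork, seed: int, noise_sd: float = DEFAULT_NOISE_SD
) -> KineticModel:
    """Draw one kinetic model: strength and cooperativity per edge, basal
    level per gene, from the documented uniform ranges."""
    _require_signed(net)
    rng = np.random.default_rng(seed)
    edges = net.sorted_edges()
    strength = dict(zip(edges, rng.uniform(*STRENGTH_RANGE, len(edges))))
    coop = dict(zip(edges, rng.uniform(*COOPERATIVITY_RANGE, len(edges))))
    basal = dict(zip(net.nodes, rng.uniform(*BASAL_RANGE, net.n_genes)))
    return KineticModel(strength, coop, basal, noise_sd)


def add_lognormal_noise(values: np.ndarray, noise_sd: float, seed: int) -> np.ndarray:
    """Multiply each value by exp(eps), eps ~ Normal(0, noise_sd^2)."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("lognormal noise requires strictly positive values")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return values.copy()
    rng = np.random.default_rng(seed)
    return values * np.exp(rng.normal(0.0, noise_sd, values.shape))


def _hill(x: np.ndarray, k: float, c: float) -> np.ndarray:
    xc = np.power(x, c)
    return xc / (xc + k**c)


def simulate_steady_state(
    net: DirectedNetwork,
    kin: KineticModel,
    n_samples: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-8,
    damping: float = 0.5,
) -> ExpressionMatrix:
    """Simulate ``n_samples`` independent steady states of the network.

    Input genes (in-degree 0) receive i.i.d. Uniform(0,1) activation levels
    per sample. A regulated gene g with basal level b takes the value

        x_g = [ b + (1 - b) * prod_act h(x_u) * prod_rep (1 - h(x_u)) ] * e_g,

    where h(x) = x^c / (x^c + K^c) is the Hill function of the incoming edge
    with half-saturation K = 1/(1+strength) and cooperativity c, and
    e_g = exp(eps_g), eps_g ~ Normal(0, noise_sd^2), is the gene's
    multiplicative lognormal noise factor (one draw per gene and sample;
    input genes carry one too). The noise is biological, not observational:
    targets read the *noisy* expression of their regulators, so dependence
    attenuates with graph distance. Acyclic networks are evaluated exactly in
    topological order; otherwise a damped fixed-point iteration runs from the
    basal levels with the noise factors held fixed.
    """
    _require_signed(net)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    idx = net.index()
    n = net.n_genes
    in_edges: dict[str, list[Edge]] = {g: [] for g in net.nodes}
    for e in net.sorted_edges():
        in_edges[e[1]].append(e)

    x = np.empty((n, n_samples))
    inputs = [g for g in net.nodes if not in_edges[g]]
    regulated = [g for g in net.nodes if in_edges[g]]
    input_levels = {g: rng.random(n_samples) for g in inputs}
    if kin.noise_sd > 0:
        noise = np.exp(rng.normal(0.0, kin.noise_sd, (n, n_samples)))
    else:
        noise = np.ones((n, n_samples))
    for g in inputs:
        x[idx[g]] = input_levels[g] * noise[idx[g]]

    def regulated_value(g: str, state: np.ndarray) -> np.ndarray:
        prod = np.ones(n_samples)
        for e in in_edges[g]:
            u = state[idx[e[0]]]
            k = 1.0 / (1.0 + kin.strength[e])
            h = _hill(u, k, kin.cooperativity[e])
            prod = prod * (h if net.signs[e] == ACTIVATOR else 1.0 - h)
        b = kin.basal[g]
        return (b + (1.0 - b) * prod) * noise[idx[g]]

    if net.is_acyclic():
        for g in net.topological_order():
            if in_edges[g]:
                x[idx[g]] = regulated_value(g, x)
    else:
        for g in regulated:
            x[idx[g]] = kin.basal[g]
        for _ in range(max_iter):
            delta = 0.0
            new = x.copy()
            for g in regulated:
                target = regulated_value(g, x)
                new[idx[g]] = (1.0 - damping) * x[idx[g]] + damping * target
                delta = max(delta, float(np.max(np.abs(new[idx[g]] - x[idx[g]]))))
            x = new
            if delta < tol:
                break
        else:
            raise SimulationError(
                f"fixed-point iteration did not converge within {max_iter} iterations"
            )
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    return ExpressionMatrix(list(net.nodes), sample_ids, x)


def generate_ensemble(
    net: DirectedNetwork,
    n_datasets: int,
    n_samples: int,
    master_seed: int,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> Ensemble:
    """Simulate ``n_datasets`` datasets, redrawing the kinetic model each time.

    The master seed drives a generator from which one (kinetics, simulation)
    seed pair per dataset is drawn in dataset order, so ensembles are
    reproducible and the per-dataset streams independent.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    _require_signed(net)
    rng = np.random.default_rng(master_seed)
    seed_pairs = rng.integers(0, 2**31 - 1, size=(n_datasets, 2))
    datasets, kinetics, seeds = [], [], []
    for kin_seed, sim_seed in seed_pairs:
        logger.info("ensemble dataset seeds: kinetics=%d simulation=%d", kin_seed, sim_seed)
        kin = draw_kinetics(net, int(kin_seed), noise_sd)
        datasets.append(simulate_steady_state(net, kin, n_samples, int(sim_seed)))
        kinetics.append(kin)
        seeds.append((int(kin_seed), int(sim_seed)))
    return Ensemble(datasets, net, seeds, kinetics)
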
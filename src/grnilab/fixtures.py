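"""Small named fixtures with analytically known properties.

Each fixture writes a signed true network, a simulated expression matrix and
an ``expectations.json`` recording the properties the fixture was built to
exhibit (motif counts, leaf edges, a separating MI threshold). Used by the
test suite and handy as minimal worked inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .io import write_expression, write_network
from .networks import ACTIVATOR, REPRESSOR, DirectedNetwork
from .simulate import ExpressionMatrix, draw_kinetics, simulate_steady_state

FIXTURES = ("tiny-chain", "tiny-star", "ffl", "separable-mi")


def _simulated(net: DirectedNetwork, seed: int, n_samples: int = 50) -> ExpressionMatrix:
    kin = draw_kinetics(net, seed, noise_sd=0.1)
    return simulate_steady_state(net, kin, n_samples, seed + 1)


def make_fixture(name: str, seed: int, outdir) -> dict:
    """Write the named fixture into ``outdir``; returns its expectations."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "tiny-chain":
        net = DirectedNetwork(
            ["A", "B", "C"],
            {("A", "B"), ("B", "C")},
            {("A", "B"): ACTIVATOR, ("B", "C"): REPRESSOR},
        )
        expectations = {
            "motif_counts": {"chain": 1, "collider": 0, "fork": 0, "triangle": 0},
            "leaf_edges": [["B", "C"]],
        }
        data = _simulated(net, seed)
    elif name == "tiny-star":
        net = DirectedNetwork(
            ["A", "B", "C", "D"],
            {("B", "A"), ("B", "C"), ("B", "D")},
            {("B", "A"): ACTIVATOR, ("B", "C"): ACTIVATOR, ("B", "D"): REPRESSOR},
        )
        expectations = {
            "motif_counts": {"chain": 0, "collider": 0, "fork": 3, "triangle": 0},
            "leaf_edges": [["B", "A"], ["B", "C"], ["B", "D"]],
        }
        data = _simulated(net, seed)
    elif name == "ffl":
        net = DirectedNetwork(
            ["A", "B", "C"],
            {("A", "B"), ("A", "C"), ("B", "C")},
            {("A", "B"): ACTIVATOR, ("A", "C"): ACTIVATOR, ("B", "C"): REPRESSOR},
        )
        expectations = {
            "motif_counts": {"chain": 0, "collider": 0, "fork": 0, "triangle": 1},
            "leaf_edges": [],
        }
        data = _simulated(net, seed)
    elif name == "separable-mi":
        # Three tightly coupled gene pairs plus independent cross pairs:
        # true-pair MI is large, cross-pair MI near zero, so a threshold of
        # 0.5 nats separates them and RN/C3NET reach F = 1 there.
        rng = np.random.default_rng(seed)
        m = 200
        genes = [f"G{i + 1}" for i in range(6)]
        vals = np.empty((6, m))
        for k in range(3):
            x = rng.random(m) + 0.5
            vals[2 * k] = x
            vals[2 * k + 1] = x * np.exp(rng.normal(0, 0.05, m))
        data = ExpressionMatrix(genes, [f"S{i + 1}" for i in range(m)], vals)
        net = DirectedNetwork(
            genes,
            {("G1", "G2"), ("G3", "G4"), ("G5", "G6")},
            {
                ("G1", "G2"): ACTIVATOR,
                ("G3", "G4"): ACTIVATOR,
                ("G5", "G6"): REPRESSOR,
            },
        )
        expectations = {"separating_threshold": 0.5, "fscore_at_threshold": 1.0}
    else:
        raise ValueError(f"unknown fixture {name!r}; options: {FIXTURES}")

    write_network(net, outdir / f"{name}-network.tsv")
    write_expression(data, outdir / f"{name}-expression.tsv")
    with open(outdir / f"{name}-expectations.json", "w") as fh:
        json.dump(expectations, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return expectations
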
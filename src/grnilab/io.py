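"""Readers and writers for all artifact formats.

Plain-text formats only: expression matrices and edge lists as TSV, networks
additionally as SIF and GraphML, run configurations / provenance as JSON.
Numeric output uses 12 significant digits so write -> read round-trips are
exact to that precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .inference import InferredNetwork
from .mi import MIMatrix
from .networks import (
    DirectedNetwork,
    SIGN_TOKENS,
    TOKEN_OF_SIGN,
)
from .simulate import ExpressionMatrix

FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """Raised with a file position when an input file is malformed."""


# -- expression matrices ----------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def read_expression(path) -> ExpressionMatrix:
    """Parse a gene-major expression TSV (first column `gene`, one column per
    sample); duplicate ids, non-numeric cells and ragged rows are reported
    with their line number."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise ParseError(f"{path}:1: need a gene column plus >= 2 sample columns")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            gene = cells[0]
            if gene in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            seen.add(gene)
            try:
                rows.append([float(c) for c in cells[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            gene_ids.append(gene)
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows))


# -- networks ---------------------------------------------------------------

def write_network(net: DirectedNetwork, path, fmt: str = "tsv") -> None:
    """Write a true network as TSV (source/target/sign), SIF or GraphML.

    Isolated nodes appear as rows with an empty target (TSV) or single-token
    lines (SIF) so round-trips preserve the node set."""
    path = Path(path)
    connected = {n for e in net.edges for n in e}
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tsign\n")
            for e in net.sorted_edges():
                fh.write(f"{e[0]}\t{e[1]}\t{TOKEN_OF_SIGN.get(net.signs.get(e), '')}\n")
            for node in net.nodes:
                if node not in connected:
                    fh.write(f"{node}\t\t\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for e in net.sorted_edges():
                token = TOKEN_OF_SIGN.get(net.signs.get(e), "regulates")
                fh.write(f"{e[0]}\t{token}\t{e[1]}\n")
            for node in net.nodes:
                if node not in connected:
                    fh.write(f"{node}\n")
    elif fmt == "graphml":
        g = net.to_networkx()
        for u, v, d in g.edges(data=True):
            if d.get("sign") is None:
                d["sign"] = ""
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}; options: tsv, sif, graphml")


def _finish_network(nodes, edges, signs, path, lineno_of_edge) -> DirectedNetwork:
    try:
        return DirectedNetwork(nodes, edges, signs)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def read_network(path, fmt: str | None = None) -> DirectedNetwork:
    """Read a directed network from TSV or SIF (format inferred from the
    extension unless given)."""
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix.lower() == ".sif" else "tsv"
    nodes: list[str] = []
    seen: set[str] = set()
    edges: set[tuple[str, str]] = set()
    signs: dict[tuple[str, str], str] = {}

    def add_node(n: str) -> None:
        if n and n not in seen:
            seen.add(n)
            nodes.append(n)

    with open(path) as fh:
        lines = list(fh)
    start = 0
    if fmt == "tsv":
        if not lines or not lines[0].startswith("source"):
            raise ParseError(f"{path}:1: missing 'source<TAB>target<TAB>sign' header")
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if fmt == "tsv":
            if len(cells) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
            src, dst = cells[0], cells[1]
            token = cells[2] if len(cells) > 2 else ""
            if not dst:  # isolated-node row
                add_node(src)
                continue
        else:  # sif
            if len(cells) == 1:
                add_node(cells[0])
                continue
            if len(cells) != 3:
                raise ParseError(f"{path}:{lineno}: SIF rows have 1 or 3 columns")
            src, token, dst = cells
            if token == "regulates":
                token = ""
        if src == dst:
            raise ParseError(f"{path}:{lineno}: self-loop on {src!r}")
        if token and token not in SIGN_TOKENS:
            raise ParseError(f"{path}:{lineno}: unknown sign token {token!r}")
        add_node(src)
        add_node(dst)
        edges.add((src, dst))
        if token:
            signs[(src, dst)] = SIGN_TOKENS[token]
    return _finish_network(nodes, edges, signs, path, None)


def write_inferred(net: InferredNetwork, path, fmt: str = "tsv") -> None:
    """Write an inferred (undirected, MI-weighted) network."""
    path = Path(path)
    idx = {g: i for i, g in enumerate(net.gene_ids)}
    ordered = sorted(net.edges, key=lambda e: (idx[e[0]], idx[e[1]]))
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("geneA\tgeneB\tmi\n")
            for a, b in ordered:
                fh.write(f"{a}\t{b}\t{FLOAT_FMT % net.weights.get((a, b), float('nan'))}\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for a, b in ordered:
                fh.write(f"{a}\tmi\t{b}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.gene_ids)
        for a, b in ordered:
            g.add_edge(a, b, mi=float(net.weights.get((a, b), float("nan"))))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; options: tsv, sif, graphml")


def read_inferred(path) -> InferredNetwork:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    genes: list[str] = []
    seen: set[str] = set()
    edges, weights = set(), {}
    for _, row in df.iterrows():
        a, b = str(row["geneA"]), str(row["geneB"])
        for g in (a, b):
            if g not in seen:
                seen.add(g)
                genes.append(g)
        edges.add((a, b))
        weights[(a, b)] = float(row["mi"])
    return InferredNetwork(genes, edges, weights)


def write_colored_graphml(
    truth: DirectedNetwork, categories: dict[tuple[str, str], str], path
) -> None:
    """True network with the per-edge TPR color category as an attribute."""
    g = truth.to_networkx()
    for u, v, d in g.edges(data=True):
        d["color"] = categories.get((u, v), "")
        if d.get("sign") is None:
            d["sign"] = ""
    nx.write_graphml(g, path)


# -- MI matrices ------------------------------------------------------------

def write_mi_matrix(mim: MIMatrix, path) -> None:
    df = pd.DataFrame(mim.values, index=mim.gene_ids, columns=mim.gene_ids)
    df.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def read_mi_matrix(path) -> MIMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MIMatrix(list(df.index), df.to_numpy(dtype=float))


# -- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved parameters of one run, echoed to a JSON provenance sidecar.

    Defaults mirror the reference interface: alpha=0.01, methodstep1="cutoff",
    cutoff_mi=0, mtc_method="BH", itnum=5.
    """

    command: str = ""
    algorithm: str = "c3net"
    alpha: float = 0.01
    methodstep1: str = "cutoff"
    cutoff_mi: float = 0.0
    mtc_method: str = "BH"
    itnum: int = 5
    tolerance: float = 0.1
    s0: float = 0.0
    seed: int | None = None
    seeds: list | None = None
    ensemble_size: int | None = None
    sample_size: int | None = None
    paths: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
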
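"""Per-sample parenclitic networks.

Each sample is represented as a complete weighted graph on the locus panel:
nodes are CpG loci, and the edge between two loci carries the sample's
Mahalanobis deviation from the baseline mixture of that pair. Networks are
kept complete (no pruning) by default; an optional threshold can zero out
edges below a given weight.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy.spatial.distance import squareform

from .baseline import BaselineModel
from .exceptions import ParseError, ValidationError
from .io_qc import BetaMatrix

__all__ = ["ParencliticNetwork", "build_network", "build_networks",
           "write_network", "read_network"]


class ParencliticNetwork:
    """Symmetric non-negative weight matrix over the panel loci."""

    def __init__(self, sample_id: str, nodes, weights: np.ndarray):
        nodes = list(nodes)
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (len(nodes), len(nodes)):
            raise ValidationError(
                f"weight matrix shape {weights.shape} does not match "
                f"{len(nodes)} nodes")
        if not np.allclose(weights, weights.T):
            raise ValidationError("weight matrix must be symmetric")
        if np.any(np.diag(weights) != 0):
            raise ValidationError("weight matrix must have a zero diagonal")
        if np.any(weights < 0):
            raise ValidationError("edge weights must be non-negative")
        self.sample_id = sample_id
        self.nodes = nodes
        self.weights = weights

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def condensed(self) -> np.ndarray:
        """Upper-triangle weights in ``numpy.triu_indices`` order."""
        return squareform(self.weights, checks=False)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(sample_id=self.sample_id)
        g.add_nodes_from(self.nodes)
        iu, ju = np.triu_indices(self.n_nodes, 1)
        for i, j in zip(iu, ju):
            g.add_edge(self.nodes[i], self.nodes[j], weight=float(self.weights[i, j]))
        return g

    def pruned(self, epsilon: float) -> "ParencliticNetwork":
        """Copy with weights below ``epsilon`` set to zero."""
        w = self.weights.copy()
        w[w < epsilon] = 0.0
        return ParencliticNetwork(self.sample_id, self.nodes, w)


def build_network(sample_betas, baseline: BaselineModel,
                  sample_id: str = "") -> ParencliticNetwork:
    """One sample's deviation graph from its panel beta values.

    ``sample_betas`` may be a mapping / Series keyed by locus or an array
    already aligned to the panel order.
    """
    panel = list(baseline.panel.loci)
    if isinstance(sample_betas, pd.Series):
        sample_betas = sample_betas.to_dict()
    if isinstance(sample_betas, dict):
        missing = [p for p in panel if p not in sample_betas]
        if missing:
            raise ValidationError(f"sample lacks beta values for loci: {missing[:10]}")
        vec = np.array([sample_betas[p] for p in panel], dtype=np.float64)
    else:
        vec = np.asarray(sample_betas, dtype=np.float64)
    if np.isnan(vec).any():
        bad = [panel[i] for i in np.where(np.isnan(vec))[0]]
        raise ValidationError(f"missing beta values at loci: {bad[:10]}")
    w = squareform(baseline.edge_weights(vec), checks=False)
    return ParencliticNetwork(sample_id, panel, w)


def build_networks(beta: BetaMatrix, baseline: BaselineModel,
                   sample_ids=None) -> list[ParencliticNetwork]:
    """Networks for each requested sample of a beta matrix."""
    ids = list(sample_ids) if sample_ids is not None else beta.sample_ids
    frame = beta.frame.loc[list(baseline.panel.loci), ids]
    return [build_network(frame[s].to_numpy(), baseline, sample_id=s) for s in ids]


# ---------------------------------------------------------------------------
# text round trips
# ---------------------------------------------------------------------------

def write_network(net: ParencliticNetwork, path, format: str | None = None) -> None:
    fmt = format or ("graphml" if str(path).endswith(".graphml") else "edgelist")
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write(f"# sample_id: {net.sample_id}\n")
            fh.write(f"# nodes: {','.join(net.nodes)}\n")
            iu, ju = np.triu_indices(net.n_nodes, 1)
            for i, j in zip(iu, ju):
                fh.write(f"{net.nodes[i]}\t{net.nodes[j]}\t{net.weights[i, j]:.12g}\n")
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path, format: str | None = None) -> ParencliticNetwork:
    fmt = format or ("graphml" if str(path).endswith(".graphml") else "edgelist")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        nodes = list(g.nodes())
        index = {v: i for i, v in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for a, b, data in g.edges(data=True):
            w[index[a], index[b]] = w[index[b], index[a]] = float(data.get("weight", 0.0))
        return ParencliticNetwork(str(g.graph.get("sample_id", "")), nodes, w)
    if fmt != "edgelist":
        raise ValidationError(f"unknown network format {format!r}")

    sample_id, nodes, seen = "", None, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                key = key.strip()
                if key == "sample_id":
                    sample_id = value.strip()
                elif key == "nodes":
                    nodes = value.strip().split(",")
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, wtxt = parts
            try:
                wv = float(wtxt)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad weight {wtxt!r}") from exc
            key = (a, b) if a <= b else (b, a)
            if key in seen and seen[key] != wv:
                raise ParseError(
                    f"{path}:{lineno}: conflicting duplicate edge {a}-{b}")
            seen[key] = wv
    if nodes is None:
        nodes = sorted({n for pair in seen for n in pair})
    index = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for (a, b), wv in seen.items():
        if a not in index or b not in index:
            raise ParseError(f"{path}: edge references unknown node {a!r} or {b!r}")
        w[index[a], index[b]] = w[index[b], index[a]] = wv
    return ParencliticNetwork(sample_id, nodes, w)
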
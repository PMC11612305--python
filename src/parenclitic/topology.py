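"""Topological descriptors of parenclitic networks.

All features are per-node and permutation-equivariant in node labels.
Path-based features (betweenness, eccentricity) treat the Mahalanobis edge
weight directly as a length: a larger deviation makes a longer edge. The
weighted node degree — the feature the classifier consumes — is simply the
sum of incident edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .exceptions import ConvergenceError, ValidationError
from .networks import ParencliticNetwork

__all__ = [
    "node_degree", "degree_centrality", "eigenvector_centrality",
    "betweenness_centrality", "second_order_centrality", "eccentricity",
    "FeatureMatrix", "feature_matrix", "feature_group_test", "FEATURES",
]


def node_degree(net: ParencliticNetwork) -> pd.Series:
    """Weighted degree: sum of edge weights incident to each node."""
    return pd.Series(net.weights.sum(axis=1), index=net.nodes, name="degree")


def degree_centrality(net: ParencliticNetwork, presence_threshold: float = 0.0) -> pd.Series:
    """Fraction of other nodes connected by an edge heavier than the threshold.

    On a complete positive-weight graph the textbook definition is
    identically 1; the threshold makes the feature informative by treating
    near-zero deviations as absent edges.
    """
    if presence_threshold < 0:
        raise ValidationError("presence_threshold must be non-negative")
    counts = (net.weights > presence_threshold).sum(axis=1)
    return pd.Series(counts / (net.n_nodes - 1), index=net.nodes, name="degree_centrality")


def eigenvector_centrality(net: ParencliticNetwork, tol: float = 1e-10,
                           max_iter: int = 1000) -> pd.Series:
    """Non-negative unit-norm dominant eigenvector of the weight matrix."""
    w = net.weights
    x = np.full(net.n_nodes, 1.0 / np.sqrt(net.n_nodes))
    for it in range(1, max_iter + 1):
        y = w @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ConvergenceError("weight matrix is zero; eigenvector undefined")
        y /= norm
        if np.linalg.norm(y - x) < tol:
            return pd.Series(y, index=net.nodes, name="eigenvector")
        x = y
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations")


def _length_matrix(net: ParencliticNetwork) -> np.ndarray:
    w = net.weights
    off = ~np.eye(net.n_nodes, dtype=bool)
    if np.any(w[off] <= 0):
        raise ValidationError(
            "zero-weight edges make path lengths ill-posed; prune them first")
    return w


def betweenness_centrality(net: ParencliticNetwork) -> pd.Series:
    """Pair-normalised weighted shortest-path betweenness (Brandes)."""
    _length_matrix(net)
    g = net.to_networkx()
    bc = nx.betweenness_centrality(g, weight="weight", normalized=True)
    return pd.Series([bc[v] for v in net.nodes], index=net.nodes, name="betweenness")


def eccentricity(net: ParencliticNetwork) -> pd.Series:
    """Maximum weighted shortest-path distance from each node to any other."""
    lengths = _length_matrix(net)
    dist = shortest_path(lengths, method="D", directed=False)
    if np.isinf(dist).any():
        raise ValidationError("graph is disconnected; eccentricity undefined")
    return pd.Series(dist.max(axis=1), index=net.nodes, name="eccentricity")


def second_order_centrality(net: ParencliticNetwork) -> pd.Series:
    """Standard deviation of return times of the stationary random walk.

    The walk moves with probability proportional to edge weight. For node v
    with stationary probability pi_v and fundamental matrix
    Z = (I - P + 1 pi^T)^-1, the return time T_v has E[T_v] = 1/pi_v and
    E[T_v^2] = (2 Z_vv / pi_v - 1) / pi_v, computed here in closed form.
    """
    w = net.weights
    deg = w.sum(axis=1)
    if np.any(deg == 0):
        raise ValidationError("isolated node: the random walk is not irreducible")
    n_comp, _ = connected_components((w > 0).astype(np.int8), directed=False)
    if n_comp > 1:
        raise ValidationError("graph is disconnected; return times undefined")
    p = w / deg[:, None]
    pi = deg / deg.sum()
    z = np.linalg.inv(np.eye(net.n_nodes) - p + np.outer(np.ones(net.n_nodes), pi))
    m2 = (2.0 * np.diag(z) / pi - 1.0) / pi
    var = m2 - (1.0 / pi) ** 2
    return pd.Series(np.sqrt(np.clip(var, 0.0, None)), index=net.nodes,
                     name="second_order")


FEATURES = {
    "degree": node_degree,
    "degree_centrality": degree_centrality,
    "eigenvector": eigenvector_centrality,
    "betweenness": betweenness_centrality,
    "second_order": second_order_centrality,
    "eccentricity": eccentricity,
}


@dataclass
class FeatureMatrix:
    """Samples x loci matrix of one named topological feature."""

    name: str
    frame: pd.DataFrame  # rows = samples, columns = panel loci
    params: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def loci(self) -> list[str]:
        return self.frame.columns.tolist()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# feature: {self.name}\n")
            for key in sorted(self.params):
                fh.write(f"# {key}: {self.params[key]}\n")
            self.frame.to_csv(fh, sep="\t", float_format="%.10g")

    @classmethod
    def read(cls, path) -> "FeatureMatrix":
        name, params, header = "", {}, []
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].partition(":")
                if key.strip() == "feature":
                    name = value.strip()
                else:
                    params[key.strip()] = value.strip()
                pos = fh.tell()
            fh.seek(pos)
            frame = pd.read_csv(fh, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        return cls(name=name, frame=frame, params=params)


def feature_matrix(networks, feature_name: str, params: dict | None = None) -> FeatureMatrix:
    """Assemble one feature across samples: one row per network, panel order."""
    if feature_name not in FEATURES:
        raise ValidationError(
            f"unknown feature {feature_name!r}; choose from {sorted(FEATURES)}")
    networks = list(networks)
    if not networks:
        raise ValidationError("no networks supplied")
    nodes = networks[0].nodes
    for net in networks:
        if net.nodes != nodes:
            raise ValidationError(
                f"network {net.sample_id!r} uses a different locus panel")
    func = FEATURES[feature_name]
    params = dict(params or {})
    rows = [func(net, **params) for net in networks]
    frame = pd.DataFrame(
        [r.to_numpy() for r in rows],
        index=pd.Index([n.sample_id for n in networks], name="sample_id"),
        columns=nodes,
    )
    return FeatureMatrix(name=feature_name, frame=frame, params=params)


def feature_group_test(fm: FeatureMatrix, labels) -> pd.DataFrame:
    """Two-sided Mann-Whitney test per locus with Benjamini-Hochberg control.

    ``labels`` maps each sample to aggressive / non_aggressive (a Series,
    mapping, or aligned array). Returns a DataFrame indexed by locus with
    columns ``p`` and ``q``; loci with all-tied values get p = 1.
    """
    lab = pd.Series(labels)
    lab = lab.reindex(fm.frame.index) if set(fm.frame.index) <= set(lab.index) else lab
    if len(lab) != len(fm.frame):
        raise ValidationError("labels do not align with the feature matrix rows")
    pos = fm.frame.loc[(lab == "aggressive").to_numpy()].to_numpy()
    neg = fm.frame.loc[(lab == "non_aggressive").to_numpy()].to_numpy()
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.vstack([pos, neg])
    tied = np.ptp(combined, axis=0) == 0
    p = np.ones(combined.shape[1])
    if (~tied).any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = mannwhitneyu(pos[:, ~tied], neg[:, ~tied], axis=0,
                               alternative="two-sided", method="auto")
        p[~tied] = np.nan_to_num(res.pvalue, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"p": p, "q": q},
                        index=pd.Index(fm.loci, name="locus"))
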
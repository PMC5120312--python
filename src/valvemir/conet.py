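"""Thresholded Pearson co-expression graph and Markov clustering (MCL).

The graph is built over a chosen feature subset (typically the
differentially expressed miRNAs); an edge joins two features whose sample
Pearson correlation passes the threshold, and the signed correlation is kept
as the edge weight. Clustering uses Markov Clustering: alternate expansion
(matrix power of the column-stochastic transition matrix, simulating random
-walk flow) and inflation (entrywise power followed by column
renormalization, which strengthens intra-cluster flow), until the matrix
stops changing. Inflation controls granularity; 2.0 is the conventional
default. Transition probabilities must be non-negative, so edge weights
enter the matrix as magnitudes; self-loops of weight 1 are added before
normalization to damp oscillations on bipartite-like structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationGraph:
    graph: nx.Graph
    threshold: float
    mode: str  # "positive" | "absolute"
    dropped_features: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


@dataclass
class MclClusters:
    assignment: dict[str, int]  # node -> cluster id (1-based)
    inflation: float
    expansion: int
    prune_below: float
    max_iter: int
    tol: float
    converged: bool
    iterations: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["node", "cluster_id"]
        )

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))


def correlation_graph(
    x: ExpressionMatrix,
    features: list[str] | None = None,
    threshold: float = 0.5,
    mode: str = "positive",
) -> CorrelationGraph:
    """Build the thresholded Pearson correlation graph.

    ``mode="positive"`` keeps edges with ``r > threshold``;
    ``mode="absolute"`` keeps ``|r| > threshold``. Edge weights are the
    signed correlations either way. Constant (zero-variance) features are
    dropped with a warning, never an error.
    """
    if mode not in ("positive", "absolute"):
        raise ValidationError(f"unknown correlation mode {mode!r}")
    if x.n_samples < 3:
        raise ValidationError("need at least 3 samples for correlation")
    feats = list(features) if features is not None else x.feature_ids
    missing = set(feats) - set(x.feature_ids)
    if missing:
        raise ValidationError(f"features absent from matrix: {sorted(missing)}")

    sub = x.values.loc[feats].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    dropped = [f for f, s in zip(feats, sd) if s == 0]
    if dropped:
        logger.warning("dropping %d constant feature(s): %s", len(dropped), dropped)
    keep = [i for i, s in enumerate(sd) if s > 0]
    feats = [feats[i] for i in keep]
    sub = sub[keep]

    g = nx.Graph()
    g.add_nodes_from(feats)
    if len(feats) >= 2:
        r = np.corrcoef(sub)
        iu, ju = np.triu_indices(len(feats), k=1)
        w = r[iu, ju]
        passes = w > threshold if mode == "positive" else np.abs(w) > threshold
        for i, j, rv in zip(iu[passes], ju[passes], w[passes]):
            g.add_edge(feats[i], feats[j], weight=float(rv))
    return CorrelationGraph(g, threshold, mode, dropped)


def mcl(
    graph: CorrelationGraph | nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> MclClusters:
    """Markov Clustering of a weighted undirected graph.

    Iterates expansion (matrix power ``expansion``) and inflation (entrywise
    power ``inflation`` with column renormalization), pruning entries below
    ``prune_below``, until the maximum column-wise change falls below
    ``tol``. Clusters are read off the attractors (rows with nonzero
    diagonal mass); each node joins the attractor receiving the largest flow
    from it, and attractors that exchange flow are merged into one cluster.
    Deterministic given the node order; cluster ids are assigned 1..k in
    order of each cluster's lexicographically smallest member.
    """
    g = graph.graph if isinstance(graph, CorrelationGraph) else graph
    nodes = list(g.nodes)
    if not nodes:
        raise ValidationError("MCL requires a non-empty graph")
    if inflation <= 1:
        raise ValidationError("inflation must exceed 1")

    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = abs(float(data.get("weight", 1.0)))
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    np.fill_diagonal(m, 1.0)  # self-loops of weight 1
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m /= m.sum(axis=0, keepdims=True)
        m[m < prune_below] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)

    # attractors: rows with nonzero diagonal mass
    attractors = np.flatnonzero(np.diag(m) > prune_below)
    if attractors.size == 0:  # pathological; treat max-row nodes as attractors
        attractors = np.arange(n)
    # merge attractors that exchange flow into attractor systems
    asys = nx.Graph()
    asys.add_nodes_from(attractors.tolist())
    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > 0 or m[j, i] > 0):
                asys.add_edge(int(i), int(j))
    system_of: dict[int, int] = {}
    for comp_id, comp in enumerate(nx.connected_components(asys)):
        for a in comp:
            system_of[a] = comp_id

    raw: dict[str, int] = {}
    for j, node in enumerate(nodes):
        mass = m[attractors, j]
        if mass.max() <= 0:
            # no attractor reaches this node (isolated after pruning): own system
            raw[node] = -1 - j
        else:
            best = attractors[int(np.argmax(mass))]
            raw[node] = system_of[int(best)]

    # relabel clusters 1..k by smallest member node (sorted order)
    members: dict[int, list[str]] = {}
    for node, c in raw.items():
        members.setdefault(c, []).append(node)
    ordered = sorted(members.values(), key=lambda ms: min(str(v) for v in ms))
    assignment = {
        node: cid for cid, ms in enumerate(ordered, start=1) for node in ms
    }
    return MclClusters(
        assignment=assignment,
        inflation=inflation,
        expansion=expansion,
        prune_below=prune_below,
        max_iter=max_iter,
        tol=tol,
        converged=converged,
        iterations=iterations,
    )


def degree_table(graph: CorrelationGraph | nx.Graph) -> pd.DataFrame:
    """Per-node degree counts, sorted by decreasing degree then node id."""
    g = graph.graph if isinstance(graph, CorrelationGraph) else graph
    df = pd.DataFrame(
        [(v, d) for v, d in g.degree()], columns=["node", "degree"]
    )
    return df.sort_values(
        ["degree", "node"], ascending=[False, True], ignore_index=True
    )


def edge_list(graph: CorrelationGraph) -> pd.DataFrame:
    rows = [
        (min(u, v), max(u, v), data["weight"])
        for u, v, data in graph.graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).sort_values(
        ["node_a", "node_b"], ignore_index=True
    )
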
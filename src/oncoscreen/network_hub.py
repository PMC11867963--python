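"""Interaction-network construction and random-walk hub scoring.

Hub genes are prioritized by an energy-diffusion random walk with restart
(RWR): every node starts with one unit of energy, and at each step a
(1 - r) fraction of each node's energy flows along its (weighted) edges
while an r fraction is re-injected at the node's own starting
distribution:

    e  <-  (1 - r) * P @ e  +  r * e0,      e0 = 1 for every node,

where P is the column-normalized weighted adjacency matrix. Columns of
degree-zero nodes act as the identity, so isolated nodes simply retain
their unit of energy. Because P is column-stochastic the total energy is
conserved at the node count, and the iteration converges to the unique
fixed point of (I - (1-r) P) e = r e0 for any restart r in (0, 1]. The
steady-state energy per node is the random-walk score; pure diffusion
(r = 0) is excluded because it oscillates on bipartite graphs and reduces
to weighted-degree centrality elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .types import GeneSet

log = logging.getLogger(__name__)

__all__ = ["RandomWalkResult", "build_network", "random_walk_scores", "rank_hub_genes"]


@dataclass(frozen=True)
class RandomWalkResult:
    scores: pd.Series  # steady-state energy per node
    iterations: int
    residual: float  # final L1 change
    restart: float
    converged: bool


def build_network(
    edges: pd.DataFrame | nx.Graph | Iterable[tuple[str, str, float]],
    restrict_to: GeneSet | Sequence[str] | None = None,
) -> nx.Graph:
    """Build an undirected weighted graph, optionally restricted to a node set.

    ``edges`` may be a graph, an interaction DataFrame (regulator_id /
    target_id / score columns), or (u, v, weight) triples. When
    ``restrict_to`` is given, only edges between members are kept but every
    member appears as a node, so candidates without interactions are
    retained as isolated nodes (and reported in the log).
    """
    graph = nx.Graph()
    if isinstance(edges, nx.Graph):
        pairs = [(u, v, d.get("weight", 1.0)) for u, v, d in edges.edges(data=True)]
        if not pairs and restrict_to is None:
            raise DataError("empty edge input")
        nodes = list(edges.nodes)
    elif isinstance(edges, pd.DataFrame):
        if edges.shape[0] == 0:
            raise DataError("empty edge input")
        score = edges["score"] if "score" in edges.columns else pd.Series(1.0, index=edges.index)
        score = pd.to_numeric(score, errors="coerce").fillna(1.0)
        pairs = list(zip(edges["regulator_id"], edges["target_id"], score))
        nodes = []
    else:
        pairs = [(u, v, w) for u, v, w in edges]
        if not pairs:
            raise DataError("empty edge input")
        nodes = []

    allowed = None
    if restrict_to is not None:
        members = restrict_to.members if isinstance(restrict_to, GeneSet) else tuple(restrict_to)
        allowed = set(members)
        graph.add_nodes_from(members)
    graph.add_nodes_from(n for n in nodes if allowed is None or n in allowed)
    for u, v, w in pairs:
        if u == v:
            continue
        if allowed is not None and (u not in allowed or v not in allowed):
            continue
        w = float(w)
        if graph.has_edge(u, v):
            graph[u][v]["weight"] = max(graph[u][v]["weight"], w)
        else:
            graph.add_edge(u, v, weight=w)
    isolated = list(nx.isolates(graph))
    if isolated:
        log.info(
            "network: %d of %d nodes isolated (%s%s)",
            len(isolated),
            graph.number_of_nodes(),
            ", ".join(sorted(isolated)[:5]),
            "..." if len(isolated) > 5 else "",
        )
    if graph.number_of_nodes() == 0:
        raise DataError("network has no nodes")
    return graph


def random_walk_scores(
    network: nx.Graph,
    restart: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> RandomWalkResult:
    """Iterate the restart diffusion to its steady state.

    Returns per-node energies summing to the node count (conservation).
    Non-convergence within ``max_iter`` returns ``converged=False`` rather
    than raising.
    """
    if not (0 < restart <= 1):
        raise ConfigurationError(f"restart must lie in (0, 1], got {restart}")
    if network.number_of_nodes() == 0:
        raise DataError("empty network")
    nodes = list(network.nodes)
    n = len(nodes)
    adj = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    col_sums = adj.sum(axis=0)
    p = np.zeros_like(adj)
    nonzero = col_sums > 0
    p[:, nonzero] = adj[:, nonzero] / col_sums[nonzero]
    p[np.ix_(~nonzero, ~nonzero)] = np.eye((~nonzero).sum())  # isolated nodes self-retain

    e0 = np.ones(n)
    e = e0.copy()
    residual = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        e_next = (1.0 - restart) * (p @ e) + restart * e0
        residual = float(np.abs(e_next - e).sum())
        e = e_next
        if residual < tol:
            break
    converged = residual < tol
    if not converged:
        log.warning("random walk did not converge in %d iterations (residual %.3g)", max_iter, residual)
    return RandomWalkResult(
        scores=pd.Series(e, index=pd.Index(nodes, name="gene"), name="rw_score"),
        iterations=iterations,
        residual=residual,
        restart=restart,
        converged=converged,
    )


def rank_hub_genes(result: RandomWalkResult) -> list[str]:
    """Nodes in descending score order, ties broken lexicographically."""
    s = result.scores
    order = sorted(s.index, key=lambda node: (-s[node], node))
    return order
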
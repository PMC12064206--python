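"""2-mode -> 1-mode projection of diary incidence onto activity networks.

The projection follows the affiliation-network recipe: each activity is a
person-indexed participation vector (binary, or minute-weighted), pairwise
cosine similarity between the vectors gives a dense symmetric matrix, and
an edge is kept when the similarity reaches the threshold ``tau``. Nodes
whose every similarity falls below the threshold remain in the graph as
isolates — the distribution indices report on them explicitly.

Activities with fewer than ``min_participants`` distinct participants
(default 2) are removed *before* projection; a single-participant column
carries no co-participation information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import networkx as nx
import numpy as np

from .diary_io import IncidenceMatrix

__all__ = [
    "ActivityNetwork",
    "cosine_similarity_matrix",
    "threshold_network",
    "project_to_network",
    "prune_inactive_nodes",
]


@dataclass
class ActivityNetwork:
    """Undirected weighted 1-mode network over activity nodes.

    Edge weights are the cosine similarities that survived thresholding;
    the node set is the post-filter activity universe, isolates included.
    """

    graph: nx.Graph
    threshold_used: float
    group_label: str = ""
    day_type: str = ""
    weighting: str = "binary"
    removed_low_participation: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def provenance(self) -> tuple[str, str, str]:
        return (self.group_label, self.day_type, self.weighting)

    def adjacency(self, weighted: bool = True) -> tuple[list[str], np.ndarray]:
        """Dense symmetric adjacency over sorted node labels."""
        labels = self.nodes
        mat = nx.to_numpy_array(self.graph, nodelist=labels, weight="weight" if weighted else None)
        return labels, mat

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def to_edgelist(self, path: str | Path) -> None:
        """Tab-separated weighted edge list: node_a, node_b, weight."""
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for a, b, w in sorted(self.graph.edges(data="weight")):
                fh.write(f"{a}\t{b}\t{w:.6f}\n")


def cosine_similarity_matrix(incidence: IncidenceMatrix,
                             weighting: str = "binary",
                             mode: str = "activity") -> tuple[list[str], np.ndarray]:
    """Pairwise cosine similarity between participation vectors.

    ``weighting`` selects binary or minute-weighted cells; ``mode``
    selects which side of the 2-mode matrix becomes the node set
    (``activity``, the default, or ``person``). Returns the node labels
    and a symmetric matrix in [0, 1] with a zero diagonal.
    """
    if weighting not in ("binary", "minutes"):
        raise ValueError(f"weighting must be 'binary' or 'minutes', got {weighting!r}")
    if mode not in ("activity", "person"):
        raise ValueError(f"mode must be 'activity' or 'person', got {mode!r}")
    cells = incidence.binary if weighting == "binary" else incidence.weights
    if mode == "activity":
        vectors, labels = cells.T, list(incidence.activities)
    else:
        vectors, labels = cells, list(incidence.persons)
    n = len(labels)
    if n == 0:
        return labels, np.zeros((0, 0))
    if n == 1:
        warnings.warn("single-node incidence: similarity matrix is 1x1 zero")
        return labels, np.zeros((1, 1))
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        # zero-participant columns/rows are dropped upstream; defend anyway
        norms = np.where(norms == 0, 1.0, norms)
    sim = (vectors @ vectors.T) / np.outer(norms, norms)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    np.fill_diagonal(sim, 0.0)
    return labels, sim


def threshold_network(labels: list[str], sim: np.ndarray, tau: float) -> nx.Graph:
    """Keep edges with similarity >= tau (strictly positive ones only)."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    g = nx.Graph()
    g.add_nodes_from(labels)
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    # >= with a float-noise allowance so that e.g. exactly-identical
    # participant sets (cosine 1.0 up to rounding) survive tau = 1
    keep = (sim[iu, ju] >= tau - 1e-12) & (sim[iu, ju] > 0.0)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(labels[i], labels[j], weight=float(sim[i, j]))
    return g


def project_to_network(incidence: IncidenceMatrix, tau: float = 0.3,
                       weighting: str = "binary", min_participants: int = 2,
                       mode: str = "activity") -> ActivityNetwork:
    """Project a 2-mode incidence matrix to a thresholded 1-mode network.

    Activity columns with fewer than ``min_participants`` participants are
    removed before the similarity computation; edges require cosine
    similarity >= ``tau`` (ties at exactly tau are kept; exact-zero
    similarities never become edges, even at tau = 0). Nodes with no
    surviving edge are retained as isolates.
    """
    if min_participants < 1:
        raise ValueError("min_participants must be >= 1")
    removed: list[str] = []
    if mode == "activity" and min_participants > 1 and not incidence.empty:
        counts = incidence.participant_counts()
        keep = counts >= min_participants
        removed = [a for a, k in zip(incidence.activities, keep) if not k]
        if removed:
            incidence = IncidenceMatrix(
                persons=incidence.persons,
                activities=[a for a, k in zip(incidence.activities, keep) if k],
                binary=incidence.binary[:, keep],
                weights=incidence.weights[:, keep],
                group_label=incidence.group_label,
                day_type=incidence.day_type,
            )
    labels, sim = cosine_similarity_matrix(incidence, weighting=weighting, mode=mode)
    graph = threshold_network(labels, sim, tau)
    return ActivityNetwork(
        graph=graph,
        threshold_used=tau,
        group_label=incidence.group_label,
        day_type=incidence.day_type,
        weighting=weighting,
        removed_low_participation=removed,
    )


def prune_inactive_nodes(net: ActivityNetwork, min_degree: int = 0,
                         min_centrality: float = float("inf")
                         ) -> tuple[ActivityNetwork, list[str]]:
    """Remove nodes below BOTH the degree and centrality cut-offs.

    Off by default in the pipeline: the distribution indices report
    isolated nodes, so isolates are normally kept for metric time. A
    cut-off left at its default never blocks the other one (min_degree=0
    removes nothing; min_centrality=inf defers entirely to the degree
    rule). Returns the pruned network and the removal log.
    """
    if min_degree < 0 or min_centrality < 0:
        raise ValueError("pruning thresholds must be >= 0")
    n = net.n_nodes
    removed = []
    for node in net.nodes:
        deg = net.graph.degree(node)
        cent = deg / (n - 1) if n > 1 else 0.0
        if deg < min_degree and cent < min_centrality:
            removed.append(node)
    graph = net.graph.copy()
    graph.remove_nodes_from(removed)
    pruned = ActivityNetwork(graph=graph, threshold_used=net.threshold_used,
                             group_label=net.group_label, day_type=net.day_type,
                             weighting=net.weighting,
                             removed_low_participation=list(net.removed_low_participation))
    return pruned, removed
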
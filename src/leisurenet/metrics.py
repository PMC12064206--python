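"""Network distribution indices and degree-centrality ranking.

Four distribution indices summarise one activity network:

* **density** — realised edges over possible edges, 2E / (N(N-1));
* **inclusiveness** — fraction of nodes with at least one edge,
  (N - isolates) / N;
* **mean distance** — average unweighted shortest-path length (hops) over
  mutually reachable unordered node pairs; unreachable pairs and isolates
  are excluded from the average, so the index stays finite on
  disconnected networks;
* **isolated nodes** — exact degree-zero census.

Degree centrality is degree / (N - 1). Table output rounds centralities
to two decimals and ranks the *rounded* values with competition ranking
(ties share the smallest rank, following ranks are skipped), which is how
tied activity rankings are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import ActivityNetwork

__all__ = [
    "UndefinedMetricError",
    "NetworkSummary",
    "density",
    "inclusiveness",
    "isolated_nodes",
    "mean_distance",
    "degree_centrality",
    "summarize",
    "top_k",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for this network (too few nodes/edges)."""


def _graph(net: ActivityNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, ActivityNetwork) else net


@dataclass
class NetworkSummary:
    """The distribution-index row for one network."""

    group_label: str
    day_type: str
    n_nodes: int
    n_edges: int
    density: float
    inclusiveness: float
    mean_distance: float
    reachable_pairs: int
    isolated_count: int
    isolated_labels: list[str]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def density(net: ActivityNetwork | nx.Graph) -> float:
    """Edge density 2E / (N(N-1)); weights are ignored."""
    g = _graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise UndefinedMetricError(f"density undefined for {n} node(s)")
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def isolated_nodes(net: ActivityNetwork | nx.Graph) -> tuple[int, list[str]]:
    """Degree-zero census: (count, sorted labels)."""
    g = _graph(net)
    labels = sorted((str(v) for v in nx.isolates(g)))
    return len(labels), labels


def inclusiveness(net: ActivityNetwork | nx.Graph) -> float:
    """(N - isolates) / N — the share of nodes that are connected at all."""
    g = _graph(net)
    n = g.number_of_nodes()
    if n < 1:
        raise UndefinedMetricError("inclusiveness undefined for the empty network")
    count, _ = isolated_nodes(g)
    return (n - count) / n


def mean_distance(net: ActivityNetwork | nx.Graph,
                  with_pairs: bool = False) -> float | tuple[float, int]:
    """Mean unweighted shortest-path length over reachable pairs.

    Averages hop counts over all unordered node pairs lying in the same
    connected component; cross-component pairs (and therefore isolates)
    do not enter the average. Pass ``with_pairs=True`` to also get the
    number of pairs averaged over.
    """
    g = _graph(net)
    if g.number_of_edges() == 0:
        raise UndefinedMetricError("mean distance undefined for an edgeless network")
    total, pairs = 0, 0
    for component in nx.connected_components(g):
        if len(component) < 2:
            continue
        sub = g.subgraph(component)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        pairs += len(component) * (len(component) - 1) // 2
    value = (total / 2) / pairs  # each unordered pair counted twice above
    return (value, pairs) if with_pairs else value


def degree_centrality(net: ActivityNetwork | nx.Graph,
                      decimals: int = 2) -> pd.DataFrame:
    """Normalised degree centrality with competition-ranked table output.

    Returns a DataFrame with columns ``activity``, ``degree``,
    ``centrality`` (exact degree/(N-1)), ``index`` (rounded to
    ``decimals``) and ``rank`` (competition ranking of the rounded
    values), sorted by rank then label.
    """
    g = _graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise UndefinedMetricError(f"degree centrality undefined for {n} node(s)")
    rows = pd.DataFrame({
        "activity": [str(v) for v in g.nodes],
        "degree": [g.degree(v) for v in g.nodes],
    })
    rows["centrality"] = rows["degree"] / (n - 1)
    rows["index"] = rows["centrality"].round(decimals)
    rows["rank"] = rows["index"].rank(method="min", ascending=False).astype(int)
    return rows.sort_values(["rank", "activity"]).reset_index(drop=True)


def top_k(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Rows whose competition rank is within the top ``k``.

    All rows tied at a qualifying rank are kept, so the result can hold
    more than ``k`` rows (ten activities sharing rank 1 all stay).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return table[table["rank"] <= k].reset_index(drop=True)


def summarize(net: ActivityNetwork | nx.Graph) -> NetworkSummary:
    """Assemble the distribution-index summary for one network.

    Mean distance is reported as 0.0 (with zero reachable pairs) for an
    edgeless network rather than raising, so summaries stay total.
    """
    g = _graph(net)
    n = g.number_of_nodes()
    if n < 1:
        raise UndefinedMetricError("summary undefined for the empty network")
    count, labels = isolated_nodes(g)
    if g.number_of_edges() > 0:
        md, pairs = mean_distance(g, with_pairs=True)
    else:
        md, pairs = 0.0, 0
    group_label = net.group_label if isinstance(net, ActivityNetwork) else ""
    day_type = net.day_type if isinstance(net, ActivityNetwork) else ""
    return NetworkSummary(
        group_label=group_label,
        day_type=day_type,
        n_nodes=n,
        n_edges=g.number_of_edges(),
        density=density(g) if n >= 2 else 0.0,
        inclusiveness=inclusiveness(g),
        mean_distance=md,
        reachable_pairs=pairs,
        isolated_count=count,
        isolated_labels=labels,
    )
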
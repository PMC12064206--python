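"""Quadratic Assignment Procedure (QAP) correlation between networks.

Dyadic observations in two networks over the same node set are not
independent, so an ordinary correlation test is invalid. QAP keeps the
observed Pearson correlation between the vectorised off-diagonal cells
and builds its null distribution by relabelling the nodes of one matrix:
each permutation is applied simultaneously to rows and columns, which
preserves the matrix's internal structure while breaking its alignment
with the other network. The p-value uses the add-one permutation
estimator (b + 1) / (m + 1), which can never report an exact zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .network import ActivityNetwork

__all__ = ["QAPResult", "align_networks", "qap_correlation", "qap_table"]


class ZeroVarianceError(ValueError):
    """An off-diagonal vector is constant; the correlation is undefined."""


@dataclass
class QAPResult:
    r_observed: float
    p_value: float
    n_permutations: int
    sidedness: str
    seed: int
    null_quantiles: tuple[float, float, float]  # 2.5%, 50%, 97.5%
    null_r: np.ndarray

    def __repr__(self) -> str:  # keep the array out of the default repr
        lo, med, hi = self.null_quantiles
        return (f"QAPResult(r={self.r_observed:.4f}, p={self.p_value:.4f}, "
                f"m={self.n_permutations}, {self.sidedness}, "
                f"null 2.5/50/97.5% = {lo:.3f}/{med:.3f}/{hi:.3f})")


def align_networks(a: ActivityNetwork, b: ActivityNetwork,
                   weighted: bool = True
                   ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Place two networks on their common node universe.

    The universe is the sorted union of both node sets; a node absent
    from one network appears there as a zero row/column. Both adjacency
    matrices come back in the same row/column order.
    """
    labels = sorted(set(a.graph.nodes) | set(b.graph.nodes))
    weight = "weight" if weighted else None

    def dense(net: ActivityNetwork) -> np.ndarray:
        import networkx as nx

        g = net.graph.copy()
        g.add_nodes_from(labels)
        return nx.to_numpy_array(g, nodelist=labels, weight=weight)

    return labels, dense(a), dense(b)


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def qap_correlation(matrix_a: np.ndarray, matrix_b: np.ndarray,
                    n_permutations: int = 1000, seed: int = 0,
                    sidedness: str = "two_sided",
                    exhaustive: bool = False) -> QAPResult:
    """QAP correlation test between two symmetric matrices.

    r_observed is the Pearson correlation of the off-diagonal upper
    triangles. Each null draw relabels matrix_b's nodes by one random
    permutation applied to rows and columns together. With
    ``exhaustive=True`` all n! permutations are enumerated instead
    (feasible only for small n; the p-value is then exact and
    ``n_permutations`` is ignored).
    """
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    n = a.shape[0]
    if n < 3:
        raise ValueError("QAP needs at least 3 nodes")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    if sidedness not in ("two_sided", "greater"):
        raise ValueError(f"sidedness must be 'two_sided' or 'greater', got {sidedness!r}")

    x = _upper(a)
    if np.ptp(x) == 0:
        raise ZeroVarianceError("matrix_a has a constant off-diagonal vector")
    if np.ptp(_upper(b)) == 0:
        raise ZeroVarianceError("matrix_b has a constant off-diagonal vector")
    r_obs = _pearson(x, _upper(b))

    if exhaustive:
        perms = [np.asarray(p) for p in permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_permutations)]
    null = np.empty(len(perms))
    for k, p in enumerate(perms):
        null[k] = _pearson(x, _upper(b[np.ix_(p, p)]))

    if sidedness == "two_sided":
        extreme = int(np.sum(np.abs(null) >= np.abs(r_obs) - 1e-12))
    else:
        extreme = int(np.sum(null >= r_obs - 1e-12))
    if exhaustive:
        p_value = extreme / len(perms)  # the identity permutation is in the null
    else:
        p_value = (extreme + 1) / (len(perms) + 1)

    q = np.quantile(null, [0.025, 0.5, 0.975])
    return QAPResult(
        r_observed=r_obs,
        p_value=float(p_value),
        n_permutations=len(perms),
        sidedness=sidedness,
        seed=seed,
        null_quantiles=(float(q[0]), float(q[1]), float(q[2])),
        null_r=null,
    )


def qap_table(networks: dict[str, ActivityNetwork], n_permutations: int = 1000,
              seed: int = 0, weighted: bool = True,
              sidedness: str = "two_sided") -> pd.DataFrame:
    """Pairwise QAP correlations for a set of networks.

    Returns one row per unordered pair (the lower triangle of the
    correlation table) with columns network_a, network_b, r, p_value.
    Pair order follows the insertion order of ``networks``.
    """
    names = list(networks)
    rows = []
    for i, (na, nb) in enumerate(combinations(names, 2)):
        _, a, b = align_networks(networks[na], networks[nb], weighted=weighted)
        res = qap_correlation(a, b, n_permutations=n_permutations,
                              seed=seed + i, sidedness=sidedness)
        rows.append({"network_a": na, "network_b": nb,
                     "r": res.r_observed, "p_value": res.p_value})
    return pd.DataFrame(rows)
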
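"""Per-individual centrality on posterior network draws.

Three measures, chosen for their epidemiological relevance:

- **strength** — the sum of an individual's incident edge weights, i.e. its
  total grooming rate (contact intensity);
- **closeness** — the inverse of the mean weighted shortest-path length to
  every other individual, with each edge's length taken as the reciprocal of
  its weight (a rate-to-distance transform), computed on the full complete
  draw;
- **degree** — the number of incident edges at or above the group-year's
  minimum observed non-zero edge weight.  Posterior draws are complete
  graphs, so degree is only meaningful after thresholding; using each
  group-year's own smallest observed weight keeps the measure as independent
  of strength as possible and is sensitive to the loss of weak connections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .edges import PosteriorNetworkDraw

__all__ = [
    "compute_strength",
    "compute_closeness",
    "compute_degree",
    "centrality_table",
]


def compute_strength(net: PosteriorNetworkDraw, id_: str) -> float:
    """Weighted sum of the individual's social connections."""
    return float(net.weights[net.index_of(id_)].sum())


def _distance_matrix(net: PosteriorNetworkDraw) -> np.ndarray:
    with np.errstate(divide="ignore"):
        dist = 1.0 / net.weights
    np.fill_diagonal(dist, 0.0)
    return shortest_path(dist, method="D", directed=False)


def compute_closeness(net: PosteriorNetworkDraw, id_: str) -> float:
    """Inverse of the mean weighted shortest-path length to all others.

    Edge length is the reciprocal of edge weight; stronger ties are shorter.
    Raises if any node is unreachable (cannot occur on complete draws with
    positive weights).
    """
    i = net.index_of(id_)
    sp = _distance_matrix(net)[i]
    others = np.delete(sp, i)
    if np.any(np.isinf(others)):
        raise ValueError(f"{id_!r} cannot reach every node in {net.label}/{net.draw_index}")
    return float(1.0 / others.mean())


def compute_degree(net: PosteriorNetworkDraw, threshold: float | None = None) -> dict[str, int]:
    """Number of incident edges with weight >= threshold, per individual.

    The threshold defaults to the group-year's minimum observed non-zero
    edge weight carried on the draw; edges exactly at the threshold count.
    """
    if threshold is None:
        threshold = net.threshold
    if threshold <= 0:
        raise ValueError("degree threshold must be strictly positive")
    counts = (net.weights >= threshold).sum(axis=1) - (np.diag(net.weights) >= threshold)
    return {id_: int(c) for id_, c in zip(net.ids, counts)}


def centrality_table(draws: list[PosteriorNetworkDraw]) -> pd.DataFrame:
    """Long-format table (group_year, draw, id, age, strength, closeness,
    degree) over a list of posterior draws."""
    rows = []
    for net in draws:
        strength = net.weights.sum(axis=1)
        sp = _distance_matrix(net)
        n = net.n
        if n > 1:
            mean_sp = (sp.sum(axis=1)) / (n - 1)
            closeness = 1.0 / mean_sp
        else:
            closeness = np.zeros(1)
        deg = (net.weights >= net.threshold).sum(axis=1)
        for k in range(n):
            rows.append(
                (net.label, net.draw_index, net.ids[k], net.ages[k],
                 strength[k], closeness[k], int(deg[k]))
            )
    return pd.DataFrame(
        rows, columns=["group_year", "draw", "id", "age", "strength", "closeness", "degree"]
    )
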
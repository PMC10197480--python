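"""Network parameters of a trait network.

Three parameters carry the ecological interpretation: the *degree* of a
trait (number of significant partners; a high-degree trait is a hub
trait), the *edge density* (realized edges over the ``p(p-1)/2``
possible ones), and the *modularity* Q of a detected community
partition — the Newman–Girvan quality ``Q = sum_c (e_cc - a_c^2)``,
where ``e_cc`` is the fraction of edges inside community c and ``a_c``
the fraction of edge endpoints in c.  On top of these sit the hub
ranking and the category-importance summary (mean degree per
functional trait category, absolute, and that mean over the total
degree sum, relative).

Community detection defaults to greedy modularity maximization
(Clauset–Newman–Moore), which is deterministic; Louvain is available
behind a seed.  Isolated traits always form singleton modules, and the
empty network gets Q = 0 with an all-singleton partition by convention.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import TraitNetwork
from .trait_data import TraitCategory, validate_categories

logger = logging.getLogger(__name__)


@dataclass
class NetworkMetrics:
    """Per-network parameter bundle."""

    trait_names: list[str]
    degree: np.ndarray
    edge_density: float
    modularity: float
    partition: dict[str, int]
    n_modules: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-trait table: degree and module label."""
        return pd.DataFrame(
            {
                "trait": self.trait_names,
                "degree": self.degree,
                "module": [self.partition[t] for t in self.trait_names],
            }
        )

    def scalars(self) -> dict[str, float]:
        return {
            "edge_density": self.edge_density,
            "modularity": self.modularity,
            "n_modules": self.n_modules,
        }


def degree(net: TraitNetwork) -> np.ndarray:
    """Degree of every trait, in ``trait_names`` order."""
    return net.adjacency.sum(axis=1).astype(int)


def edge_density(net: TraitNetwork) -> float:
    """Edges realized over the ``p(p-1)/2`` possible; in [0, 1]."""
    p = net.n_traits
    if p < 2:
        raise ValueError("edge density needs at least 2 traits")
    return net.n_edges / (p * (p - 1) / 2)


def modularity_q(adjacency: np.ndarray, communities: Sequence[set[int]]) -> float:
    """Newman–Girvan Q of a node partition of a binary graph.

    Defined as 0 for the empty graph (no edges), by convention.
    """
    a = np.asarray(adjacency)
    m2 = a.sum()  # = 2m
    if m2 == 0:
        return 0.0
    q = 0.0
    deg = a.sum(axis=1)
    for comm in communities:
        idx = sorted(comm)
        e_cc = a[np.ix_(idx, idx)].sum() / m2
        a_c = deg[idx].sum() / m2
        q += e_cc - a_c * a_c
    return float(q)


def detect_modules(
    net: TraitNetwork, method: str = "greedy", seed: int | None = None
) -> tuple[dict[str, int], float]:
    """Partition the trait network into modules and score it with Q.

    ``method="greedy"`` runs deterministic greedy modularity
    maximization; ``method="louvain"`` requires a seed and is
    reproducible given it.  Module labels are consecutive integers
    ordered by each module's first trait in ``trait_names`` order.
    Returns ``(partition, Q)``.
    """
    names = net.trait_names
    if net.n_edges == 0:
        logger.info("empty network: singleton partition, Q = 0 by convention")
        return {t: i for i, t in enumerate(names)}, 0.0

    g = nx.Graph()
    g.add_nodes_from(range(len(names)))
    g.add_edges_from(map(tuple, np.argwhere(np.triu(net.adjacency, 1))))
    if method == "greedy":
        comms = nx.community.greedy_modularity_communities(g)
    elif method == "louvain":
        if seed is None:
            raise ValueError("louvain requires a seed for reproducibility")
        comms = nx.community.louvain_communities(g, seed=seed)
    else:
        raise ValueError(f"unknown community method {method!r}")

    comms = _refine_partition(net.adjacency, [set(c) for c in comms])
    q = modularity_q(net.adjacency, comms)
    # label modules by their lowest-index member for determinism
    comms.sort(key=min)
    partition = {names[i]: lab for lab, comm in enumerate(comms) for i in comm}
    return partition, q


def _refine_partition(
    adjacency: np.ndarray, comms: list[set[int]]
) -> list[set[int]]:
    """Deterministic single-node-move refinement of a partition.

    Greedy agglomerative detection is known to misplace individual
    nodes; sweeping nodes in index order and moving each to the
    adjacent community that most increases Q (strictly, ties to the
    lowest community index) repairs those without sacrificing
    determinism.  Stops when a full sweep makes no move.
    """
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    m2 = a.sum()
    if m2 == 0:
        return comms
    deg = a.sum(axis=1)
    label = np.empty(n, dtype=int)
    for c, comm in enumerate(comms):
        for i in comm:
            label[i] = c
    sums = np.zeros(len(comms))          # total degree per community
    for i in range(n):
        sums[label[i]] += deg[i]
    for _sweep in range(100):
        moved = False
        for v in range(n):
            cur = label[v]
            # degree of v into each community
            k_in = np.zeros(len(comms))
            for u in range(n):
                if a[v, u]:
                    k_in[label[u]] += a[v, u]
            base = k_in[cur] / m2 * 2 - 2 * deg[v] * (sums[cur] - deg[v]) / (m2 * m2)
            best_gain, best_c = 0.0, cur
            for c in range(len(comms)):
                if c == cur or (k_in[c] == 0 and sums[c] > 0):
                    continue
                gain = (k_in[c] / m2 * 2
                        - 2 * deg[v] * sums[c] / (m2 * m2)) - base
                if gain > best_gain + 1e-12 or (
                    abs(gain - best_gain) <= 1e-12 and best_gain > 0 and c < best_c
                ):
                    best_gain, best_c = gain, c
            if best_c != cur:
                sums[cur] -= deg[v]
                sums[best_c] += deg[v]
                label[v] = best_c
                moved = True
        if not moved:
            break
    out: dict[int, set[int]] = {}
    for i in range(n):
        out.setdefault(label[i], set()).add(i)
    return list(out.values())


def compute_metrics(
    net: TraitNetwork, method: str = "greedy", seed: int | None = None
) -> NetworkMetrics:
    """Degree, edge density, modularity and module assignment in one pass."""
    partition, q = detect_modules(net, method=method, seed=seed)
    return NetworkMetrics(
        trait_names=list(net.trait_names),
        degree=degree(net),
        edge_density=edge_density(net),
        modularity=q,
        partition=partition,
        n_modules=len(set(partition.values())),
    )


def hub_traits(metrics: NetworkMetrics, k: int = 1) -> list[tuple[str, int]]:
    """Top-k traits by degree, ties broken lexicographically by name."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        zip(metrics.trait_names, (int(d) for d in metrics.degree)),
        key=lambda td: (-td[1], td[0]),
    )
    return ranked[:k]


@dataclass
class ImportanceTable:
    """Mean degree per trait category (absolute) and its share of the
    total degree sum (relative; 0 on an empty network)."""

    categories: list[str]
    absolute: dict[str, float]
    relative: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.categories,
                "absolute_importance": [self.absolute[c] for c in self.categories],
                "relative_importance": [self.relative[c] for c in self.categories],
            }
        )


def importance(
    metrics: NetworkMetrics, categories: Sequence[TraitCategory]
) -> ImportanceTable:
    """Category importance from a metrics bundle.

    Absolute importance of a category is the mean degree of its traits;
    relative importance divides that by the sum of all trait degrees.
    """
    validate_categories(categories, metrics.trait_names)
    deg = {t: int(d) for t, d in zip(metrics.trait_names, metrics.degree)}
    total = sum(deg.values())
    absolute: dict[str, float] = {}
    relative: dict[str, float] = {}
    names = []
    for cat in categories:
        names.append(cat.name)
        mean_deg = float(np.mean([deg[t] for t in cat.members]))
        absolute[cat.name] = mean_deg
        relative[cat.name] = mean_deg / total if total > 0 else 0.0
    return ImportanceTable(categories=names, absolute=absolute, relative=relative)


# ---------------------------------------------------------------------------
# Exhaustive search (small graphs only) — used as an internal oracle and
# for auditing greedy suboptimality on toy networks.


def best_partition_exhaustive(adjacency: np.ndarray) -> tuple[list[set[int]], float]:
    """Globally Q-optimal partition by enumerating all set partitions.

    Feasible only for a handful of nodes (Bell(6) = 203 partitions);
    intended for validation, not analysis.
    """
    n = adjacency.shape[0]
    if n > 10:
        raise ValueError("exhaustive search is limited to <= 10 nodes")
    best_q = -np.inf
    best: list[set[int]] = [set(range(n))]
    for part in _set_partitions(list(range(n))):
        q = modularity_q(adjacency, part)
        if q > best_q:
            best_q = q
            best = part
    return best, float(best_q)


def _set_partitions(items: list[int]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in _set_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [sub[i] | {first}] + sub[i + 1:]
        yield [{first}] + sub
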
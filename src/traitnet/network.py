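"""Build trait networks from pairwise Pearson correlations.

A plant trait network (PTN) is an undirected graph whose nodes are
traits and whose edges are statistically significant pairwise trait
correlations: the pairwise Pearson matrix is computed on the
log-transformed trait table, two-sided p-values come from the exact
t-transform ``t = r sqrt(n-2) / sqrt(1-r^2)`` with ``n-2`` degrees of
freedom, and pairs with ``p < alpha`` (default 0.05, strict) become
unit entries of a binary, symmetric, hollow adjacency matrix.  Edges
are unsigned — a significant negative correlation is an edge just like
a positive one — but the signed correlation matrix is kept alongside
the adjacency for inspection and export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .trait_data import TraitMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
#: Smallest pairwise-complete sample size for which a correlation (and
#: its p-value, which needs n-2 >= 2 degrees of freedom) is computed.
MIN_PAIR_N = 4


@dataclass
class CorrelationResult:
    """Pairwise Pearson coefficients, p-values and pairwise sample sizes."""

    r: np.ndarray
    pvalue: np.ndarray
    n_eff: np.ndarray
    trait_names: list[str]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        names = self.trait_names
        return (
            pd.DataFrame(self.r, index=names, columns=names),
            pd.DataFrame(self.pvalue, index=names, columns=names),
        )


@dataclass
class TraitNetwork:
    """Binary significance-thresholded trait network.

    ``adjacency[i, j] = 1`` iff the correlation between traits i and j
    was significant at ``alpha`` over at least the minimum pairwise
    sample size.  ``source`` keeps the correlation matrices the network
    was thresholded from.
    """

    adjacency: np.ndarray
    trait_names: list[str]
    alpha: float
    source: CorrelationResult | None = None
    categories: dict[str, str] | None = None

    @property
    def n_traits(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_graph(self) -> nx.Graph:
        """networkx view with trait-name nodes and category attributes."""
        g = nx.Graph()
        cat = self.categories or {}
        for t in self.trait_names:
            g.add_node(t, category=cat.get(t, ""))
        idx = np.argwhere(np.triu(self.adjacency, 1))
        for i, j in idx:
            attrs = {}
            if self.source is not None:
                r = float(self.source.r[i, j])
                attrs = {"r": r, "p": float(self.source.pvalue[i, j]),
                         "sign": int(np.sign(r))}
            g.add_edge(self.trait_names[i], self.trait_names[j], **attrs)
        return g


def _pearson_arrays(values: np.ndarray, min_n: int = MIN_PAIR_N):
    """Pearson r / p / n_eff matrices for an (n, p) array with NaN missing.

    Uses a vectorized path on complete data and a pairwise-complete
    loop otherwise.  Zero-variance pairs and pairs with fewer than
    ``min_n`` complete records get ``r = NaN`` and ``p = 1`` (never an
    edge) rather than raising.
    """
    x = np.asarray(values, dtype=float)
    n, p = x.shape
    r = np.full((p, p), np.nan)
    pval = np.ones((p, p))
    has_missing = np.isnan(x).any()

    if not has_missing:
        n_eff = np.full((p, p), n, dtype=int)
        if n >= min_n:
            sd = x.std(axis=0)
            ok = sd > 0
            if not ok.all():
                logger.warning(
                    "zero-variance traits excluded from correlations: %s",
                    [i for i in range(p) if not ok[i]],
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.corrcoef(x, rowvar=False)
            c = np.clip(c, -1.0, 1.0)
            mask = np.outer(ok, ok)
            r[mask] = c[mask]
            pval = _p_from_r(r, n_eff)
            pval[~mask] = 1.0
    else:
        obs = ~np.isnan(x)
        n_eff = (obs.astype(int).T @ obs.astype(int))
        for i in range(p):
            for j in range(i + 1, p):
                both = obs[:, i] & obs[:, j]
                ne = int(both.sum())
                if ne < min_n:
                    continue
                xi, xj = x[both, i], x[both, j]
                si, sj = xi.std(), xj.std()
                if si == 0 or sj == 0:
                    logger.warning(
                        "zero variance for pair (%d, %d); no edge possible", i, j
                    )
                    continue
                rij = float(np.clip(
                    np.mean((xi - xi.mean()) * (xj - xj.mean())) / (si * sj),
                    -1.0, 1.0,
                ))
                r[i, j] = r[j, i] = rij
                pv = _p_scalar(rij, ne)
                pval[i, j] = pval[j, i] = pv

    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(pval, 0.0)
    return r, pval, n_eff


def _p_from_r(r: np.ndarray, n_eff: np.ndarray) -> np.ndarray:
    """Two-sided p from the t-transform, elementwise; NaN r -> p = 1."""
    df = n_eff - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.where(np.isnan(r), 1.0, p)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), 1.0, p)
    return p


def _p_scalar(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def pairwise_pearson(m: TraitMatrix, min_n: int = MIN_PAIR_N) -> CorrelationResult:
    """Pairwise-complete Pearson correlations between all trait pairs.

    Expects a log-transformed matrix (warns otherwise, since the
    network stages of the pipeline are defined on the log scale).
    """
    if min_n < MIN_PAIR_N:
        raise ValueError(f"min_n must be >= {MIN_PAIR_N}")
    if not m.log_transformed:
        logger.warning("correlations computed on a matrix not marked log-transformed")
    r, p, n_eff = _pearson_arrays(m.values, min_n=min_n)
    return CorrelationResult(r=r, pvalue=p, n_eff=n_eff,
                             trait_names=list(m.trait_names))


def threshold_network(
    c: CorrelationResult,
    alpha: float = DEFAULT_ALPHA,
    adjust: str = "none",
    categories: dict[str, str] | None = None,
) -> TraitNetwork:
    """Threshold a correlation result into a binary trait network.

    An edge appears where the two-sided ``p`` is strictly below
    ``alpha``; ``p == alpha`` exactly is NOT an edge.  ``adjust="bh"``
    applies a Benjamini–Hochberg step-up over the off-diagonal pairs
    before thresholding — an optional extension, not the default
    procedure of raw per-pair thresholding.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    p = c.pvalue.copy()
    k = p.shape[0]
    if adjust == "bh":
        iu = np.triu_indices(k, 1)
        flat = p[iu]
        order = np.argsort(flat, kind="stable")
        m_tests = flat.size
        ranked = flat[order] * m_tests / (np.arange(m_tests) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(flat)
        out[order] = np.minimum(adj, 1.0)
        p[iu] = out
        p.T[iu] = out
    elif adjust != "none":
        raise ValueError(f"unknown adjust method {adjust!r}")

    adj_matrix = (p < alpha).astype(int)
    np.fill_diagonal(adj_matrix, 0)
    return TraitNetwork(
        adjacency=adj_matrix,
        trait_names=list(c.trait_names),
        alpha=alpha,
        source=c,
        categories=categories,
    )


def build_network(
    m: TraitMatrix,
    alpha: float = DEFAULT_ALPHA,
    min_n: int = MIN_PAIR_N,
    adjust: str = "none",
) -> TraitNetwork:
    """Convenience: pairwise correlations then significance threshold."""
    c = pairwise_pearson(m, min_n=min_n)
    return threshold_network(c, alpha=alpha, adjust=adjust,
                             categories=m.category_of() or None)


# ---------------------------------------------------------------------------
# Export


def edge_list(net: TraitNetwork) -> pd.DataFrame:
    """Edges as a tidy table: trait_a, trait_b, r, p, sign."""
    rows = []
    idx = np.argwhere(np.triu(net.adjacency, 1))
    for i, j in idx:
        r = p = np.nan
        if net.source is not None:
            r = float(net.source.r[i, j])
            p = float(net.source.pvalue[i, j])
        rows.append(
            {
                "trait_a": net.trait_names[i],
                "trait_b": net.trait_names[j],
                "r": r,
                "p": p,
                "sign": int(np.sign(r)) if np.isfinite(r) else 0,
            }
        )
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "p", "sign"])


def write_edge_list(net: TraitNetwork, path) -> None:
    edge_list(net).to_csv(path, index=False)


def write_graphml(net: TraitNetwork, path) -> None:
    nx.write_graphml(net.to_graph(), path)


def write_correlations(c: CorrelationResult, r_path, p_path) -> None:
    rdf, pdf = c.to_frames()
    rdf.to_csv(r_path)
    pdf.to_csv(p_path)
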
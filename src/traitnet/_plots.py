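"""Figure helpers for pipeline reports.

Figures are conveniences: every plot gets a CSV twin written next to
it containing exactly the plotted numbers, so nothing is recorded only
as pixels.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .compare import DuncanResult
from .metrics import NetworkMetrics
from .network import TraitNetwork
from .resampling import RarefactionCurve, ResampleSummary

_MODULE_CMAP = plt.get_cmap("tab10")


def plot_network(
    net: TraitNetwork, metrics: NetworkMetrics, path, seed: int = 0
) -> None:
    """Spring-layout network with nodes colored by detected module."""
    path = Path(path)
    g = net.to_graph()
    pos = nx.spring_layout(g, seed=seed)
    colors = [_MODULE_CMAP(metrics.partition[t] % 10) for t in g.nodes]
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx(g, pos=pos, ax=ax, node_color=colors, node_size=900,
                     font_size=8, edge_color="0.6")
    ax.set_title(
        f"trait network: density={metrics.edge_density:.3f}, "
        f"Q={metrics.modularity:.3f}, {metrics.n_modules} modules"
    )
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    metrics.to_frame().to_csv(path.with_suffix(".csv"), index=False)


def plot_degree_bars(
    summaries: dict[str, ResampleSummary],
    trait_names: list[str],
    path,
    letters: DuncanResult | None = None,
) -> None:
    """Bootstrap mean degree per trait with SE error bars and, when a
    Duncan result is given, its letter annotations."""
    path = Path(path)
    rows = []
    for t in trait_names:
        s = summaries[f"degree[{t}]"]
        rows.append({"trait": t, "mean_degree": s.mean, "se": s.se,
                     "letters": letters.letters.get(t, "") if letters else ""})
    df = pd.DataFrame(rows).sort_values("mean_degree", ascending=False)
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.bar(df["trait"], df["mean_degree"], yerr=df["se"], color="#4878b0",
           capsize=2)
    if letters is not None:
        for x, (_, row) in enumerate(df.iterrows()):
            ax.text(x, row["mean_degree"] + row["se"] + 0.1, row["letters"],
                    ha="center", fontsize=8)
    ax.set_ylabel("degree (bootstrap mean ± SE)")
    ax.tick_params(axis="x", rotation=60)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    df.to_csv(path.with_suffix(".csv"), index=False)


def plot_importance_bars(imp_frame: pd.DataFrame, path) -> None:
    """Absolute importance per trait category."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(imp_frame["category"], imp_frame["absolute_importance"],
           color=["#d65f5f", "#4878b0", "#ee854a"])
    ax.set_ylabel("absolute importance (mean degree)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    imp_frame.to_csv(path.with_suffix(".csv"), index=False)


def plot_rarefaction(curve: RarefactionCurve, path) -> None:
    """Mean ± SE of edge density and modularity against species count."""
    path = Path(path)
    df = curve.to_frame()
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, param in zip(axes, ("edge_density", "modularity")):
        sub = df[df["parameter"] == param]
        ax.errorbar(sub["species_count"], sub["mean"], yerr=sub["se"],
                    marker="o", capsize=2)
        ax.set_xlabel("species count")
        ax.set_ylabel(param.replace("_", " "))
    fig.tight_layout()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    df.to_csv(path.with_suffix(".csv"), index=False)
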
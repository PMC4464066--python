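"""Manhattan-style and network visualization.

Three Manhattan plot types share the y-axis -log10(p) and differ in
the x-axis: type 1 plots m/z, type 2 retention time (revealing e.g.
late-eluting lipid clusters), type 3 mean log10 ion intensity
(separating isotopologue abundance). Positive correlations are blue,
negative red; the BH significance cutoff is a dashed line.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .mwas import MwasResult
from .network import AssociationNetwork

_POS_COLOR = "tab:blue"
_NEG_COLOR = "tab:red"

_X_AXES = {1: ("mz", "m/z"), 2: ("rt", "retention time (s)"),
           3: ("mean_log_intensity", "mean log10 intensity")}


def bh_cutoff_p(p: np.ndarray, q: np.ndarray, alpha: float) -> Optional[float]:
    """Largest raw p among features with q < alpha, or None if none."""
    ok = np.isfinite(p) & np.isfinite(q) & (q < alpha)
    if not ok.any():
        return None
    return float(np.max(p[ok]))


def plot_manhattan(
    result: MwasResult,
    plot_type: int,
    alpha: float = 0.05,
    path: Optional[str] = None,
) -> plt.Figure:
    """Render a type-1/2/3 Manhattan plot of a targeted MWAS result.

    Returns the figure; writes a vector file when ``path`` ends in
    .pdf or .svg.
    """
    if plot_type not in _X_AXES:
        raise ValueError(f"plot_type must be 1, 2 or 3; got {plot_type}")
    rec = result.records
    if rec.empty:
        raise ValueError("result has no records to plot")
    col, xlabel = _X_AXES[plot_type]
    ok = rec["p"].notna()
    x = rec.loc[ok, col].to_numpy()
    p = rec.loc[ok, "p"].to_numpy()
    r = rec.loc[ok, "r"].to_numpy()
    with np.errstate(divide="ignore"):
        y = -np.log10(np.maximum(p, 1e-300))
    colors = np.where(r >= 0, _POS_COLOR, _NEG_COLOR)

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.scatter(x, y, c=colors, s=12, alpha=0.8, linewidths=0)
    cutoff = bh_cutoff_p(rec["p"].to_numpy(), rec["q"].to_numpy(), alpha)
    if cutoff is not None:
        ax.axhline(-np.log10(max(cutoff, 1e-300)), linestyle="--",
                   color="black", linewidth=1, label=f"FDR {alpha:g}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_title(f"Targeted MWAS: {result.target_id} (type {plot_type})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


def plot_network(
    network: AssociationNetwork,
    path: Optional[str] = None,
    layout_seed: int = 0,
) -> plt.Figure:
    """Render an association network with a seeded force-directed layout.

    Seed metabolites are drawn as larger squares; edges are blue for
    positive and red for negative correlation.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    pos = nx.spring_layout(g, seed=layout_seed)
    fig, ax = plt.subplots(figsize=(6, 6))
    seeds = [v for v, d in g.nodes(data=True) if d.get("is_seed")]
    others = [v for v in g.nodes if v not in set(seeds)]
    nx.draw_networkx_nodes(g, pos, nodelist=others, node_size=60,
                           node_color="lightgray", edgecolors="gray", ax=ax)
    if seeds:
        nx.draw_networkx_nodes(g, pos, nodelist=seeds, node_size=160,
                               node_shape="s", node_color="gold",
                               edgecolors="black", ax=ax)
    pos_edges = [(u, v) for u, v, d in g.edges(data=True) if d.get("r", 0) >= 0]
    neg_edges = [(u, v) for u, v, d in g.edges(data=True) if d.get("r", 0) < 0]
    nx.draw_networkx_edges(g, pos, edgelist=pos_edges, edge_color=_POS_COLOR, ax=ax)
    nx.draw_networkx_edges(g, pos, edgelist=neg_edges, edge_color=_NEG_COLOR, ax=ax)
    ax.set_title(
        f"{network.method} network, |r| > {network.r_min:g}, q < {network.q_max:g}"
    )
    ax.set_axis_off()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
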
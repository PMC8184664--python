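"""Thresholded connectivity graphs, heatmap matrices and line-map rendering.

A cell pair becomes an edge of the connectivity graph iff its correlation
exceeds the strength threshold AND its resampling p-value beats the
significance threshold (both strict): R > 0.25 and p < 0.001 by default.
Each edge is colour-binned by strength — green for R in (0.25, 0.5), yellow
for [0.5, 0.75), red for [0.75, 1.0] — and drawn as a straight line between
the two cells' Cartesian positions.  The companion display is the full
Pearson heatmap matrix with the colour scale fixed to [−1, 1].

All graph logic lives in the exported tables; rendering is a thin
matplotlib layer over them so everything is testable headlessly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import CorrelationResult
from .traces import CellCoordinates

R_MIN_DEFAULT = 0.25
ALPHA_DEFAULT = 0.001

#: bin lower edges (half-open upward); r == 0.5 is yellow, r == 0.75 is red
BIN_EDGES = ((0.75, "red"), (0.5, "yellow"), (0.25, "green"))
BIN_COLOURS = {"green": "#2ca02c", "yellow": "#e6b800", "red": "#d62728"}

#: tolerance for clipping r slightly above 1 from floating-point noise
NUMERIC_EPS = 1e-9


def classify_edge_bin(r: float) -> str:
    """Strength bin for an edge coefficient: green / yellow / red.

    green for r in (0.25, 0.5), yellow for [0.5, 0.75), red for [0.75, 1.0];
    boundary values belong to the upper bin.  Raises outside (0.25, 1].
    """
    if r > 1.0:
        if r <= 1.0 + NUMERIC_EPS:
            r = 1.0
        else:
            raise ValueError(f"r={r} exceeds 1")
    if r <= R_MIN_DEFAULT:
        raise ValueError(f"r={r} is not above the edge threshold {R_MIN_DEFAULT}")
    for lo, name in BIN_EDGES:
        if r >= lo:
            return name
    return "green"  # unreachable: r > 0.25 handled above


def build_graph(
    corr: CorrelationResult,
    coords: CellCoordinates,
    r_min: float = R_MIN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> nx.Graph:
    """Threshold a correlation result into a connectivity graph.

    An edge exists iff ``r > r_min`` AND ``p < alpha`` (both strict).  Nodes
    carry the supplied Cartesian coordinates; edges carry ``r``, ``p`` and a
    strength ``bin``.  The thresholds are stored as graph attributes.
    Raises if the correlation result and the coordinates disagree on cell
    ids, listing the symmetric difference.
    """
    a, b = set(corr.cell_ids), set(coords.cell_ids)
    if a != b:
        raise ValueError(
            f"cell-id mismatch between correlations and coordinates; "
            f"symmetric difference: {sorted(a ^ b)}"
        )
    g = nx.Graph(r_min=float(r_min), alpha=float(alpha))
    for cid in corr.cell_ids:
        x, y = coords.position(cid)
        g.add_node(cid, x=x, y=y)
    n = len(corr.cell_ids)
    for i in range(n):
        for j in range(i + 1, n):
            r, p = float(corr.R[i, j]), float(corr.P[i, j])
            if r > r_min and p < alpha:
                r_clipped = min(r, 1.0)
                g.add_edge(
                    corr.cell_ids[i],
                    corr.cell_ids[j],
                    r=r_clipped,
                    p=p,
                    bin=classify_edge_bin(r_clipped),
                )
    return g


@dataclass
class ConnectivitySummary:
    """Islet-level summary of a connectivity graph."""

    n_cells: int
    n_edges: int
    pct_connected_pairs: float  # 100 * n_edges / C(n_cells, 2)
    mean_r_significant: float  # NaN when there are no edges
    degree: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_cells": self.n_cells,
                    "n_edges": self.n_edges,
                    "pct_connected_pairs": self.pct_connected_pairs,
                    "mean_r_significant": None
                    if math.isnan(self.mean_r_significant)
                    else self.mean_r_significant,
                    "degree": self.degree,
                },
                fh,
                indent=2,
            )


def connectivity_summary(g: nx.Graph) -> ConnectivitySummary:
    """Percentage of connected pairs, per-cell degrees and mean significant R."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 cells to summarise connectivity")
    n_edges = g.number_of_edges()
    n_pairs = n * (n - 1) // 2
    rs = [d["r"] for _, _, d in g.edges(data=True)]
    return ConnectivitySummary(
        n_cells=n,
        n_edges=n_edges,
        pct_connected_pairs=100.0 * n_edges / n_pairs,
        mean_r_significant=float(np.mean(rs)) if rs else float("nan"),
        degree={cid: int(d) for cid, d in g.degree()},
    )


def edge_table(g: nx.Graph) -> pd.DataFrame:
    """Edge list ``cell_a, cell_b, r, p, bin`` sorted by cell ids."""
    rows = [
        (*sorted((u, v)), d["r"], d["p"], d["bin"]) for u, v, d in g.edges(data=True)
    ]
    return pd.DataFrame(
        sorted(rows), columns=["cell_a", "cell_b", "r", "p", "bin"]
    )


def export_heatmap_matrix(corr: CorrelationResult, path, figure_path=None) -> pd.DataFrame:
    """Write the Pearson matrix as a tab-delimited square table (diagonal NA).

    Values are clipped to the display range [−1, 1].  If ``figure_path`` is
    given a heatmap with the colour scale fixed to [−1, 1] is rendered next
    to it (suffix decides the format, e.g. .svg or .png).
    """
    mat = np.clip(corr.R, -1.0, 1.0)
    df = pd.DataFrame(mat, index=corr.cell_ids, columns=corr.cell_ids)
    df.to_csv(path, sep="\t", na_rep="NA")
    if figure_path is not None:
        plot_heatmap(corr, figure_path)
    return df


def plot_heatmap(corr: CorrelationResult, path) -> None:
    """Render the Pearson matrix with the colour scale fixed to [−1, 1]."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(np.clip(corr.R, -1, 1), vmin=-1.0, vmax=1.0, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.cell_ids)))
    ax.set_yticks(range(len(corr.cell_ids)))
    ax.set_xticklabels(corr.cell_ids, rotation=90, fontsize=5)
    ax.set_yticklabels(corr.cell_ids, fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson R")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_line_map(g: nx.Graph, path) -> None:
    """Connectivity line map: cells at their Cartesian positions, connected
    pairs joined by straight lines coloured by strength bin."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for u, v, d in g.edges(data=True):
        xu, yu = g.nodes[u]["x"], g.nodes[u]["y"]
        xv, yv = g.nodes[v]["x"], g.nodes[v]["y"]
        ax.plot([xu, xv], [yu, yv], color=BIN_COLOURS[d["bin"]], lw=1.2, zorder=1)
    xs = [d["x"] for _, d in g.nodes(data=True)]
    ys = [d["y"] for _, d in g.nodes(data=True)]
    ax.scatter(xs, ys, s=30, c="0.2", zorder=2)
    ax.set_aspect("equal")
    ax.set_xlabel("x (a.u.)")
    ax.set_ylabel("y (a.u.)")
    ax.set_title(f"{g.number_of_edges()} connections, "
                 f"R > {g.graph['r_min']}, p < {g.graph['alpha']}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
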
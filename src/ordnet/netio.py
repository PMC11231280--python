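"""Network layout, export, and plotting helpers.

Layout follows the Fruchterman-Reingold force-directed algorithm with
absolute edge weights as attraction, so strongly associated nodes land
close together; exports go to GraphML (interchange) or a tidy edge-list
CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .glasso import NetworkModel

__all__ = ["layout", "to_graph", "export_network", "import_graphml", "network_to_json", "network_from_json", "plot_network"]


def to_graph(model: NetworkModel, domain_map: dict[str, str] | None = None) -> nx.Graph:
    """networkx graph with signed ``weight`` and ``abs_weight`` edge attributes."""
    names = model.node_names or [f"node_{i + 1}" for i in range(model.p)]
    G = nx.Graph()
    for i, name in enumerate(names):
        attrs = {}
        if domain_map and name in domain_map:
            attrs["domain"] = domain_map[name]
        G.add_node(name, **attrs)
    for i in range(model.p):
        for j in range(i + 1, model.p):
            w = float(model.W[i, j])
            if w != 0.0:
                G.add_edge(names[i], names[j], weight=w, abs_weight=abs(w))
    return G


def layout(W: np.ndarray, iterations: int = 500, seed: int = 0,
           node_names: list[str] | None = None) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold coordinates using |weight| as attraction.

    Deterministic under a fixed seed. A single node sits at the origin.
    """
    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    names = node_names or [f"node_{i + 1}" for i in range(p)]
    if p == 1:
        return {names[0]: (0.0, 0.0)}
    G = nx.Graph()
    G.add_nodes_from(names)
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] != 0.0:
                G.add_edge(names[i], names[j], abs_weight=abs(float(W[i, j])))
    pos = nx.spring_layout(G, weight="abs_weight", iterations=iterations, seed=seed)
    return {k: (float(v[0]), float(v[1])) for k, v in pos.items()}


def export_network(model: NetworkModel, path: str | Path, fmt: str = "graphml",
                   domain_map: dict[str, str] | None = None) -> None:
    """Write a network as GraphML or edge-list CSV (lossless weights)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(to_graph(model, domain_map), path)
    elif fmt == "csv":
        model.edges().to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def network_to_json(model: NetworkModel, path: str | Path, meta: dict | None = None) -> None:
    obj = {
        "nodes": model.node_names,
        "W": model.W.tolist(),
        "lambda_selected": model.lambda_selected,
        "gamma": model.gamma,
        "n": model.n,
        "p": model.p,
        "lambda_path": model.lambda_path.tolist(),
        "ebic_trace": model.ebic_trace.tolist(),
        "edge_count": model.edge_count,
    }
    if meta:
        obj["meta"] = meta
    Path(path).write_text(json.dumps(obj, indent=2))


def network_from_json(path: str | Path) -> NetworkModel:
    obj = json.loads(Path(path).read_text())
    W = np.asarray(obj["W"], dtype=float)
    # K is not serialized; rebuild the unit-diagonal precision whose partial
    # correlations equal W
    K = -W.copy()
    np.fill_diagonal(K, 1.0)
    return NetworkModel(
        W=W,
        K=K,
        lambda_selected=obj["lambda_selected"],
        gamma=obj["gamma"],
        n=obj["n"],
        p=obj["p"],
        lambda_path=np.asarray(obj["lambda_path"]),
        ebic_trace=np.asarray(obj["ebic_trace"]),
        edge_count=obj["edge_count"],
        node_names=list(obj["nodes"]),
    )


def plot_network(model: NetworkModel, path: str | Path, seed: int = 0,
                 domain_map: dict[str, str] | None = None) -> None:
    """Basic static figure: blue positive edges, red negative, FR layout."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    G = to_graph(model, domain_map)
    pos = nx.spring_layout(G, weight="abs_weight", iterations=500, seed=seed)
    fig, ax = plt.subplots(figsize=(7, 7))
    colors = ["tab:blue" if G.edges[e]["weight"] > 0 else "tab:red" for e in G.edges]
    widths = [6.0 * G.edges[e]["abs_weight"] for e in G.edges]
    nx.draw_networkx(G, pos, ax=ax, edge_color=colors, width=widths,
                     node_color="lightgray", node_size=900, font_size=7)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
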
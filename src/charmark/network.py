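"""Export first-order transition models as directed weighted networks.

Each character is a node; a directed edge carries the smoothed transition
probability. Rendering tools read the exports (DOT, GraphML, or a plain
edge CSV); pruning by a probability threshold keeps the dominant structure
legible — dense self-loops and concentrated local transitions are the
visual signature of rigid production.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .alphabet import SPACE, SPACE_GLYPH
from .markov import TransitionModel

FORMATS = ("dot", "edge_csv", "graphml")


class NetworkError(ValueError):
    pass


def to_graph(model: TransitionModel, prune_threshold: float = 0.0) -> nx.DiGraph:
    """Build the directed transition graph, keeping edges with probability
    >= prune_threshold. Node and edge order follow the alphabet, so exports
    are deterministic. Self-loops are retained."""
    if model.order != 1:
        raise NetworkError("network export is defined for order-1 models only")
    names = [SPACE_GLYPH if s == SPACE else s for s in model.alphabet.symbols]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for i, src in enumerate(names):
        for j, dst in enumerate(names):
            p = float(model.P[i, j])
            if p >= prune_threshold:
                g.add_edge(src, dst, probability=p)
    return g


def export_network(
    model: TransitionModel,
    path: str | Path,
    prune_threshold: float = 0.0,
    format: str = "edge_csv",
) -> Path:
    """Write the pruned transition network to ``path`` in the given format."""
    if format not in FORMATS:
        raise NetworkError(f"unknown format {format!r}; choose from {FORMATS}")
    path = Path(path)
    g = to_graph(model, prune_threshold)
    if format == "edge_csv":
        rows = [
            {"from": u, "to": v, "probability": d["probability"]}
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["from", "to", "probability"]).to_csv(
            path, index=False, float_format="%.12g"
        )
    elif format == "graphml":
        nx.write_graphml(g, path)
    else:  # dot — written directly; the format is line-oriented and simple
        lines = ["digraph transitions {"]
        for node in g.nodes:
            lines.append(f'  "{node}";')
        for u, v, d in g.edges(data=True):
            p = d["probability"]
            lines.append(
                f'  "{u}" -> "{v}" [weight={p:.12g}, penwidth={1 + 8 * p:.3f}];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
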
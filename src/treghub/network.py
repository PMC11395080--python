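"""PPI graph construction from STRING-format edge lists and per-node
centrality analysis for hub-gene selection.

Centralities follow the normalized NetworkAnalyzer conventions so every value
lies in [0, 1]: betweenness is Brandes on unweighted shortest paths,
normalized by (n-1)(n-2)/2 with n the size of the node's connected component;
closeness is the reciprocal of the mean shortest-path distance to the other
nodes of the component (0 for isolated nodes); the clustering coefficient is
the fraction of a node's neighbor pairs that are themselves connected.
Interaction confidence scores are used only for edge inclusion; shortest
paths are unweighted.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

__all__ = [
    "read_string_tsv",
    "write_string_tsv",
    "centralities",
    "select_hubs",
    "annotate_filter",
]

logger = logging.getLogger(__name__)


def read_string_tsv(path, min_score: float = 400) -> nx.Graph:
    """Read a STRING-format edge list (node1 TAB node2 TAB combined_score).

    Edges below ``min_score`` are dropped; duplicated pairs (either
    orientation) keep the maximum score; self-loops are discarded with a
    logged count.  A header line starting with 'node1' or '#' is skipped.
    """
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts and parts[0].lower() in ("node1", "protein1"):
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            a, b = parts[0], parts[1]
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric score at line {lineno}") from exc
            if a == b:
                n_self += 1
                continue
            if score < min_score:
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["combined_score"] = max(g.edges[a, b]["combined_score"], score)
            else:
                g.add_edge(a, b, combined_score=score)
    if n_self:
        logger.warning("dropped %d self-loop(s)", n_self)
    return g


def write_string_tsv(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tcombined_score\n")
        for u, v, d in g.edges(data=True):
            fh.write(f"{u}\t{v}\t{d.get('combined_score', 999)}\n")


def centralities(g: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness, closeness and clustering for every node.

    Betweenness/closeness are computed component-wise so normalization uses
    the component size, matching the value ranges network-analysis tools
    report.  Returns a DataFrame indexed by gene with the four columns.
    """
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["gene", "degree", "betweenness", "closeness", "clustering"])
    degree = dict(g.degree())
    clustering = nx.clustering(g)
    betweenness: dict = {}
    closeness: dict = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) > 2:
            betweenness.update(nx.betweenness_centrality(sub, normalized=True))
        else:
            betweenness.update({v: 0.0 for v in comp})
        closeness.update(nx.closeness_centrality(sub, wf_improved=False))
    rows = [
        {
            "gene": v,
            "degree": degree[v],
            "betweenness": betweenness[v],
            "closeness": closeness[v],
            "clustering": clustering[v],
        }
        for v in g.nodes
    ]
    df = pd.DataFrame(rows).sort_values("gene", kind="mergesort").reset_index(drop=True)
    return df


def select_hubs(records: pd.DataFrame, k: int = 10) -> list[str]:
    """Top-k genes by (degree desc, betweenness desc, closeness desc, gene asc)."""
    if k > len(records):
        raise ValueError(f"k={k} exceeds the number of records ({len(records)})")
    ordered = records.sort_values(
        ["degree", "betweenness", "closeness", "gene"],
        ascending=[False, False, False, True],
        kind="mergesort",
    )
    return ordered["gene"].head(k).tolist()


def annotate_filter(hubs: list[str], annotation_set: set) -> list[str]:
    """Hubs restricted to an annotation gene set, order preserved.

    Used to narrow the hub list to e.g. chemokine-signaling genes driving
    Treg migration.
    """
    annotation_set = set(annotation_set)
    return [g for g in hubs if g in annotation_set]
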
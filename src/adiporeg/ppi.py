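"""Ortholog-filtered protein-interaction subnetworks.

Human interaction edges are carried over to mouse only when both
endpoints map to exactly one mouse gene (a conservative one-to-one
ortholog rule that avoids inflating modules through paralog fan-out).
A cluster's interaction module is the distance-0 induced subgraph: only
edges with *both* endpoints in the cluster's gene list are kept.
Self-loops (homodimer-style interactions) are legitimate edges.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "read_ortholog_table",
    "map_orthologs",
    "induced_subgraph",
]

Edge = tuple[str, str]


def _canonical(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


def read_ortholog_table(path_or_df) -> dict[str, set[str]]:
    """Load a human->mouse ortholog table (one row per id pair)."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep="\t", comment="#", dtype=str)
    hcol, mcol = df.columns[:2]
    table: dict[str, set[str]] = {}
    for h, m in zip(df[hcol], df[mcol]):
        if not isinstance(h, str) or not isinstance(m, str) or not h or not m:
            raise ValueError("ortholog table ids must be non-empty strings")
        table.setdefault(h, set()).add(m)
    return table


def map_orthologs(
    human_edges: Iterable[Edge],
    orthologs: Mapping[str, set[str] | Sequence[str]],
) -> set[Edge]:
    """Map human edges to mouse under the one-to-one ortholog rule.

    An edge (a, b) survives iff both a and b map to exactly one mouse id;
    absent keys count as empty mappings.  Duplicate mouse edges collapse
    (edges are undirected); self-loops are preserved.
    """
    mapped: set[Edge] = set()
    for edge in human_edges:
        try:
            a, b = edge
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed edge row: {edge!r}") from exc
        ma = set(orthologs.get(a, ()))
        mb = set(orthologs.get(b, ()))
        if len(ma) == 1 and len(mb) == 1:
            mapped.add(_canonical(next(iter(ma)), next(iter(mb))))
    return mapped


def induced_subgraph(
    edges: Iterable[Edge],
    gene_list: Iterable[str],
    keep_isolated: bool = False,
) -> nx.Graph:
    """Distance-0 interaction module of a gene list.

    Keeps exactly the edges with both endpoints in ``gene_list``.  By
    default genes without any retained interaction are dropped; with
    ``keep_isolated`` they stay as isolated nodes.  Connected components
    are stored on the graph as ``graph.graph["components"]`` (a list of
    frozensets) and per node as the ``component`` attribute.
    """
    genes = set(gene_list)
    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(genes)
    for a, b in edges:
        if a in genes and b in genes:
            g.add_edge(a, b)
    components = [frozenset(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), min(c)))
    g.graph["components"] = components
    for idx, comp in enumerate(components):
        for node in comp:
            g.nodes[node]["component"] = idx
    return g
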
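"""Cell-connectivity-summary networks: collapse edges to a types x types matrix.

The summary network answers "which cell types communicate the most (or most
specifically)?" by merging all ligand-receptor edges from one cell type to
another into a single directed weight. Rows are senders (ligand side),
columns receivers -- the matrix is directed and generally asymmetric. Three
weighting schemes:

* ``edge_count`` -- number of ligand-receptor pairs passing the hard
  thresholds from sender to receiver;
* ``summed_specificity`` -- sum of per-edge specificity weights, no hard
  threshold; high values mean many specific edges;
* ``summed_expression`` -- sum of per-edge mean-expression weights.

Autocrine (diagonal) entries are retained throughout, including top-k
ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .edge_extraction import EdgeTable, filter_edges
from .expression_io import FilterSettings

SCHEMES = ("edge_count", "summed_specificity", "summed_expression")

_SCHEME_COLUMN = {
    "summed_specificity": "specificity_weight",
    "summed_expression": "mean_weight",
}


@dataclass
class SummaryNetwork:
    """Directed weighted adjacency over cell types under one scheme."""

    adjacency: pd.DataFrame  # rows: sender, columns: receiver
    scheme: str
    settings: FilterSettings = field(default_factory=FilterSettings)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        if not self.adjacency.index.equals(self.adjacency.columns):
            raise ValueError("adjacency must be square with matching labels")
        if (self.adjacency.values < 0).any():
            raise ValueError("summary weights must be non-negative")

    @property
    def cell_types(self) -> list[str]:
        return list(self.adjacency.index)


def _empty_adjacency(cell_types: list[str]) -> pd.DataFrame:
    types = sorted(cell_types)
    return pd.DataFrame(0.0, index=pd.Index(types), columns=pd.Index(types))


def edge_count_network(
    edges: EdgeTable, f: FilterSettings | None = None, cell_types: list[str] | None = None
) -> SummaryNetwork:
    """Entry (i, j) = number of distinct pairs with a surviving edge i -> j."""
    f = f or edges.settings
    surviving = filter_edges(edges, f)
    adj = _empty_adjacency(cell_types or edges.cell_types)
    if not surviving.empty:
        counts = surviving.groupby(["sender", "receiver"]).size()
        for (s, r), c in counts.items():
            adj.loc[s, r] = float(c)
    return SummaryNetwork(adjacency=adj, scheme="edge_count", settings=f)


def summed_weight_network(
    edges: EdgeTable, scheme: str, cell_types: list[str] | None = None
) -> SummaryNetwork:
    """Entry (i, j) = sum over pairs of the per-edge weight for i -> j.

    No hard threshold beyond what the edge table already encodes.
    """
    if scheme not in _SCHEME_COLUMN:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {sorted(_SCHEME_COLUMN)}"
        )
    col = _SCHEME_COLUMN[scheme]
    adj = _empty_adjacency(cell_types or edges.cell_types)
    if len(edges):
        sums = edges.edges.groupby(["sender", "receiver"])[col].sum()
        for (s, r), w in sums.items():
            adj.loc[s, r] = float(w)
    return SummaryNetwork(adjacency=adj, scheme=scheme, settings=edges.settings)


def top_k_summary_edges(net: SummaryNetwork, k: int) -> list[tuple[str, str, float]]:
    """The k highest-weight directed entries, autocrine included.

    Ties at the boundary break by (sender, receiver) lexicographic order so
    the ranking is deterministic. Zero-weight entries never qualify; if fewer
    than k are nonzero, all nonzero entries are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    entries = [
        (s, r, float(net.adjacency.loc[s, r]))
        for s in net.cell_types
        for r in net.cell_types
        if net.adjacency.loc[s, r] > 0
    ]
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    if k > len(entries):
        warnings.warn(
            f"requested top {k} but only {len(entries)} nonzero summary edges",
            stacklevel=2,
        )
        return entries
    return entries[:k]


def connected_communities(
    edge_list: list[tuple[str, str]] | list[tuple[str, str, float]],
) -> list[set[str]]:
    """Weakly-connected components of the directed graph induced by the edges.

    Self-loops are allowed; a node appearing only in a self-loop forms its
    own community. Components are returned sorted by (size desc, then by
    smallest member) for determinism.
    """
    if not edge_list:
        raise ValueError("empty edge list")
    g = nx.DiGraph()
    for e in edge_list:
        g.add_edge(e[0], e[1])
    comps = [set(c) for c in nx.weakly_connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def write_adjacency(net: SummaryNetwork, path) -> None:
    adj = net.adjacency
    if net.scheme == "edge_count":
        adj = adj.astype(int)
    adj.to_csv(path, sep="\t", index_label="Sender\\Receiver")


def read_adjacency(path, scheme: str, settings: FilterSettings | None = None) -> SummaryNetwork:
    adj = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    adj.index = adj.index.map(str)
    adj.columns = adj.columns.map(str)
    return SummaryNetwork(adjacency=adj, scheme=scheme, settings=settings or FilterSettings())
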
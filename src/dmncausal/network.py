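"""Directed causal graphs over DMN nodes and hub-communication metrics.

A subject's significant Granger influences form a binary directed graph.
Per node, ``d_out`` counts significant outgoing influences and ``d_in``
incoming ones.  ``D_outer`` is the number of significant edges joining a hub
to a non-hub (either direction), ``D_all`` the total number of significant
edges, and the hub index ``D_outer / D_all`` measures how much of the
network's causal traffic involves hub-to-non-hub communication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .timeseries import DEFAULT_HUB_LABELS, DEFAULT_NODE_LABELS

logger = logging.getLogger(__name__)

#: Edge-proportion display bands (graph-figure line styles).
PROPORTION_BANDS = ("above_80", "60_to_80", "50_to_60", "below_50")


@dataclass(frozen=True)
class CausalGraph:
    """Binary directed graph of significant causal influences.

    Parameters
    ----------
    node_labels : tuple of str
        All DMN node names (isolated nodes included).
    hub_labels : tuple of str
        Subset of ``node_labels`` designated as hubs.
    edges : frozenset of (source, target)
        Ordered pairs, no self-loops.
    """

    node_labels: tuple[str, ...] = DEFAULT_NODE_LABELS
    hub_labels: tuple[str, ...] = DEFAULT_HUB_LABELS
    edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        object.__setattr__(self, "hub_labels", tuple(self.hub_labels))
        object.__setattr__(self, "edges", frozenset(self.edges))
        nodes = set(self.node_labels)
        if len(nodes) != len(self.node_labels):
            raise ValueError("node labels must be unique")
        if not set(self.hub_labels) <= nodes:
            raise ValueError("hub_labels must be a subset of node_labels")
        for s, t in self.edges:
            if s == t:
                raise ValueError(f"self-loop {s}->{t} not allowed")
            if s not in nodes or t not in nodes:
                raise ValueError(f"edge {s}->{t} has endpoint outside node_labels")

    @property
    def non_hub_labels(self) -> tuple[str, ...]:
        hubs = set(self.hub_labels)
        return tuple(n for n in self.node_labels if n not in hubs)

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self.edges

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_labels)
        for n in self.node_labels:
            g.nodes[n]["hub"] = n in self.hub_labels
        g.add_edges_from(sorted(self.edges))
        return g

    def to_json_dict(self) -> dict:
        return {
            "node_labels": list(self.node_labels),
            "hub_labels": list(self.hub_labels),
            "edges": sorted(list(e) for e in self.edges),
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "CausalGraph":
        return cls(
            node_labels=tuple(d["node_labels"]),
            hub_labels=tuple(d["hub_labels"]),
            edges=frozenset((s, t) for s, t in d["edges"]),
        )


@dataclass(frozen=True)
class HubIndexResult:
    """Degree metrics and hub index for one subject's causal graph.

    ``ratio`` is ``d_outer / d_all``; for an empty graph it is undefined
    (flagged via ``defined=False``, ``ratio`` is NaN) rather than zero:
    0/0 carries no evidence about hub communication.
    """

    d_out: Mapping[str, int]
    d_in: Mapping[str, int]
    d_outer: int
    d_all: int
    ratio: float
    defined: bool


def hub_index(graph: CausalGraph) -> HubIndexResult:
    """Compute D_out/D_in per node, D_outer, D_all and the hub index.

    D_outer counts edges with exactly one endpoint in the hub set, in
    either direction; D_all counts all edges.
    """
    d_out = {n: 0 for n in graph.node_labels}
    d_in = {n: 0 for n in graph.node_labels}
    hubs = set(graph.hub_labels)
    d_outer = 0
    for s, t in graph.edges:
        d_out[s] += 1
        d_in[t] += 1
        if (s in hubs) != (t in hubs):
            d_outer += 1
    d_all = len(graph.edges)
    if d_all > 0:
        return HubIndexResult(d_out, d_in, d_outer, d_all, d_outer / d_all, True)
    logger.warning("empty causal graph: hub index undefined (excluded from group stats)")
    return HubIndexResult(d_out, d_in, d_outer, d_all, float("nan"), False)


def build_graph(
    edge_table: pd.DataFrame,
    node_labels: Sequence[str] = DEFAULT_NODE_LABELS,
    hub_labels: Sequence[str] = DEFAULT_HUB_LABELS,
) -> CausalGraph:
    """Binary graph from a per-pair significance table.

    ``edge_table`` needs columns ``source``, ``target``, ``significant``;
    an edge (s, t) is present iff the s->t test was significant.
    Duplicate (source, target) rows are rejected.
    """
    pairs = list(zip(edge_table["source"], edge_table["target"]))
    if len(pairs) != len(set(pairs)):
        raise ValueError("duplicate (source, target) rows in edge table")
    edges = frozenset(
        (str(s), str(t))
        for s, t, sig in zip(
            edge_table["source"], edge_table["target"], edge_table["significant"]
        )
        if bool(sig)
    )
    return CausalGraph(tuple(node_labels), tuple(hub_labels), edges)


def group_edge_proportions(graphs: Sequence[CausalGraph]) -> pd.DataFrame:
    """Fraction of subjects showing each directed edge.

    Returns a table with one row per ordered node pair and columns
    ``source``, ``target``, ``proportion``, ``band``.
    """
    if not graphs:
        raise ValueError("no graphs given")
    labels = graphs[0].node_labels
    for g in graphs[1:]:
        if g.node_labels != labels:
            raise ValueError("graphs have mismatched node labels")
    rows = []
    n = len(graphs)
    for s in labels:
        for t in labels:
            if s == t:
                continue
            count = sum(g.has_edge(s, t) for g in graphs)
            frac = count / n
            rows.append(
                {
                    "source": s,
                    "target": t,
                    "proportion": frac,
                    "band": categorize_proportion(frac),
                }
            )
    return pd.DataFrame(rows)


def categorize_proportion(fraction: float) -> str:
    """Map a subject proportion to its display band.

    Bands follow the figure convention: > 0.8 thick ("above_80"),
    [0.6, 0.8] ("60_to_80"), [0.5, 0.6) ("50_to_60"), and below 0.5 edges
    are not drawn ("below_50").  Lower boundaries are inclusive.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"proportion {fraction} outside [0, 1]")
    if fraction > 0.8:
        return "above_80"
    if fraction >= 0.6:
        return "60_to_80"
    if fraction >= 0.5:
        return "50_to_60"
    return "below_50"


def degree_partition(graph: CausalGraph) -> dict[str, int]:
    """Partition of D_all into hub-hub, hub-nonhub (= D_outer) and
    nonhub-nonhub edge counts."""
    hubs = set(graph.hub_labels)
    counts = {"hub_hub": 0, "hub_nonhub": 0, "nonhub_nonhub": 0}
    for s, t in graph.edges:
        k = (s in hubs) + (t in hubs)
        counts[("nonhub_nonhub", "hub_nonhub", "hub_hub")[k]] += 1
    return counts


def edges_to_table(graph: CausalGraph) -> pd.DataFrame:
    """Edge list as a two-column table (for TSV serialization)."""
    return pd.DataFrame(sorted(graph.edges), columns=["source", "target"])
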
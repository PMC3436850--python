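"""Alternative-splicing event detection and classification.

An event is a pair of internally node-disjoint paths through a gene's
splice graph connecting the same two anchor nodes (or a virtual SOURCE /
SINK for alternate promoters and terminators).  Classification is purely
topological:

* ``exon_skip`` / ``cassette_exons`` — direct junction versus a path
  through one / two-or-more skipped nodes;
* ``retained_intron`` — direct junction versus an unbroken adjacency
  chain through the genomically contiguous retained sequence;
* ``alt_donor`` / ``alt_acceptor`` — direct junction versus an adjacency
  extension of the anchor exon followed (preceded) by a junction, i.e.
  variation at the transcription-upstream (downstream) side of the
  intron; working in transcription order makes the rule strand-symmetric;
* ``mutually_exclusive`` — both paths carry internal nodes absent from
  the other;
* ``alt_promoter`` / ``alt_terminator`` — paths from two distinct start
  nodes converging at their first shared node (mirror image for end
  nodes).

A junction only counts as *observed* in a sample when at least
``min_reads`` reads extend at least ``min_overhang`` bases into both
flanking exons (defaults 2 and 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .quant import QuantTable
from .splice_graph import ADJACENCY, JUNCTION, SpliceEdge, SpliceGraph
from .tiling_align import ObservationCounts, edge_key, node_key

SOURCE = "SOURCE"
SINK = "SINK"

EVENT_TYPES = (
    "exon_skip",
    "cassette_exons",
    "alt_donor",
    "alt_acceptor",
    "retained_intron",
    "mutually_exclusive",
    "alt_promoter",
    "alt_terminator",
)


@dataclass
class ASEvent:
    event_id: str
    gene_id: str
    etype: str
    anchor_from: str  # node_id or SOURCE
    anchor_to: str  # node_id or SINK
    path_a: tuple[str, ...]  # element labels (edges and internal nodes)
    path_b: tuple[str, ...]
    path_a_edges: tuple[SpliceEdge, ...]
    path_b_edges: tuple[SpliceEdge, ...]
    path_a_nodes: tuple[str, ...]  # internal nodes only
    path_b_nodes: tuple[str, ...]
    observed_support: Optional[tuple] = None  # (min junction reads path_a, path_b)


def _internals(path: Sequence[SpliceEdge]) -> list[str]:
    return [e.to_node for e in path[:-1]]


def _elements(path: Sequence[SpliceEdge]) -> tuple[str, ...]:
    out: list[str] = []
    for i, e in enumerate(path):
        out.append(e.label())
        if i < len(path) - 1:
            out.append(e.to_node)
    return tuple(out)


def classify_path_pair(
    path_a: Sequence[SpliceEdge], path_b: Sequence[SpliceEdge]
) -> str:
    """Event type of two anchored, internally node-disjoint paths."""
    int_a, int_b = _internals(path_a), _internals(path_b)
    if int_a and int_b:
        return "mutually_exclusive"
    if not int_a and not int_b:
        # parallel single edges of different type: splice versus read-through
        return "retained_intron"
    direct, longer = (path_a, path_b) if not int_a else (path_b, path_a)
    types = [e.etype for e in longer]
    if direct[0].etype == JUNCTION:
        if all(t == ADJACENCY for t in types):
            return "retained_intron"
        if len(types) >= 2 and types[-1] == JUNCTION and all(
            t == ADJACENCY for t in types[:-1]
        ):
            return "alt_donor"
        if len(types) >= 2 and types[0] == JUNCTION and all(
            t == ADJACENCY for t in types[1:]
        ):
            return "alt_acceptor"
    return "exon_skip" if len(_internals(longer)) == 1 else "cassette_exons"


def _multigraph(graph: SpliceGraph) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    g.add_nodes_from(n.node_id for n in graph.nodes)
    for e in graph.edges:
        g.add_edge(e.from_node, e.to_node, key=e.etype)
    return g


def _edge_paths(g: nx.MultiDiGraph, u: str, v: str) -> list[tuple[SpliceEdge, ...]]:
    if u == v:
        return [()]
    paths = []
    for p in nx.all_simple_edge_paths(g, u, v):
        paths.append(tuple(SpliceEdge(a, b, k) for a, b, k in p))
    return paths


def _path_nodes(start: str, path: Sequence[SpliceEdge]) -> set[str]:
    nodes = {start}
    nodes.update(e.to_node for e in path)
    return nodes


def detect_events(graph: SpliceGraph) -> list[ASEvent]:
    """Enumerate and classify all alternative-splicing events of a graph."""
    g = _multigraph(graph)
    order = graph.node_order
    events: list[tuple] = []  # (sort key, ...fields)

    def add(etype, anc_from, anc_to, pa, pb, start_a, start_b):
        # deterministic path_a/path_b convention: more internal nodes first,
        # ties broken lexicographically on element labels
        ka = (-len(_internals(pa)), _elements(pa))
        kb = (-len(_internals(pb)), _elements(pb))
        if kb < ka:
            pa, pb = pb, pa
            start_a, start_b = start_b, start_a
        events.append(
            (
                etype,
                anc_from,
                anc_to,
                _elements(pa) or (start_a,),
                _elements(pb) or (start_b,),
                pa,
                pb,
                tuple(_internals(pa)),
                tuple(_internals(pb)),
            )
        )

    nodes = [n.node_id for n in graph.nodes]
    for u, v in combinations(nodes, 2):  # transcription order pairs
        paths = _edge_paths(g, u, v)
        if len(paths) < 2:
            continue
        for pa, pb in combinations(paths, 2):
            ia, ib = set(_internals(pa)), set(_internals(pb))
            if ia & ib:
                continue
            add(classify_path_pair(pa, pb), u, v, pa, pb, u, u)

    for s1, s2 in combinations(sorted(graph.start_nodes, key=order.get), 2):
        for v in nodes:
            for p1 in _edge_paths(g, s1, v):
                for p2 in _edge_paths(g, s2, v):
                    if _path_nodes(s1, p1) & _path_nodes(s2, p2) != {v}:
                        continue
                    add("alt_promoter", SOURCE, v, p1, p2, s1, s2)

    for e1, e2 in combinations(sorted(graph.end_nodes, key=order.get), 2):
        for v in nodes:
            for p1 in _edge_paths(g, v, e1):
                for p2 in _edge_paths(g, v, e2):
                    if _path_nodes(v, p1) & _path_nodes(v, p2) != {v}:
                        continue
                    add("alt_terminator", v, SINK, p1, p2, v, v)

    events.sort(key=lambda t: (t[1], t[2], t[0], t[3], t[4]))
    out = []
    for i, (etype, af, at, ela, elb, pa, pb, ina, inb) in enumerate(events, start=1):
        out.append(
            ASEvent(
                event_id=f"{graph.gene_id}:ev{i:03d}",
                gene_id=graph.gene_id,
                etype=etype,
                anchor_from=af,
                anchor_to=at,
                path_a=ela,
                path_b=elb,
                path_a_edges=pa,
                path_b_edges=pb,
                path_a_nodes=ina,
                path_b_nodes=inb,
            )
        )
    return out


# -- sample-level activity -------------------------------------------------

def junction_observed(
    records: Iterable[tuple[int, int]],
    min_reads: int = 2,
    min_overhang: int = 4,
) -> bool:
    """True iff >= ``min_reads`` reads overlap >= ``min_overhang`` bases
    into *both* flanking exons."""
    n = sum(1 for lo, ro in records if lo >= min_overhang and ro >= min_overhang)
    return n >= min_reads


def _path_support(
    gene_id: str,
    edges: Sequence[SpliceEdge],
    counts: ObservationCounts,
    min_overhang: int,
) -> Optional[int]:
    """Minimum qualifying-read count over the path's junctions (None if
    the path has no junction edges)."""
    mins = None
    for e in edges:
        if e.etype != JUNCTION:
            continue
        recs = counts.junction_overhangs.get((gene_id, e.from_node, e.to_node), ())
        n = sum(1 for lo, ro in recs if lo >= min_overhang and ro >= min_overhang)
        mins = n if mins is None else min(mins, n)
    return mins


def event_support(
    event: ASEvent, counts: ObservationCounts, min_overhang: int = 4
) -> tuple[Optional[int], Optional[int]]:
    return (
        _path_support(event.gene_id, event.path_a_edges, counts, min_overhang),
        _path_support(event.gene_id, event.path_b_edges, counts, min_overhang),
    )


def event_active(
    event: ASEvent,
    counts: ObservationCounts,
    min_junction_reads: int = 2,
    min_overhang: int = 4,
    min_exon_reads: int = 1,
) -> bool:
    """An event is active in a sample when every junction on both paths
    passes the observation filter and every internal node is confirmed
    by exon reads."""
    for edges in (event.path_a_edges, event.path_b_edges):
        for e in edges:
            if e.etype != JUNCTION:
                continue
            recs = counts.junction_overhangs.get(
                (event.gene_id, e.from_node, e.to_node), ()
            )
            if not junction_observed(recs, min_junction_reads, min_overhang):
                return False
    for nodes in (event.path_a_nodes, event.path_b_nodes):
        for n in nodes:
            if counts.element_obs.get(node_key(event.gene_id, n), 0) < min_exon_reads:
                return False
    return True


def summarize_single_sample(
    graphs: Mapping[str, SpliceGraph],
    events_by_gene: Mapping[str, list[ASEvent]],
    quant: QuantTable,
    counts: ObservationCounts,
    min_junction_reads: int = 2,
    min_overhang: int = 4,
    min_exon_reads: int = 1,
    feature_impacts: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-event report for one sample.

    ``feature_impacts`` optionally maps gene_id to a summary string of
    functional features affected by that gene's splicing (joined from the
    protein module by the pipeline).
    """
    rows = []
    for gid in sorted(graphs):
        for ev in events_by_gene.get(gid, []):
            sup_a, sup_b = event_support(ev, counts, min_overhang)
            active = event_active(
                ev, counts, min_junction_reads, min_overhang, min_exon_reads
            )
            ev.observed_support = (sup_a, sup_b)
            rows.append(
                {
                    "gene_id": gid,
                    "event_id": ev.event_id,
                    "event_type": ev.etype,
                    "anchor_from": ev.anchor_from,
                    "anchor_to": ev.anchor_to,
                    "path_a": "|".join(ev.path_a),
                    "path_b": "|".join(ev.path_b),
                    "min_junction_reads_a": sup_a if sup_a is not None else "",
                    "min_junction_reads_b": sup_b if sup_b is not None else "",
                    "active": active,
                    "gene_opkm": quant.gene_opkm.get(gid, 0.0),
                    "impacted_features": (feature_impacts or {}).get(gid, ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "event_id", "event_type", "anchor_from", "anchor_to",
            "path_a", "path_b", "min_junction_reads_a", "min_junction_reads_b",
            "active", "gene_opkm", "impacted_features",
        ],
    )


def genes_with_active_events(summary: pd.DataFrame) -> list[str]:
    """Genes showing multiple splice forms in this sample (>= 1 active event)."""
    if summary.empty:
        return []
    return sorted(summary.loc[summary["active"], "gene_id"].unique())
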
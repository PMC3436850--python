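"""Per-gene splice graphs.

A gene's transcripts are merged into one directed acyclic graph whose
nodes are *sub-exons* — maximal exonic segments between consecutive exon
boundaries pooled over all of the gene's transcripts — and whose edges
are either splice *junctions* (an intron was removed between the two
nodes in some transcript) or *adjacencies* (the two nodes abut
genomically and are covered consecutively within a single annotated
exon).  Because the sub-exon partition is taken over the union of all
boundary coordinates, every genomic base of the gene occupies exactly
one node: the unique-location property that makes read alignment to the
graph unambiguous.

Node identifiers follow the composite-exon display convention
``E<exon>.<sub-exon>``: runs of genomically abutting sub-exons are
grouped into one composite exon, numbered in transcription order; a
composite exon with a single sub-exon is written plain (``E2``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .annotation_io import GenomicInterval, TranscriptModel
from .errors import SpliceQuantError, ValidationError

JUNCTION = "junction"
ADJACENCY = "adjacency"


@dataclass(frozen=True)
class SubExonNode:
    node_id: str
    interval: GenomicInterval

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True, order=True)
class SpliceEdge:
    from_node: str
    to_node: str
    etype: str  # JUNCTION or ADJACENCY

    def key(self) -> tuple[str, str, str]:
        return (self.from_node, self.to_node, self.etype)

    def label(self) -> str:
        sep = ".." if self.etype == ADJACENCY else "->"
        return f"{self.from_node}{sep}{self.to_node}"


class SpliceGraph:
    """DAG of sub-exon nodes and splice/adjacency edges for one gene."""

    def __init__(
        self,
        gene_id: str,
        chrom: str,
        strand: str,
        nodes: Sequence[SubExonNode],
        edges: Sequence[SpliceEdge],
        tx_paths: Mapping[str, list[str]],
        node_support: Mapping[str, set[str]],
        edge_support: Mapping[tuple[str, str, str], set[str]],
    ) -> None:
        self.gene_id = gene_id
        self.chrom = chrom
        self.strand = strand
        self.nodes = list(nodes)  # transcription order
        self.edges = sorted(set(edges))
        self.tx_paths = {t: list(p) for t, p in tx_paths.items()}
        self.node_support = {n: set(s) for n, s in node_support.items()}
        self.edge_support = {k: set(s) for k, s in edge_support.items()}
        self.node_by_id = {n.node_id: n for n in self.nodes}
        self.node_order = {n.node_id: i for i, n in enumerate(self.nodes)}
        self.start_nodes = {p[0] for p in self.tx_paths.values()}
        self.end_nodes = {p[-1] for p in self.tx_paths.values()}
        self._out: dict[str, list[SpliceEdge]] = {n.node_id: [] for n in self.nodes}
        self._in: dict[str, list[SpliceEdge]] = {n.node_id: [] for n in self.nodes}
        for e in self.edges:
            self._out[e.from_node].append(e)
            self._in[e.to_node].append(e)
        for adj in (self._out, self._in):
            for lst in adj.values():
                lst.sort(key=lambda e: (self.node_order[e.to_node], e.etype))

    # -- topology ---------------------------------------------------------
    def out_edges(self, node_id: str) -> list[SpliceEdge]:
        return self._out[node_id]

    def in_edges(self, node_id: str) -> list[SpliceEdge]:
        return self._in[node_id]

    def transcript_path(self, transcript_id: str) -> list[str]:
        """Ordered node ids visited by one annotated transcript."""
        try:
            return list(self.tx_paths[transcript_id])
        except KeyError:
            raise SpliceQuantError(
                f"transcript {transcript_id} not in gene {self.gene_id}"
            ) from None

    @property
    def exonic_length(self) -> int:
        return sum(n.length for n in self.nodes)

    # -- serialization ----------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "chrom": self.chrom,
            "strand": self.strand,
            "nodes": [
                {"id": n.node_id, "start": n.interval.start, "end": n.interval.end}
                for n in self.nodes
            ],
            "edges": [
                {
                    "from": e.from_node,
                    "to": e.to_node,
                    "etype": e.etype,
                    "transcripts": sorted(self.edge_support.get(e.key(), ())),
                }
                for e in self.edges
            ],
            "node_transcripts": {
                n: sorted(s) for n, s in sorted(self.node_support.items())
            },
            "transcript_paths": {t: p for t, p in sorted(self.tx_paths.items())},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SpliceGraph":
        nodes = [
            SubExonNode(
                x["id"],
                GenomicInterval(d["chrom"], x["start"], x["end"], d["strand"]),
            )
            for x in d["nodes"]
        ]
        edges = [SpliceEdge(x["from"], x["to"], x["etype"]) for x in d["edges"]]
        edge_support = {
            (x["from"], x["to"], x["etype"]): set(x["transcripts"]) for x in d["edges"]
        }
        node_support = {n: set(s) for n, s in d["node_transcripts"].items()}
        return cls(
            d["gene_id"],
            d["chrom"],
            d["strand"],
            nodes,
            edges,
            d["transcript_paths"],
            node_support,
            edge_support,
        )


def build_splice_graph(transcripts: Sequence[TranscriptModel]) -> SpliceGraph:
    """Construct the splice graph of one gene from its transcripts.

    Sub-exon boundaries are the union of all exon start/end coordinates
    across the gene's transcripts, which guarantees that the resulting
    node intervals are pairwise disjoint (any two are either identical
    partition cells or do not touch).
    """
    if not transcripts:
        raise ValidationError("build_splice_graph requires >= 1 transcript")
    gene_ids = {t.gene_id for t in transcripts}
    chroms = {t.chrom for t in transcripts}
    strands = {t.strand for t in transcripts}
    if len(gene_ids) != 1 or len(chroms) != 1 or len(strands) != 1:
        raise ValidationError(
            f"transcripts of genes {sorted(gene_ids)} mix chromosomes or strands"
        )
    for t in transcripts:
        t.validate()
    gene_id, chrom, strand = gene_ids.pop(), chroms.pop(), strands.pop()

    boundaries = sorted(
        {e.start for t in transcripts for e in t.exons}
        | {e.end for t in transcripts for e in t.exons}
    )

    def partition(exon: GenomicInterval) -> list[tuple[int, int]]:
        cuts = [b for b in boundaries if exon.start <= b <= exon.end]
        return [(a, b) for a, b in zip(cuts, cuts[1:])]

    cells: set[tuple[int, int]] = set()
    for t in transcripts:
        for e in t.exons:
            cells.update(partition(e))

    rev = strand == "-"
    ordered = sorted(cells, reverse=rev)

    # composite-exon grouping: maximal runs of genomically abutting cells
    node_ids: dict[tuple[int, int], str] = {}
    groups: list[list[tuple[int, int]]] = []
    for cell in ordered:
        if groups:
            prev = groups[-1][-1]
            abut = (prev[0] == cell[1]) if rev else (prev[1] == cell[0])
            if abut:
                groups[-1].append(cell)
                continue
        groups.append([cell])
    for gi, group in enumerate(groups, start=1):
        if len(group) == 1:
            node_ids[group[0]] = f"E{gi}"
        else:
            for si, cell in enumerate(group, start=1):
                node_ids[cell] = f"E{gi}.{si}"

    nodes = [
        SubExonNode(node_ids[c], GenomicInterval(chrom, c[0], c[1], strand))
        for c in ordered
    ]

    tx_paths: dict[str, list[str]] = {}
    node_support: dict[str, set[str]] = {}
    edge_support: dict[tuple[str, str, str], set[str]] = {}
    edges: set[SpliceEdge] = set()
    for t in sorted(transcripts, key=lambda x: x.transcript_id):
        path: list[str] = []
        exon_of: list[int] = []  # index of originating exon per path node
        for xi, exon in enumerate(t.exons):
            pieces = sorted(partition(exon), reverse=rev)
            for p in pieces:
                path.append(node_ids[p])
                exon_of.append(xi)
        tx_paths[t.transcript_id] = path
        for nid in path:
            node_support.setdefault(nid, set()).add(t.transcript_id)
        for i in range(len(path) - 1):
            etype = ADJACENCY if exon_of[i] == exon_of[i + 1] else JUNCTION
            e = SpliceEdge(path[i], path[i + 1], etype)
            edges.add(e)
            edge_support.setdefault(e.key(), set()).add(t.transcript_id)

    return SpliceGraph(
        gene_id,
        chrom,
        strand,
        nodes,
        sorted(edges),
        tx_paths,
        node_support,
        edge_support,
    )


def graph_sequence(graph: SpliceGraph, genome) -> dict[str, str]:
    """Per-node nucleotide sequence in transcription orientation.

    ``genome`` is any mapping chrom -> sliceable sequence (a
    ``pyfaidx.Fasta`` or a plain dict of strings).  Minus-strand nodes
    are reverse-complemented.
    """
    try:
        chrom_seq = genome[graph.chrom]
    except KeyError:
        raise SpliceQuantError(f"genome lacks chromosome {graph.chrom}") from None
    out = {}
    for n in graph.nodes:
        iv = n.interval
        raw = str(chrom_seq[iv.start : iv.end]).upper()
        if len(raw) != n.length:
            raise SpliceQuantError(
                f"{graph.gene_id}/{n.node_id}: interval {iv.start}-{iv.end} "
                f"outside chromosome bounds"
            )
        out[n.node_id] = str(Seq(raw).reverse_complement()) if iv.strand == "-" else raw
    return out


# -- graph database -------------------------------------------------------

def graphs_to_json(graphs: Mapping[str, SpliceGraph]) -> dict:
    return {g: graphs[g].to_json_dict() for g in sorted(graphs)}


def graphs_from_json(d: dict) -> dict[str, SpliceGraph]:
    return {g: SpliceGraph.from_json_dict(x) for g, x in d.items()}


def graph_db_checksum(graphs: Mapping[str, SpliceGraph]) -> str:
    blob = json.dumps(graphs_to_json(graphs), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def export_bed(graphs: Mapping[str, SpliceGraph], path) -> None:
    """BED of sub-exons, for genome-browser cross-checking."""
    with open(path, "w") as fh:
        for gid in sorted(graphs):
            g = graphs[gid]
            for n in g.nodes:
                fh.write(
                    f"{g.chrom}\t{n.interval.start}\t{n.interval.end}\t"
                    f"{gid}:{n.node_id}\t0\t{g.strand}\n"
                )
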
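"""Tile database generation, ungapped read alignment, and observation counting.

The alignment target is a database of overlapping *tiles*: sequence
windows over splice-graph paths, generated by depth-first traversal from
every node at regularly spaced offsets.  With the default tile length
``T = 2R - 1`` and step ``S = R - (2*min_overhang - 1)`` every read-length
window of every annotated transcript path — including windows crossing
any number of junctions — lies wholly inside at least one tile.

Reads are matched to tiles ungapped (substitutions only) through an
exact k-mer seed lookup followed by a full-length Hamming check; by the
pigeonhole principle ``max_mismatch + 1`` non-overlapping seeds suffice
to find every alignment within the mismatch budget whenever the read is
long enough to carry them.  Hits reached through different overlapping
tiles but denoting the same graph location collapse to one; a read whose
hits denote more than one distinct graph location (within or across
genes) is *ambiguous* and discarded from counting.

A read "observes" every graph element in its footprint: each node it
overlaps by at least one base and each edge it crosses with at least
``min_overhang`` bases extending into both flanking nodes.  The overhang
requirement keeps the raw junction total consistent with the junction
effective length used for OPKM (the number of read start positions that
cross with valid overhang), and the per-read overhangs are recorded so
the downstream junction-observation filter can be applied at any
threshold.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pysam

from .errors import SpliceQuantError, ValidationError
from .splice_graph import ADJACENCY, JUNCTION, SpliceEdge, SpliceGraph

DEFAULT_KMER = 16
DEFAULT_MAX_MISMATCH = 2
DEFAULT_MIN_OVERHANG = 4
DEFAULT_MAX_PATHS = 64


def default_tile_len(read_len: int) -> int:
    return 2 * read_len - 1

def default_tile_step(read_len: int, min_overhang: int = DEFAULT_MIN_OVERHANG) -> int:
    return max(1, read_len - (2 * min_overhang - 1))


# element tokens used throughout counting/quant:
#   ("node", gene_id, node_id)
#   ("edge", gene_id, from_node, to_node, etype)
ElementKey = tuple


def node_key(gene_id: str, node_id: str) -> ElementKey:
    return ("node", gene_id, node_id)


def edge_key(gene_id: str, edge: SpliceEdge) -> ElementKey:
    return ("edge", gene_id, edge.from_node, edge.to_node, edge.etype)


@dataclass(frozen=True)
class Tile:
    """One alignment-database entry: a sequence window over a graph path.

    ``backmap`` lists ``(node_id, offset_in_node, length)`` spans covering
    every base of ``sequence``; ``edges`` holds the graph edge between
    consecutive spans (``len(edges) == len(backmap) - 1``).
    """

    tile_id: str
    gene_id: str
    sequence: str
    backmap: tuple[tuple[str, int, int], ...]
    edges: tuple[SpliceEdge, ...]

    def __post_init__(self) -> None:
        if sum(s[2] for s in self.backmap) != len(self.sequence):
            raise ValidationError(f"tile {self.tile_id}: backmap/sequence mismatch")
        if len(self.edges) != len(self.backmap) - 1:
            raise ValidationError(f"tile {self.tile_id}: edges/backmap mismatch")


@dataclass
class AlignmentHit:
    """One read placed on one graph location."""

    read_id: str
    tile_id: str
    gene_id: str
    offset: int
    mismatches: int
    elements: frozenset  # ElementKeys: nodes touched and edges crossed
    junction_overhangs: dict  # (gene, from, to) -> (left, right)


@dataclass
class AlignedRead:
    """Final disposition of one read after hit collapsing."""

    read_id: str
    status: str  # unique | ambiguous | unaligned | too_short
    hit: Optional[AlignmentHit] = None
    n_locations: int = 0


class ObservationCounts:
    """Raw observation totals per graph element, per sample."""

    def __init__(self) -> None:
        self.element_obs: dict[ElementKey, int] = defaultdict(int)
        self.junction_overhangs: dict[tuple, list[tuple[int, int]]] = defaultdict(list)
        self.gene_totals: dict[str, int] = defaultdict(int)
        self.n_aligned = 0
        self.n_ambiguous = 0
        self.n_unaligned = 0

    def add(self, read: AlignedRead) -> None:
        if read.status == "unique":
            hit = read.hit
            self.n_aligned += 1
            genes = set()
            for el in hit.elements:
                self.element_obs[el] += 1
                genes.add(el[1])
            for jk, (lo, ro) in hit.junction_overhangs.items():
                self.junction_overhangs[jk].append((lo, ro))
            for g in genes:
                self.gene_totals[g] += 1
        elif read.status == "ambiguous":
            self.n_ambiguous += 1
        else:
            self.n_unaligned += 1

    def to_json_dict(self) -> dict:
        return {
            "element_obs": [[list(k), v] for k, v in sorted(self.element_obs.items())],
            "junction_overhangs": [
                [list(k), v] for k, v in sorted(self.junction_overhangs.items())
            ],
            "gene_totals": dict(sorted(self.gene_totals.items())),
            "n_aligned": self.n_aligned,
            "n_ambiguous": self.n_ambiguous,
            "n_unaligned": self.n_unaligned,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ObservationCounts":
        c = cls()
        for k, v in d["element_obs"]:
            c.element_obs[tuple(k)] = v
        for k, v in d["junction_overhangs"]:
            c.junction_overhangs[tuple(k)] = [tuple(x) for x in v]
        c.gene_totals.update(d["gene_totals"])
        c.n_aligned = d["n_aligned"]
        c.n_ambiguous = d["n_ambiguous"]
        c.n_unaligned = d["n_unaligned"]
        return c


# -- tile generation ------------------------------------------------------

def generate_tiles(
    graph: SpliceGraph,
    node_seqs: Mapping[str, str],
    read_len: int,
    tile_len: Optional[int] = None,
    step: Optional[int] = None,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    max_paths: int = DEFAULT_MAX_PATHS,
    warn=None,
) -> list[Tile]:
    """Enumerate overlapping tiles by recursive depth-first graph traversal.

    From every node, at offsets spaced by ``step``, every outgoing path is
    followed until ``tile_len`` bases have been emitted or the path ends.
    Tiles identical in graph location (same spans at the same offsets) are
    emitted once.
    """
    if read_len < 2 * min_overhang:
        raise ValidationError("read_len must be >= 2*min_overhang")
    T = tile_len if tile_len is not None else default_tile_len(read_len)
    S = step if step is not None else default_tile_step(read_len, min_overhang)
    if T < read_len:
        raise ValidationError("tile_len must be >= read_len")
    if S > T - read_len + 1:
        raise ValidationError("step too large: tiling would miss read windows")

    seen: set[tuple] = set()
    tiles: list[Tile] = []

    def emit(spans: list[tuple[str, int, int]], edges: list[SpliceEdge]) -> None:
        key = tuple(spans)
        if key in seen:
            return
        # a truncated tile shorter than the read can hold no read window;
        # keep only the offset-0 one so short single-node genes still get
        # a database entry
        if sum(s[2] for s in spans) < read_len and spans[0][1] > 0:
            return
        seen.add(key)
        seq = "".join(node_seqs[n][o : o + ln] for n, o, ln in spans)
        tiles.append(
            Tile(
                tile_id=f"{graph.gene_id}|{len(tiles):05d}",
                gene_id=graph.gene_id,
                sequence=seq,
                backmap=tuple(spans),
                edges=tuple(edges),
            )
        )

    def extend(
        spans: list[tuple[str, int, int]],
        edges: list[SpliceEdge],
        remaining: int,
        counter: list[int],
    ) -> None:
        last_node = spans[-1][0]
        outs = graph.out_edges(last_node) if remaining > 0 else []
        if not outs:
            emit(spans, edges)
            counter[0] += 1
            return
        for e in outs:
            nxt = graph.node_by_id[e.to_node]
            take = min(nxt.length, remaining)
            extend(
                spans + [(e.to_node, 0, take)],
                edges + [e],
                remaining - take,
                counter,
            )

    for node in graph.nodes:
        for off in range(0, node.length, S):
            take = min(node.length - off, T)
            counter = [0]
            extend([(node.node_id, off, take)], [], T - take, counter)
            if counter[0] > max_paths and warn is not None:
                warn(
                    f"{graph.gene_id}/{node.node_id}@{off}: window expanded to "
                    f"{counter[0]} tiles (> max_paths={max_paths})"
                )
    return tiles


def export_tiles_fasta(tiles: Sequence[Tile], fasta_path, backmap_path=None) -> None:
    """Write tiles as FASTA (headers = tile ids) plus a JSON backmap sidecar."""
    import json

    with open(fasta_path, "w") as fh:
        for t in tiles:
            fh.write(f">{t.tile_id}\n{t.sequence}\n")
    if backmap_path is not None:
        side = {
            t.tile_id: {
                "gene_id": t.gene_id,
                "backmap": [list(s) for s in t.backmap],
                "edges": [[e.from_node, e.to_node, e.etype] for e in t.edges],
            }
            for t in tiles
        }
        with open(backmap_path, "w") as fh:
            json.dump(side, fh, indent=1)


def tiles_from_backmap_json(d: dict, tile_seqs: Mapping[str, str]) -> list[Tile]:
    tiles = []
    for tid, x in d.items():
        tiles.append(
            Tile(
                tile_id=tid,
                gene_id=x["gene_id"],
                sequence=tile_seqs[tid],
                backmap=tuple(tuple(s) for s in x["backmap"]),
                edges=tuple(SpliceEdge(*e) for e in x["edges"]),
            )
        )
    return tiles


# -- footprint arithmetic -------------------------------------------------

def hit_footprint(
    tile: Tile, start: int, length: int, min_overhang: int
) -> tuple[frozenset, dict]:
    """Graph elements observed by a read at ``[start, start+length)`` of a tile.

    Returns (elements, junction_overhangs).  Nodes require >= 1 base of
    overlap; edges require >= min_overhang bases on each side.
    """
    end = start + length
    elements = set()
    overhangs: dict[tuple, tuple[int, int]] = {}
    off = 0
    for i, (nid, _, ln) in enumerate(tile.backmap):
        span_start, span_end = off, off + ln
        if span_start < end and start < span_end:
            elements.add(node_key(tile.gene_id, nid))
        if i < len(tile.edges):
            boundary = span_end
            left = boundary - start
            right = end - boundary
            if left >= min_overhang and right >= min_overhang:
                e = tile.edges[i]
                elements.add(edge_key(tile.gene_id, e))
                if e.etype == JUNCTION:
                    overhangs[(tile.gene_id, e.from_node, e.to_node)] = (left, right)
        off += ln
    return frozenset(elements), overhangs


# -- alignment ------------------------------------------------------------

class TileIndex:
    """Exact k-mer seed index over a tile database (all genes)."""

    def __init__(self, tiles: Sequence[Tile], k: int = DEFAULT_KMER) -> None:
        self.tiles = list(tiles)
        self.k = k
        self.arrays = [
            np.frombuffer(t.sequence.encode(), dtype=np.uint8) for t in self.tiles
        ]
        self.kmers: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ti, t in enumerate(self.tiles):
            s = t.sequence
            for pos in range(len(s) - k + 1):
                self.kmers[s[pos : pos + k]].append((ti, pos))
        self.kmers = dict(self.kmers)


def align_read(
    read_id: str,
    seq: str,
    index: TileIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> AlignedRead:
    """Align one read; collapse equal graph footprints; flag ambiguity."""
    k = index.k
    L = len(seq)
    if L < k:
        return AlignedRead(read_id, "too_short")
    n_seeds = min(max_mismatch + 1, L // k)
    read_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_mask = read_arr == ord("N")
    candidates: set[tuple[int, int]] = set()
    for si in range(n_seeds):
        off = si * k
        for ti, pos in index.kmers.get(seq[off : off + k], ()):
            start = pos - off
            if start >= 0 and start + L <= len(index.tiles[ti].sequence):
                candidates.add((ti, start))
    footprints: dict[frozenset, AlignmentHit] = {}
    for ti, start in sorted(candidates):
        tile_arr = index.arrays[ti]
        seg = tile_arr[start : start + L]
        mm = int(np.count_nonzero(seg != read_arr))
        if n_mask.any():
            # N never matches, even against an N in the reference
            mm += int(np.count_nonzero(n_mask & (seg == read_arr)))
        if mm > max_mismatch:
            continue
        tile = index.tiles[ti]
        elements, overh = hit_footprint(tile, start, L, min_overhang)
        if elements not in footprints or mm < footprints[elements].mismatches:
            footprints[elements] = AlignmentHit(
                read_id, tile.tile_id, tile.gene_id, start, mm, elements, overh
            )
    if not footprints:
        return AlignedRead(read_id, "unaligned")
    if len(footprints) > 1:
        return AlignedRead(read_id, "ambiguous", n_locations=len(footprints))
    (hit,) = footprints.values()
    return AlignedRead(read_id, "unique", hit=hit, n_locations=1)


def align_reads(
    reads: Iterable[tuple[str, str, str]],
    index: TileIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> Iterator[AlignedRead]:
    for read_id, seq, _qual in reads:
        yield align_read(read_id, seq, index, max_mismatch, min_overhang)


def count_observations(aligned: Iterable[AlignedRead]) -> ObservationCounts:
    """Accumulate observation totals: every element of a unique read's
    footprint gains exactly +1."""
    counts = ObservationCounts()
    for read in aligned:
        counts.add(read)
    return counts


# -- SAM import/export ----------------------------------------------------

def import_sam(
    path,
    tiles: Sequence[Tile],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> Iterator[AlignedRead]:
    """Convert a SAM alignment against the exported tile FASTA into
    AlignedReads, applying the same footprint-collapsing and ambiguity
    rules as the internal matcher.

    The SAM must come from an ungapped aligner: any record whose CIGAR
    contains operations other than M/=/X is rejected.  Records for the
    same read name are grouped (the file need not be sorted).
    """
    by_id = {t.tile_id: t for t in tiles}
    per_read: dict[str, dict[frozenset, AlignmentHit]] = defaultdict(dict)
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            name = rec.query_name
            if name not in per_read:
                order.append(name)
                per_read[name]  # touch
            if rec.is_unmapped:
                continue
            tile = by_id.get(rec.reference_name)
            if tile is None:
                raise SpliceQuantError(
                    f"SAM reference {rec.reference_name!r} is not a known tile"
                )
            if any(op not in (0, 7, 8) for op, _ in rec.cigartuples or ()):
                raise SpliceQuantError(
                    f"read {name}: CIGAR {rec.cigarstring} contains indels/clips; "
                    "only ungapped alignments can be imported"
                )
            mm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            if mm > max_mismatch:
                continue
            L = rec.query_length or len(rec.query_sequence or "")
            elements, overh = hit_footprint(
                tile, rec.reference_start, L, min_overhang
            )
            hits = per_read[name]
            if elements not in hits or mm < hits[elements].mismatches:
                hits[elements] = AlignmentHit(
                    name, tile.tile_id, tile.gene_id, rec.reference_start,
                    mm, elements, overh,
                )
    for name in order:
        hits = per_read[name]
        if not hits:
            yield AlignedRead(name, "unaligned")
        elif len(hits) > 1:
            yield AlignedRead(name, "ambiguous", n_locations=len(hits))
        else:
            (hit,) = hits.values()
            yield AlignedRead(name, "unique", hit=hit, n_locations=1)
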
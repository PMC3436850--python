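"""Shared independent oracles and random-input generators for the tests.

Everything here deliberately avoids the code paths it is used to check:
event classification works from genomic coordinates instead of edge
types, path enumeration is a hand-written DFS instead of networkx, and
Fisher p-values come from scipy or from vectorized hypergeometric
enumeration rather than the package's integer-arithmetic routine.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy import stats

from splicequant.annotation_io import GenomicInterval, TranscriptModel
from splicequant.quant import QuantTable
from splicequant.splice_graph import JUNCTION, SpliceGraph
from splicequant.tiling_align import edge_key, node_key

# ---------------------------------------------------------------- fisher

def fisher_oracle_scipy(o_a, g_a, o_b, g_b) -> float:
    table = [[o_a, g_a - o_a], [o_b, g_b - o_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def fisher_oracle_hypergeom(o_a, g_a, o_b, g_b) -> float:
    """Exhaustive enumeration of the hypergeometric support using scipy's
    pmf (floating point), summing outcomes no more probable than observed."""
    r1, r2 = g_a, g_b
    c1 = o_a + o_b
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = stats.hypergeom.pmf(o_a, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


# ------------------------------------------------------- random gene sets

def random_gene_transcripts(
    rng: np.random.Generator,
    gene_id: str = "GR",
    chrom: str = "chrR",
    max_exons: int = 4,
    max_tx: int = 3,
    strand: str | None = None,
) -> list[TranscriptModel]:
    """Random small multi-transcript gene (introns always >= 5 bp)."""
    n_ex = int(rng.integers(2, max_exons + 1))
    pos = int(rng.integers(0, 30))
    exons = []
    for _ in range(n_ex):
        ln = int(rng.integers(8, 40))
        exons.append((pos, pos + ln))
        pos += ln + int(rng.integers(5, 30))
    if strand is None:
        strand = "+" if rng.integers(2) == 0 else "-"
    n_tx = int(rng.integers(1, max_tx + 1))
    txs = []
    for t in range(n_tx):
        keep = [i for i in range(n_ex) if rng.random() < 0.8]
        if not keep:
            keep = [int(rng.integers(n_ex))]
        ivs = [list(exons[i]) for i in keep]
        if rng.random() < 0.5:
            j = int(rng.integers(len(ivs)))
            s, e = ivs[j]
            d = int(rng.integers(0, (e - s) // 2 + 1))
            if rng.random() < 0.5:
                ivs[j] = [s + d, e]
            else:
                ivs[j] = [s, e - d]
        ordered = ivs if strand == "+" else list(reversed(ivs))
        txs.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t{t + 1}",
                gene_id=gene_id,
                exons=[GenomicInterval(chrom, s, e, strand) for s, e in ordered],
            )
        )
    return txs


def random_genome_for(transcripts, rng: np.random.Generator) -> dict[str, str]:
    """Random sequence dict covering every transcript's span."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    by_chrom: dict[str, int] = {}
    for t in transcripts:
        for e in t.exons:
            by_chrom[e.chrom] = max(by_chrom.get(e.chrom, 0), e.end)
    for chrom, ln in by_chrom.items():
        out[chrom] = bases[rng.integers(0, 4, size=ln + 10)].tobytes().decode()
    return out


# -------------------------------------------------------- event oracle

def _paths_between(graph: SpliceGraph, u: str, v: str):
    """All simple edge paths u -> v by plain recursive DFS."""
    out: dict[str, list] = {}
    order = graph.node_order
    for e in graph.edges:
        out.setdefault(e.from_node, []).append(e)
    res = []

    def dfs(node, acc, visited):
        if node == v:
            res.append(tuple(acc))
            return
        for e in out.get(node, []):
            if e.to_node in visited or order[e.to_node] > order[v]:
                continue
            dfs(e.to_node, acc + [e], visited | {e.to_node})

    if u == v:
        return [()]
    dfs(u, [], {u})
    return res


def _contiguous(graph: SpliceGraph, a: str, b: str) -> bool:
    iva = graph.node_by_id[a].interval
    ivb = graph.node_by_id[b].interval
    return iva.end == ivb.start if graph.strand == "+" else ivb.end == iva.start


def _classify_by_coords(graph, u, v, pa, pb) -> str:
    def internal(p):
        return [e.to_node for e in p[:-1]]

    ia, ib = internal(pa), internal(pb)
    if ia and ib:
        return "mutually_exclusive"
    if not ia and not ib:
        return "retained_intron"
    longer = pa if ia else pb
    chain = [u] + internal(longer) + [v]
    steps = [_contiguous(graph, x, y) for x, y in zip(chain, chain[1:])]
    if all(steps):
        return "retained_intron"
    if len(steps) >= 2 and all(steps[:-1]) and not steps[-1]:
        return "alt_donor"
    if len(steps) >= 2 and not steps[0] and all(steps[1:]):
        return "alt_acceptor"
    return "exon_skip" if len(internal(longer)) == 1 else "cassette_exons"


def _path_sig(start, edges):
    return (start, tuple(e.key() for e in edges))


def events_oracle(graph: SpliceGraph) -> Counter:
    """Brute-force enumeration of all anchored internally-disjoint path
    pairs (plus SOURCE/SINK convergences), classified from coordinates.

    Returns a canonical multiset for comparison with detect_events.
    """
    sigs = Counter()
    nodes = [n.node_id for n in graph.nodes]
    order = graph.node_order
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            paths = _paths_between(graph, u, v)
            for a in range(len(paths)):
                for b in range(a + 1, len(paths)):
                    pa, pb = paths[a], paths[b]
                    ia = {e.to_node for e in pa[:-1]}
                    ib = {e.to_node for e in pb[:-1]}
                    if ia & ib:
                        continue
                    et = _classify_by_coords(graph, u, v, pa, pb)
                    sigs[
                        (et, u, v, frozenset({_path_sig(u, pa), _path_sig(u, pb)}))
                    ] += 1

    def converge(anchors, reverse):
        found = Counter()
        srt = sorted(anchors, key=order.get)
        for x in range(len(srt)):
            for y in range(x + 1, len(srt)):
                s1, s2 = srt[x], srt[y]
                for v in nodes:
                    p1s = (
                        _paths_between(graph, s1, v)
                        if not reverse
                        else _paths_between(graph, v, s1)
                    )
                    p2s = (
                        _paths_between(graph, s2, v)
                        if not reverse
                        else _paths_between(graph, v, s2)
                    )
                    for p1 in p1s:
                        n1 = {s1} | {e.to_node for e in p1} | (
                            {e.from_node for e in p1} if reverse else set()
                        )
                        n1 |= {v}
                        for p2 in p2s:
                            n2 = {s2} | {e.to_node for e in p2} | (
                                {e.from_node for e in p2} if reverse else set()
                            )
                            n2 |= {v}
                            if n1 & n2 != {v}:
                                continue
                            start1 = s1 if not reverse else v
                            start2 = s2 if not reverse else v
                            found[
                                (
                                    frozenset({_path_sig(start1, p1), _path_sig(start2, p2)}),
                                    v,
                                )
                            ] += 1
        return found

    for (pair, v), cnt in converge(graph.start_nodes, reverse=False).items():
        sigs[("alt_promoter", "SOURCE", v, pair)] += cnt
    for (pair, v), cnt in converge(graph.end_nodes, reverse=True).items():
        sigs[("alt_terminator", v, "SINK", pair)] += cnt
    return sigs


def events_to_sigs(events) -> Counter:
    """Canonicalize detect_events output the same way as events_oracle."""
    sigs = Counter()
    for ev in events:
        def start_of(elements, edges):
            return edges[0].from_node if edges else elements[0]

        pa = _path_sig(start_of(ev.path_a, ev.path_a_edges), ev.path_a_edges)
        pb = _path_sig(start_of(ev.path_b, ev.path_b_edges), ev.path_b_edges)
        sigs[(ev.etype, ev.anchor_from, ev.anchor_to, frozenset({pa, pb}))] += 1
    return sigs


# -------------------------------------------------------- quant scaffolds

def quant_from_opkm(
    graph: SpliceGraph,
    node_opkm: dict | None = None,
    edge_opkm: dict | None = None,
    n_aligned: int = 1000,
    gene_total: int = 1000,
) -> QuantTable:
    """Hand-build a QuantTable with prescribed OPKM values (for traversal
    tests that do not need the alignment stage)."""
    gid = graph.gene_id
    opkm = {}
    raw = {}
    eff = {}
    for n in graph.nodes:
        k = node_key(gid, n.node_id)
        opkm[k] = float((node_opkm or {}).get(n.node_id, 0.0))
        raw[k] = int(opkm[k])
        eff[k] = n.length
    for e in graph.edges:
        k = edge_key(gid, e)
        opkm[k] = float((edge_opkm or {}).get((e.from_node, e.to_node), 0.0))
        raw[k] = int(opkm[k])
        eff[k] = 1
    return QuantTable(
        n_aligned=n_aligned,
        raw=raw,
        eff_len=eff,
        opkm=opkm,
        gene_opkm={gid: 1.0},
        gene_raw_total={gid: gene_total},
    )


def transcript_window_set(graph: SpliceGraph, node_seqs, read_len: int) -> set[str]:
    wins = set()
    for tx, path in graph.tx_paths.items():
        m = "".join(node_seqs[n] for n in path)
        for p in range(len(m) - read_len + 1):
            wins.add(m[p : p + read_len])
    return wins
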
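"""Tile generation, ungapped alignment, footprints and counting."""

from __future__ import annotations

import numpy as np
import pytest

from splicequant.annotation_io import GenomicInterval, TranscriptModel
from splicequant.errors import SpliceQuantError, ValidationError
from splicequant.simulate import expected_footprint
from splicequant.splice_graph import build_splice_graph, graph_sequence
from splicequant.tiling_align import (
    AlignedRead,
    TileIndex,
    align_read,
    count_observations,
    edge_key,
    generate_tiles,
    import_sam,
    node_key,
)

from helpers import (
    random_gene_transcripts,
    random_genome_for,
    transcript_window_set,
)


# ---------------------------------------------------------------- tiles

def test_single_short_node_yields_one_truncated_tile():
    t = TranscriptModel("T", "G", [GenomicInterval("c", 0, 5, "+")])
    g = build_splice_graph([t])
    tiles = generate_tiles(g, {"E1": "ACGTA"}, read_len=10, tile_len=19)
    assert len(tiles) == 1
    assert tiles[0].sequence == "ACGTA"
    assert tiles[0].backmap == (("E1", 0, 5),)


def test_skip_graph_tiles_consistent_and_complete(skip_graph):
    graph, seqs = skip_graph
    tiles = generate_tiles(graph, seqs, read_len=10, tile_len=19, step=10)
    edge_keys = {(e.from_node, e.to_node, e.etype) for e in graph.edges}
    backmaps = set()
    for t in tiles:
        assert t.backmap not in backmaps, "duplicate tile"
        backmaps.add(t.backmap)
        for e in t.edges:
            assert e.key() in edge_keys
        # spans after the first start at node offset 0
        for span in t.backmap[1:]:
            assert span[1] == 0
    # every 10-window of both transcript paths occurs inside >= 1 tile,
    # including those crossing the E1->E3 skip junction
    windows = transcript_window_set(graph, seqs, 10)
    tile_subs = {
        t.sequence[i : i + 10]
        for t in tiles
        for i in range(len(t.sequence) - 9)
    }
    assert windows <= tile_subs


def test_tile_parameter_validation(skip_graph):
    graph, seqs = skip_graph
    with pytest.raises(ValidationError):
        generate_tiles(graph, seqs, read_len=10, tile_len=9)
    with pytest.raises(ValidationError):
        generate_tiles(graph, seqs, read_len=10, tile_len=19, step=11)


@pytest.mark.parametrize("seed", range(15))
@pytest.mark.parametrize("read_len", [20, 36])
def test_tiling_completeness_random_graphs(seed, read_len):
    """Brute-force window enumeration: every transcript-path window of
    read length occurs wholly inside some tile."""
    rng = np.random.default_rng(300 + seed)
    txs = random_gene_transcripts(rng, max_exons=5, max_tx=3)
    graph = build_splice_graph(txs)
    seqs = graph_sequence(graph, random_genome_for(txs, rng))
    tiles = generate_tiles(graph, seqs, read_len=read_len)
    tile_subs = {
        t.sequence[i : i + read_len]
        for t in tiles
        for i in range(len(t.sequence) - read_len + 1)
    }
    assert transcript_window_set(graph, seqs, read_len) <= tile_subs


# ------------------------------------------------------------- alignment

@pytest.fixture(scope="module")
def skip_index(skip_graph):
    graph, seqs = skip_graph
    tiles = generate_tiles(graph, seqs, read_len=10, tile_len=19, step=10)
    return graph, seqs, TileIndex(tiles, k=8)


def test_exact_junction_read_single_collapsed_hit(skip_index):
    graph, seqs, index = skip_index
    read = seqs["E1"][-5:] + seqs["E3"][:5]
    res = align_read("r", read, index, max_mismatch=0, min_overhang=4)
    assert res.status == "unique"
    gid = graph.gene_id
    expect = {
        node_key(gid, "E1"),
        node_key(gid, "E3"),
        edge_key(gid, next(e for e in graph.edges
                           if (e.from_node, e.to_node) == ("E1", "E3"))),
    }
    assert set(res.hit.elements) == expect
    assert res.hit.junction_overhangs[(gid, "E1", "E3")] == (5, 5)


def test_small_overhang_excludes_junction_but_keeps_nodes(skip_index):
    graph, seqs, index = skip_index
    # 3 bases into E3 only: junction needs >= 4 on each side
    read = seqs["E1"][-7:] + seqs["E3"][:3]
    res = align_read("r", read, index, max_mismatch=0, min_overhang=4)
    assert res.status == "unique"
    kinds = {k[0] for k in res.hit.elements}
    assert kinds == {"node"}
    assert set(res.hit.elements) == {
        node_key(graph.gene_id, "E1"),
        node_key(graph.gene_id, "E3"),
    }


def test_read_matching_two_genes_is_ambiguous(skip_gene):
    transcripts, genome = skip_gene
    # identical second gene on another chromosome with identical sequence
    dup = [
        TranscriptModel(
            t.transcript_id + "d",
            "SKIP2",
            [GenomicInterval("chrT2", e.start, e.end, e.strand) for e in t.exons],
        )
        for t in transcripts
    ]
    genome2 = dict(genome)
    genome2["chrT2"] = genome["chrT"]
    tiles = []
    graphs = {}
    for txs in (transcripts, dup):
        g = build_splice_graph(txs)
        graphs[g.gene_id] = g
        tiles += generate_tiles(g, graph_sequence(g, genome2), read_len=10,
                                tile_len=19, step=10)
    index = TileIndex(tiles, k=8)
    read = genome["chrT"][10:20]
    res = align_read("r", read, index, max_mismatch=0)
    assert res.status == "ambiguous"
    counts = count_observations([res])
    assert counts.n_aligned == 0 and counts.n_ambiguous == 1
    assert not counts.element_obs


def test_n_bases_count_as_mismatches(skip_graph):
    graph, seqs = skip_graph
    tiles = generate_tiles(graph, seqs, read_len=20)
    index = TileIndex(tiles, k=8)
    read = seqs["E1"][:20]
    one_n = "N" + read[1:]
    assert align_read("r", one_n, index, max_mismatch=2).status == "unique"
    assert align_read("r", one_n, index, max_mismatch=0).status == "unaligned"
    three_n = "NNN" + read[3:]
    assert align_read("r", three_n, index, max_mismatch=2).status == "unaligned"


def test_read_shorter_than_seed_unaligned(skip_index):
    _, _, index = skip_index
    assert align_read("r", "ACGT", index).status == "too_short"


# ------------------------------------------------------------- counting

@pytest.fixture(scope="module")
def triple_junction_gene():
    """Gene whose middle exon (10 bp) lets a 20-bp read cross two
    junctions and three exons at once."""
    chrom = "chr3x"
    rng = np.random.default_rng(99)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {chrom: bases[rng.integers(0, 4, size=450)].tobytes().decode()}
    t1 = TranscriptModel(
        "T1",
        "TRI",
        [
            GenomicInterval(chrom, 0, 100, "+"),
            GenomicInterval(chrom, 200, 210, "+"),
            GenomicInterval(chrom, 300, 400, "+"),
        ],
    )
    graph = build_splice_graph([t1])
    seqs = graph_sequence(graph, genome)
    tiles = generate_tiles(graph, seqs, read_len=20)
    return graph, seqs, TileIndex(tiles, k=8)


def test_read_crossing_two_junctions_observes_five_elements(triple_junction_gene):
    graph, seqs, index = triple_junction_gene
    mrna = seqs["E1"] + seqs["E2"] + seqs["E3"]
    read = mrna[94:114]  # 6 in E1, all of E2, 4 in E3
    res = align_read("r", read, index, max_mismatch=0, min_overhang=4)
    assert res.status == "unique"
    counts = count_observations([res])
    assert counts.n_aligned == 1
    assert len(counts.element_obs) == 5
    assert all(v == 1 for v in counts.element_obs.values())
    kinds = sorted(k[0] for k in counts.element_obs)
    assert kinds == ["edge", "edge", "node", "node", "node"]
    assert counts.gene_totals["TRI"] == 1


def test_identical_reads_count_linearly(triple_junction_gene):
    graph, seqs, index = triple_junction_gene
    read = seqs["E1"][:20]
    results = [align_read(f"r{i}", read, index) for i in range(1000)]
    counts = count_observations(results)
    assert counts.n_aligned == 1000
    assert counts.element_obs[node_key("TRI", "E1")] == 1000


def test_empty_stream_all_zero():
    counts = count_observations([])
    assert counts.n_aligned == 0 and not counts.element_obs


def test_footprints_match_per_read_oracle(skip_graph):
    """Error-free transcript windows align with exactly the footprint
    their origin dictates.  Windows whose overhang into a branch is
    shorter than the mismatch-free distinguishing length may legitimately
    match both branches; those must be reported ambiguous, never
    misassigned."""
    graph, seqs = skip_graph
    R = 20
    tiles = generate_tiles(graph, seqs, read_len=R)
    index = TileIndex(tiles, k=16)
    results = []
    expected = []
    for tx, path in graph.tx_paths.items():
        m = "".join(seqs[n] for n in path)
        for pos in range(len(m) - R + 1):
            results.append(align_read(f"{tx}:{pos}", m[pos : pos + R],
                                      index, max_mismatch=0))
            expected.append(expected_footprint(graph, tx, pos, R))
    n_unique = 0
    total_obs = 0
    for res, exp in zip(results, expected):
        assert res.status in ("unique", "ambiguous")
        if res.status == "unique":
            assert res.hit.elements == exp
            n_unique += 1
            total_obs += len(exp)
    assert n_unique >= 0.95 * len(results)
    counts = count_observations(results)
    assert sum(counts.element_obs.values()) == total_obs
    assert counts.n_aligned == n_unique


# ------------------------------------------------------------- SAM import

def _sam_text(tiles, records):
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for t in tiles:
        lines.append(f"@SQ\tSN:{t.tile_id}\tLN:{len(t.sequence)}")
    lines.extend(records)
    return "\n".join(lines) + "\n"


def test_import_sam_matches_internal_matcher(tmp_path, skip_graph):
    """Placements discovered independently by substring search, written
    as SAM, produce the same counts as the internal matcher."""
    graph, seqs = skip_graph
    R = 20
    tiles = generate_tiles(graph, seqs, read_len=R)
    index = TileIndex(tiles, k=16)
    reads = []
    for tx, path in graph.tx_paths.items():
        m = "".join(seqs[n] for n in path)
        for pos in range(0, len(m) - R + 1, 7):
            reads.append((f"{tx}.{pos}", m[pos : pos + R]))

    records = []
    for rid, seq in reads:
        for t in tiles:
            start = t.sequence.find(seq)
            while start != -1:
                records.append(
                    f"{rid}\t0\t{t.tile_id}\t{start + 1}\t255\t{R}M\t*\t0\t0\t"
                    f"{seq}\t{'I' * R}\tNM:i:0"
                )
                start = t.sequence.find(seq, start + 1)
    sam = tmp_path / "hits.sam"
    sam.write_text(_sam_text(tiles, records))

    counts_sam = count_observations(import_sam(sam, tiles))
    counts_int = count_observations(
        align_read(rid, seq, index) for rid, seq in reads
    )
    assert counts_sam.n_aligned == counts_int.n_aligned == len(reads)
    assert dict(counts_sam.element_obs) == dict(counts_int.element_obs)
    assert dict(counts_sam.junction_overhangs) == dict(
        counts_int.junction_overhangs
    )


def test_import_sam_skips_unmapped_and_rejects_indels(tmp_path, skip_graph):
    graph, seqs = skip_graph
    tiles = generate_tiles(graph, seqs, read_len=20)
    seq20 = tiles[0].sequence[:20]
    unmapped = f"ru\t4\t*\t0\t0\t*\t*\t0\t0\t{seq20}\t{'I' * 20}"
    sam = tmp_path / "u.sam"
    sam.write_text(_sam_text(tiles, [unmapped]))
    (res,) = list(import_sam(sam, tiles))
    assert res.status == "unaligned"

    indel = f"ri\t0\t{tiles[0].tile_id}\t1\t255\t10M2D10M\t*\t0\t0\t{seq20}\t{'I' * 20}"
    sam2 = tmp_path / "i.sam"
    sam2.write_text(_sam_text(tiles, [indel]))
    with pytest.raises(SpliceQuantError, match="ungapped"):
        list(import_sam(sam2, tiles))


def test_import_sam_unknown_tile_errors(tmp_path, skip_graph):
    graph, seqs = skip_graph
    tiles = generate_tiles(graph, seqs, read_len=20)
    rec = f"rx\t0\tNOT_A_TILE\t1\t255\t5M\t*\t0\t0\tACGTA\tIIIII"
    sam = tmp_path / "x.sam"
    sam.write_text(
        _sam_text(tiles, []).replace(
            "@HD\tVN:1.6\tSO:unsorted",
            "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:NOT_A_TILE\tLN:100",
        )
        + rec
        + "\n"
    )
    with pytest.raises(SpliceQuantError, match="not a known tile"):
        list(import_sam(sam, tiles))
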
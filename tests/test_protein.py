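"""Weighted traversal, translation and functional-feature impact."""

from __future__ import annotations

import numpy as np
import pytest

from splicequant.annotation_io import GenomicInterval, ProteinFeature, TranscriptModel
from splicequant.errors import ValidationError
from splicequant.protein import (
    feature_impact,
    predict_proteins,
    translate_path,
    weighted_traversal,
)
from splicequant.splice_graph import build_splice_graph, graph_sequence

from helpers import quant_from_opkm, random_gene_transcripts

# ------------------------------------------------------------ traversal

def test_linear_graph_single_path_weight_one():
    t = TranscriptModel(
        "T", "G",
        [GenomicInterval("c", 0, 50, "+"), GenomicInterval("c", 100, 150, "+")],
    )
    g = build_splice_graph([t])
    quant = quant_from_opkm(g, node_opkm={"E1": 5.0}, edge_opkm={("E1", "E2"): 5.0})
    paths, pruned, flags = weighted_traversal(g, quant)
    assert [(p.path, p.weight) for p in paths] == [(("E1", "E2"), 1.0)]
    assert pruned == 0.0 and flags == []


def test_skip_graph_branch_split_proportional_to_opkm(skip_graph):
    graph, _ = skip_graph
    quant = quant_from_opkm(
        graph,
        node_opkm={"E1": 40.0},
        edge_opkm={("E1", "E2"): 30.0, ("E1", "E3"): 10.0, ("E2", "E3"): 20.0},
    )
    paths, pruned, _ = weighted_traversal(graph, quant)
    assert {p.path: pytest.approx(p.weight) for p in paths} == {
        ("E1", "E2", "E3"): pytest.approx(0.75),
        ("E1", "E3"): pytest.approx(0.25),
    }
    assert pruned == pytest.approx(0.0)


def test_min_ratio_prunes_minor_path_and_reports_mass(skip_graph):
    graph, _ = skip_graph
    quant = quant_from_opkm(
        graph,
        node_opkm={"E1": 40.0},
        edge_opkm={("E1", "E2"): 30.0, ("E1", "E3"): 10.0, ("E2", "E3"): 20.0},
    )
    paths, pruned, _ = weighted_traversal(graph, quant, min_ratio=0.5)
    assert [p.path for p in paths] == [("E1", "E2", "E3")]
    assert paths[0].weight == pytest.approx(0.75)
    assert pruned == pytest.approx(0.25)


def test_zero_read_gene_returns_heaviest_annotated_path(skip_graph):
    graph, _ = skip_graph
    quant = quant_from_opkm(graph, gene_total=0)
    paths, pruned, flags = weighted_traversal(graph, quant)
    assert flags == ["no-data"]
    assert [(p.path, p.weight) for p in paths] == [(("E1", "E2", "E3"), 1.0)]
    assert pruned == 0.0


def test_zero_depth_branches_split_equally(skip_graph):
    graph, _ = skip_graph
    quant = quant_from_opkm(graph, node_opkm={"E1": 1.0})  # edges all zero
    paths, pruned, _ = weighted_traversal(graph, quant)
    weights = {p.path: p.weight for p in paths}
    assert weights[("E1", "E2", "E3")] == pytest.approx(0.5)
    assert weights[("E1", "E3")] == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(20))
@pytest.mark.parametrize("min_ratio", [0.01, 0.2])
def test_weight_conservation_random_graphs(seed, min_ratio):
    """Reported path weights plus pruned mass equal 1 within 1e-9."""
    rng = np.random.default_rng(60 + seed)
    graph = build_splice_graph(random_gene_transcripts(rng, max_exons=5))
    node_opkm = {n.node_id: float(rng.uniform(0, 50)) for n in graph.nodes}
    edge_opkm = {
        (e.from_node, e.to_node): float(rng.uniform(0, 50)) for e in graph.edges
    }
    quant = quant_from_opkm(graph, node_opkm, edge_opkm)
    paths, pruned, _ = weighted_traversal(graph, quant, min_ratio=min_ratio)
    assert sum(p.weight for p in paths) + pruned == pytest.approx(1.0, abs=1e-9)
    assert all(p.weight >= min_ratio for p in paths)


# ----------------------------------------------------------- translation

def _one_node_gene(seq, gene="G1"):
    t = TranscriptModel(
        "T", gene, [GenomicInterval("c", 0, len(seq), "+")]
    )
    g = build_splice_graph([t])
    return g, {"E1": seq}, [t]


def test_translate_simple_orf():
    g, seqs, txs = _one_node_gene("ATGAAATAG")
    form = translate_path(g, ["E1"], seqs, txs)
    assert form.protein == "MK"
    assert form.orf_start == 0
    assert "unannotated-start" in form.flags


def test_translate_no_start_codon_non_coding():
    g, seqs, txs = _one_node_gene("CCCCCCGGGTTT")
    form = translate_path(g, ["E1"], seqs, txs)
    assert form.protein == "" and "non-coding" in form.flags


# three-exon coding gene used for skip/feature fixtures
E1 = "C" * 9 + "ATG" + "GCT" * 36          # 120 bp, ATG at 9
E2_INFRAME = "GAA" * 33                     # 99 bp, divisible by 3
E2_SHIFT = "GAA" * 33 + "G"                 # 100 bp, frameshifting
E3 = "GGT" * 20 + "TAA" + "C" * 57          # 120 bp


def _coding_gene(e2_seq):
    chrom = "cX"
    L2 = len(e2_seq)
    genome = {
        chrom: E1 + "T" * 80 + e2_seq + "T" * (200 - L2 - 80 + 100) + E3
    }
    # exon coordinates: e1 0-120, e2 200-200+L2, e3 400-520
    genome[chrom] = (
        E1 + "T" * 80 + e2_seq + "T" * (400 - (200 + L2)) + E3
    )
    mk = lambda s, e: GenomicInterval(chrom, s, e, "+")
    t1 = TranscriptModel(
        "T1", "GX",
        [mk(0, 120), mk(200, 200 + L2), mk(400, 520)],
        cds=[mk(9, 120), mk(200, 200 + L2), mk(400, 460)],
    )
    t2 = TranscriptModel("T2", "GX", [mk(0, 120), mk(400, 520)])
    graph = build_splice_graph([t1, t2])
    seqs = graph_sequence(graph, genome)
    return graph, seqs, [t1, t2]


def test_in_frame_skip_shortens_protein_by_exon_codons():
    graph, seqs, txs = _coding_gene(E2_INFRAME)
    incl = translate_path(graph, ["E1", "E2", "E3"], seqs, txs)
    skip = translate_path(graph, ["E1", "E3"], seqs, txs)
    assert incl.orf_start == 9 and skip.orf_start == 9
    assert len(incl.protein) - len(skip.protein) == 33
    assert incl.protein[:37] == skip.protein[:37]  # M + 36 Ala
    assert incl.protein[-20:] == skip.protein[-20:]  # Gly run from E3


FEATS = [
    ProteinFeature("F_shared", "P1", 2, 10, "DOMAIN", "in exon 1", "T1"),
    ProteinFeature("F_skip", "P1", 38, 70, "DOMAIN", "in exon 2", "T1"),
    ProteinFeature("F_down", "P1", 72, 80, "DOMAIN", "in exon 3", "T1"),
]


def test_feature_impact_in_frame_skip():
    graph, seqs, txs = _coding_gene(E2_INFRAME)
    tx_by_id = {t.transcript_id: t for t in txs}
    incl = translate_path(graph, ["E1", "E2", "E3"], seqs, txs)
    present, lost, _ = feature_impact(incl, FEATS, graph, tx_by_id)
    assert set(present) == {"F_shared", "F_skip", "F_down"} and lost == []

    skip = translate_path(graph, ["E1", "E3"], seqs, txs)
    present, lost, flags = feature_impact(skip, FEATS, graph, tx_by_id)
    assert set(present) == {"F_shared", "F_down"}
    assert lost == ["F_skip"] and "truncated" not in flags.values()


def test_frameshifting_skip_loses_downstream_features():
    graph, seqs, txs = _coding_gene(E2_SHIFT)
    tx_by_id = {t.transcript_id: t for t in txs}
    feats = [
        ProteinFeature("F_shared", "P1", 2, 10, "DOMAIN", "", "T1"),
        ProteinFeature("F_down", "P1", 72, 80, "DOMAIN", "", "T1"),
    ]
    incl = translate_path(graph, ["E1", "E2", "E3"], seqs, txs)
    present, lost, _ = feature_impact(incl, feats, graph, tx_by_id)
    assert set(present) == {"F_shared", "F_down"}

    skip = translate_path(graph, ["E1", "E3"], seqs, txs)
    present, lost, flags = feature_impact(skip, feats, graph, tx_by_id)
    assert present == ["F_shared"]
    assert lost == ["F_down"] and flags["F_down"] == "frameshift"


def test_partially_spliced_feature_flagged_truncated():
    graph, seqs, txs = _coding_gene(E2_INFRAME)
    tx_by_id = {t.transcript_id: t for t in txs}
    straddle = [ProteinFeature("F_str", "P1", 30, 45, "DOMAIN", "", "T1")]
    skip = translate_path(graph, ["E1", "E3"], seqs, txs)
    present, lost, flags = feature_impact(skip, straddle, graph, tx_by_id)
    assert lost == ["F_str"] and flags["F_str"] == "truncated"


def test_feature_beyond_cds_is_validation_error():
    graph, seqs, txs = _coding_gene(E2_INFRAME)
    tx_by_id = {t.transcript_id: t for t in txs}
    bad = [ProteinFeature("F_bad", "P1", 1, 5000, "DOMAIN", "", "T1")]
    form = translate_path(graph, ["E1", "E2", "E3"], seqs, txs)
    with pytest.raises(ValidationError, match="beyond the CDS"):
        feature_impact(form, bad, graph, tx_by_id)


def test_predict_proteins_combines_stages(skip_graph):
    graph, seqs = skip_graph
    quant = quant_from_opkm(
        graph,
        node_opkm={"E1": 10.0},
        edge_opkm={("E1", "E2"): 30.0, ("E1", "E3"): 10.0, ("E2", "E3"): 30.0},
    )
    txs = [
        TranscriptModel(
            "T1", "SKIP",
            [GenomicInterval("chrT", 0, 100, "+"),
             GenomicInterval("chrT", 200, 300, "+"),
             GenomicInterval("chrT", 400, 500, "+")],
        )
    ]
    forms, pruned, _ = predict_proteins(graph, quant, seqs, txs)
    assert len(forms) == 2
    assert forms[0].ratio == pytest.approx(0.75)
    assert sum(f.ratio for f in forms) + pruned == pytest.approx(1.0, abs=1e-9)
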
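"""Shared fixtures: small hand-built gene models with known structure."""

from __future__ import annotations

import numpy as np
import pytest

from splicequant.annotation_io import GenomicInterval, TranscriptModel
from splicequant.splice_graph import build_splice_graph, graph_sequence


def _random_chrom(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bases[rng.integers(0, 4, size=length)].tobytes().decode()


@pytest.fixture(scope="session")
def skip_gene():
    """Three-exon gene with an exon-skipping isoform.

    T1: (0,100) -> (200,300) -> (400,500); T2: (0,100) -> (400,500), plus
    a random genome in which every 10-mer of both mRNAs is unique.
    """
    chrom = "chrT"
    mk = lambda s, e: GenomicInterval(chrom, s, e, "+")
    t1 = TranscriptModel("T1", "SKIP", [mk(0, 100), mk(200, 300), mk(400, 500)])
    t2 = TranscriptModel("T2", "SKIP", [mk(0, 100), mk(400, 500)])
    genome = {chrom: _random_chrom(12345, 600)}
    return [t1, t2], genome


@pytest.fixture(scope="session")
def skip_graph(skip_gene):
    transcripts, genome = skip_gene
    graph = build_splice_graph(transcripts)
    seqs = graph_sequence(graph, genome)
    return graph, seqs


@pytest.fixture(scope="session")
def overlap_gene():
    """Alternative-donor gene: T1 (0,100)->(400,500), T2 (0,120)->(400,500)."""
    chrom = "chrO"
    t1 = TranscriptModel(
        "T1",
        "OVL",
        [GenomicInterval(chrom, 0, 100, "+"), GenomicInterval(chrom, 400, 500, "+")],
    )
    t2 = TranscriptModel(
        "T2",
        "OVL",
        [GenomicInterval(chrom, 0, 120, "+"), GenomicInterval(chrom, 400, 500, "+")],
    )
    genome = {chrom: _random_chrom(54321, 600)}
    return [t1, t2], genome


@pytest.fixture(scope="session")
def overlap_graph(overlap_gene):
    transcripts, genome = overlap_gene
    graph = build_splice_graph(transcripts)
    seqs = graph_sequence(graph, genome)
    return graph, seqs
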
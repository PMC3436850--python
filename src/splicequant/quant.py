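"""OPKM normalization.

OPKM (observations per kilobase per million aligned reads) differs from
RPKM in that a read contributes to *every* graph element it observes —
each exon it overlaps and each junction it crosses — rather than being
counted once:

    OPKM_e = O_e * 1e9 / (L_e * N_aligned)

where ``O_e`` is the raw observation total, ``L_e`` the element's
effective length in bases, and ``N_aligned`` the number of unambiguously
aligned reads in the sample.  For a sub-exon node the effective length
is its genomic length.  For an edge (junction or adjacency) it is
``R - 2*min_overhang + 1`` — the number of read start positions that
cross the boundary with valid overhang on both sides — which equalizes
expected OPKM across element types under uniform coverage.

The gene-level OPKM uses the union (sub-exon) length of the graph as
denominator, which the unique-location property makes well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .splice_graph import SpliceGraph
from .tiling_align import (
    DEFAULT_MIN_OVERHANG,
    ElementKey,
    ObservationCounts,
    edge_key,
    node_key,
)


def junction_effective_length(read_len: int, min_overhang: int = DEFAULT_MIN_OVERHANG) -> int:
    return read_len - 2 * min_overhang + 1


@dataclass
class QuantTable:
    """Per-element raw totals, effective lengths and OPKM for one sample."""

    n_aligned: int
    raw: dict  # ElementKey -> int
    eff_len: dict  # ElementKey -> int
    opkm: dict  # ElementKey -> float
    gene_opkm: dict  # gene_id -> float
    gene_raw_total: dict  # gene_id -> int (reads whose footprint hits the gene)

    def opkm_of(self, key: ElementKey) -> float:
        return self.opkm.get(key, 0.0)

    def raw_of(self, key: ElementKey) -> int:
        return self.raw.get(key, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.raw):
            if key[0] == "node":
                gene, elem, etype = key[1], key[2], "node"
            else:
                gene, elem, etype = key[1], f"{key[2]}>{key[3]}", key[4]
            rows.append(
                {
                    "gene_id": gene,
                    "element_id": elem,
                    "element_type": etype,
                    "raw": self.raw[key],
                    "effective_length": self.eff_len[key],
                    "opkm": self.opkm[key],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "element_id", "element_type",
                "raw", "effective_length", "opkm",
            ],
        )


def compute_opkm(
    counts: ObservationCounts,
    graphs: Mapping[str, SpliceGraph],
    read_len: int,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> QuantTable:
    """OPKM for every node and edge of every graph (zeros included).

    With ``N_aligned == 0`` every OPKM is defined as 0.
    """
    N = counts.n_aligned
    scale = 1e9 / N if N > 0 else 0.0
    edge_len = junction_effective_length(read_len, min_overhang)
    raw: dict[ElementKey, int] = {}
    eff: dict[ElementKey, int] = {}
    opkm: dict[ElementKey, float] = {}
    gene_opkm: dict[str, float] = {}
    gene_raw: dict[str, int] = {}
    for gid in sorted(graphs):
        g = graphs[gid]
        node_o_sum = 0
        node_l_sum = 0
        for n in g.nodes:
            key = node_key(gid, n.node_id)
            o = counts.element_obs.get(key, 0)
            raw[key] = o
            eff[key] = n.length
            opkm[key] = o * scale / n.length
            node_o_sum += o
            node_l_sum += n.length
        for e in g.edges:
            key = edge_key(gid, e)
            o = counts.element_obs.get(key, 0)
            raw[key] = o
            eff[key] = edge_len
            opkm[key] = o * scale / edge_len
        gene_opkm[gid] = node_o_sum * scale / node_l_sum if node_l_sum else 0.0
        gene_raw[gid] = counts.gene_totals.get(gid, 0)
    return QuantTable(
        n_aligned=N,
        raw=raw,
        eff_len=eff,
        opkm=opkm,
        gene_opkm=gene_opkm,
        gene_raw_total=gene_raw,
    )


def rpkm_per_gene(counts: ObservationCounts, graphs: Mapping[str, SpliceGraph]) -> dict[str, float]:
    """Conventional RPKM per gene (each aligned read counted once),
    emitted only for comparison with gene OPKM."""
    N = counts.n_aligned
    scale = 1e9 / N if N > 0 else 0.0
    return {
        gid: counts.gene_totals.get(gid, 0) * scale / graphs[gid].exonic_length
        for gid in sorted(graphs)
    }
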
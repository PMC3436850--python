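"""Two-sample splice comparison: splice index and Fisher's exact test.

For each graph element the splice index contrasts the element's
gene-normalized observation fraction between samples A and B on a log2
scale:

    SI = log2((O_A + c) / (G_A + c)) - log2((O_B + c) / (G_B + c))

with ``O`` the element's raw observation total, ``G`` the gene's total
aligned reads in that sample, and ``c`` a pseudocount (default 1; c = 0
allowed).  Dividing by the gene total makes SI exactly invariant to
uniform gene-expression scaling: only redistribution of reads among a
gene's elements moves it.

Significance comes from a two-sided Fisher's exact test on the 2x2 table
[[O_A, G_A - O_A], [O_B, G_B - O_B]] — element reads versus remaining
gene reads per sample — the only 2x2 from the available counts that
conditions out gene expression.  The two-sided p-value is the classical
"sum of all hypergeometric outcomes no more probable than the observed
one", computed here in exact integer arithmetic over the support.
Benjamini–Hochberg FDR is applied across all testable elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .events import ASEvent, event_active
from .quant import QuantTable
from .splice_graph import JUNCTION, SpliceGraph
from .tiling_align import ObservationCounts, edge_key, node_key

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_SI_MIN = 1.0
DEFAULT_Q_MAX = 0.05


def splice_index(
    o_a: int, g_a: int, o_b: int, g_b: int, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Log2 contrast of gene-normalized observation fractions."""
    if not (0 <= o_a <= g_a and 0 <= o_b <= g_b):
        raise ValidationError("require 0 <= O <= G in both samples")
    c = pseudocount
    return math.log2((o_a + c) / (g_a + c)) - math.log2((o_b + c) / (g_b + c))


def fisher_element(o_a: int, g_a: int, o_b: int, g_b: int) -> tuple[float, bool]:
    """Two-sided Fisher exact p for [[O_A, G_A-O_A], [O_B, G_B-O_B]].

    Returns ``(p, testable)``; any zero margin gives p = 1 by convention
    with ``testable = False``.  The sum-of-small-tables p is computed by
    exhaustive enumeration of the hypergeometric support with exact
    integer weights, so ties are handled without floating-point fudge.
    """
    if not (0 <= o_a <= g_a and 0 <= o_b <= g_b):
        raise ValidationError("require 0 <= O <= G in both samples")
    r1, r2 = g_a, g_b
    c1 = o_a + o_b
    n = r1 + r2
    c2 = n - c1
    if min(r1, r2, c1, c2) == 0:
        return 1.0, False
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = math.comb(c1, o_a) * math.comb(c2, r1 - o_a)
    num = sum(
        w
        for k in range(lo, hi + 1)
        if (w := math.comb(c1, k) * math.comb(c2, r1 - k)) <= w_obs
    )
    return num / math.comb(n, r1), True


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def compare_samples(
    quant_a: QuantTable,
    quant_b: QuantTable,
    counts_a: ObservationCounts,
    counts_b: ObservationCounts,
    graphs: Mapping[str, SpliceGraph],
    events_by_gene: Optional[Mapping[str, list[ASEvent]]] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    si_min: float = DEFAULT_SI_MIN,
    q_max: float = DEFAULT_Q_MAX,
    min_junction_reads: int = 2,
    min_overhang: int = 4,
    min_exon_reads: int = 1,
) -> pd.DataFrame:
    """Per-element comparison rows for every node and junction.

    A gene is flagged differentially spliced when at least one of its
    elements has |SI| >= ``si_min``, q <= ``q_max`` and belongs to an
    event that is active in at least one of the two samples.
    """
    rows = []
    for gid in sorted(graphs):
        g = graphs[gid]
        g_a = counts_a.gene_totals.get(gid, 0)
        g_b = counts_b.gene_totals.get(gid, 0)
        elems: list[tuple[str, str, tuple]] = []
        for n in g.nodes:
            elems.append((n.node_id, "node", node_key(gid, n.node_id)))
        for e in g.edges:
            if e.etype == JUNCTION:
                elems.append((e.label(), "junction", edge_key(gid, e)))
        for elem_id, etype, key in elems:
            o_a = quant_a.raw_of(key)
            o_b = quant_b.raw_of(key)
            si = splice_index(o_a, g_a, o_b, g_b, pseudocount)
            if g_a > 0 and g_b > 0:
                p, testable = fisher_element(o_a, g_a, o_b, g_b)
            else:
                p, testable = 1.0, False
            rows.append(
                {
                    "gene_id": gid,
                    "element_id": elem_id,
                    "element_type": etype,
                    "O_A": o_a,
                    "O_B": o_b,
                    "G_A": g_a,
                    "G_B": g_b,
                    "SI": si,
                    "p": p,
                    "testable": testable,
                    "_key": key,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        df["q"] = []
        df["in_active_event"] = []
        df["gene_flagged"] = []
        return df.drop(columns=["_key"], errors="ignore")

    df["q"] = 1.0
    mask = df["testable"].to_numpy()
    if mask.any():
        df.loc[mask, "q"] = bh_adjust(df.loc[mask, "p"].to_list())

    # membership of elements in events active in >= 1 sample
    active_elems: set = set()
    if events_by_gene:
        for gid, evs in events_by_gene.items():
            for ev in evs:
                act = any(
                    event_active(
                        ev, c, min_junction_reads, min_overhang, min_exon_reads
                    )
                    for c in (counts_a, counts_b)
                )
                if not act:
                    continue
                for e in ev.path_a_edges + ev.path_b_edges:
                    active_elems.add(edge_key(gid, e))
                for nid in ev.path_a_nodes + ev.path_b_nodes:
                    active_elems.add(node_key(gid, nid))
    df["in_active_event"] = [k in active_elems for k in df["_key"]]

    hit = (
        (df["SI"].abs() >= si_min)
        & (df["q"] <= q_max)
        & df["testable"]
        & df["in_active_event"]
    )
    flagged_genes = set(df.loc[hit, "gene_id"])
    df["gene_flagged"] = df["gene_id"].isin(flagged_genes)
    return df.drop(columns=["_key"])


def flagged_genes(comparison: pd.DataFrame) -> list[str]:
    if comparison.empty:
        return []
    return sorted(comparison.loc[comparison["gene_flagged"], "gene_id"].unique())
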
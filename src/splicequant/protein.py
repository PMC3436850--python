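"""Protein isoform prediction by depth-weighted graph traversal.

Starting weights are distributed over the graph's start nodes in
proportion to their OPKM; at every branch node the outgoing weight is
split in proportion to the outgoing edges' OPKM (equally when all are
zero).  A path's weight — the product of its branch fractions times its
start weight — estimates the relative concentration of the isoform it
spells out.  Depth-first enumeration prunes any partial path whose
weight falls below ``min_ratio`` and reports the pruned mass, so
reported weights plus pruned mass always sum to one.

Each surviving path is translated: the mRNA is the concatenation of the
path's node sequences in transcription orientation; the ORF starts at an
annotated CDS start whose genomic position lies on the path (the most
upstream such start if several transcripts qualify) or, failing that, at
the first AUG; translation uses the standard genetic code up to the
first stop.  Protein functional features are then mapped through their
annotation transcript's CDS by codon arithmetic (amino acid *i* occupies
CDS bases ``3(i-1)..3i-1`` in transcription order) and checked against
the path: a feature is *present* only if every one of its coding bases
lies on the path, in the same reading frame as in the annotation
transcript, and inside the path's translated ORF; otherwise it is lost
(with a ``truncated`` sub-flag when only part of it remains).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .annotation_io import ProteinFeature, TranscriptModel
from .errors import ValidationError
from .quant import QuantTable
from .splice_graph import SpliceGraph
from .tiling_align import edge_key, node_key

DEFAULT_MIN_RATIO = 0.01
START_CODON = "ATG"


@dataclass
class IsoformPath:
    path: tuple[str, ...]  # node ids, start node to end node
    weight: float


@dataclass
class ProteinForm:
    gene_id: str
    path: tuple[str, ...]
    ratio: float
    mrna: str
    protein: str
    orf_start: Optional[int]  # mRNA offset of the first coding base
    flags: tuple[str, ...] = ()
    features_present: tuple[str, ...] = ()
    features_lost: tuple[str, ...] = ()
    lost_flags: dict = field(default_factory=dict)  # feature_id -> sub-flag


def _heaviest_annotated_path(graph: SpliceGraph) -> tuple[str, ...]:
    """Fallback path for a gene without read data: the annotated
    transcript with the largest exonic length (ties broken by id)."""
    def total_len(p):
        return sum(graph.node_by_id[n].length for n in p)

    best = min(
        graph.tx_paths.items(), key=lambda kv: (-total_len(kv[1]), kv[0])
    )
    return tuple(best[1])


def weighted_traversal(
    graph: SpliceGraph,
    quant: QuantTable,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> tuple[list[IsoformPath], float, list[str]]:
    """Enumerate isoform paths with depth-proportional weights.

    Returns ``(paths, pruned_mass, flags)``.  Paths are sorted by
    descending weight.  A gene with no aligned reads yields its heaviest
    annotated path at weight 1 and the ``no-data`` flag.
    """
    gid = graph.gene_id
    flags: list[str] = []
    if quant.gene_raw_total.get(gid, 0) == 0:
        return [IsoformPath(_heaviest_annotated_path(graph), 1.0)], 0.0, ["no-data"]

    starts = sorted(graph.start_nodes, key=graph.node_order.get)
    start_opkm = [quant.opkm_of(node_key(gid, s)) for s in starts]
    total = sum(start_opkm)
    if total > 0:
        start_w = [x / total for x in start_opkm]
    else:
        start_w = [1.0 / len(starts)] * len(starts)
        flags.append("uniform-start-weights")

    results: list[IsoformPath] = []
    pruned = 0.0

    def walk(node: str, weight: float, path: list[str]) -> None:
        nonlocal pruned
        if weight <= 0.0:
            return
        outs = graph.out_edges(node)
        if not outs:
            results.append(IsoformPath(tuple(path), weight))
            return
        opkms = [quant.opkm_of(edge_key(gid, e)) for e in outs]
        tot = sum(opkms)
        fracs = (
            [x / tot for x in opkms] if tot > 0 else [1.0 / len(outs)] * len(outs)
        )
        for e, f in zip(outs, fracs):
            w = weight * f
            if w < min_ratio:
                pruned += w
            else:
                walk(e.to_node, w, path + [e.to_node])

    for s, w in zip(starts, start_w):
        if w < min_ratio:
            pruned += w
        else:
            walk(s, w, [s])

    results.sort(key=lambda p: (-p.weight, p.path))
    return results, pruned, flags


# -- coordinate helpers ----------------------------------------------------

def _node_positions(graph: SpliceGraph, node_id: str) -> range:
    iv = graph.node_by_id[node_id].interval
    if graph.strand == "+":
        return range(iv.start, iv.end)
    return range(iv.end - 1, iv.start - 1, -1)


def path_position_map(graph: SpliceGraph, path: Sequence[str]) -> dict[int, int]:
    """Genomic position -> mRNA offset along a path, in transcription order."""
    out: dict[int, int] = {}
    i = 0
    for nid in path:
        for pos in _node_positions(graph, nid):
            out[pos] = i
            i += 1
    return out


def cds_positions(tx: TranscriptModel) -> list[int]:
    """Genomic positions of a transcript's CDS bases in transcription order."""
    if not tx.cds:
        raise ValidationError(f"transcript {tx.transcript_id} has no CDS")
    out: list[int] = []
    for iv in tx.cds:
        if tx.strand == "+":
            out.extend(range(iv.start, iv.end))
        else:
            out.extend(range(iv.end - 1, iv.start - 1, -1))
    return out


def translate_path(
    graph: SpliceGraph,
    path: Sequence[str],
    node_seqs: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    ratio: float = 1.0,
) -> ProteinForm:
    """Build the mRNA of a path, pick its ORF start and translate it."""
    mrna = "".join(node_seqs[n] for n in path)
    pos_map = path_position_map(graph, path)
    flags: list[str] = []

    # annotated CDS starts whose genomic position lies on the path,
    # most upstream (in the path's own mRNA) first
    candidates = []
    for tx in sorted(transcripts, key=lambda t: t.transcript_id):
        if not tx.cds or tx.gene_id != graph.gene_id:
            continue
        first = cds_positions(tx)[0]
        if first in pos_map:
            candidates.append((pos_map[first], tx.transcript_id))
    if candidates:
        orf_start = min(candidates)[0]
    else:
        found = mrna.find(START_CODON)
        orf_start = found if found >= 0 else None
        if candidates == [] and orf_start is not None:
            flags.append("unannotated-start")

    if orf_start is None:
        return ProteinForm(
            gene_id=graph.gene_id,
            path=tuple(path),
            ratio=ratio,
            mrna=mrna,
            protein="",
            orf_start=None,
            flags=tuple(flags + ["non-coding"]),
        )
    coding = mrna[orf_start:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate(to_stop=True))
    return ProteinForm(
        gene_id=graph.gene_id,
        path=tuple(path),
        ratio=ratio,
        mrna=mrna,
        protein=protein,
        orf_start=orf_start,
        flags=tuple(flags),
    )


def feature_impact(
    form: ProteinForm,
    features: Sequence[ProteinFeature],
    graph: SpliceGraph,
    transcripts_by_id: Mapping[str, TranscriptModel],
) -> tuple[list[str], list[str], dict]:
    """Classify each feature as present in or lost from a protein form.

    Returns ``(present_ids, lost_ids, lost_subflags)`` and also stores
    them on ``form``.
    """
    pos_map = path_position_map(graph, form.path)
    present: list[str] = []
    lost: list[str] = []
    subflags: dict[str, str] = {}
    orf_ok = form.orf_start is not None
    orf_end = (form.orf_start + 3 * len(form.protein)) if orf_ok else -1

    for feat in features:
        tx = transcripts_by_id[feat.mapping_transcript_id]
        positions = cds_positions(tx)
        if 3 * feat.aa_end > len(positions):
            raise ValidationError(
                f"feature {feat.feature_id} extends beyond the CDS of "
                f"{tx.transcript_id} ({len(positions) // 3} aa)"
            )
        bases = positions[3 * (feat.aa_start - 1) : 3 * feat.aa_end]
        on_path = [b in pos_map for b in bases]
        if orf_ok and all(on_path):
            ok = True
            for j, b in zip(
                range(3 * (feat.aa_start - 1), 3 * feat.aa_end), bases
            ):
                idx = pos_map[b]
                if not (form.orf_start <= idx < orf_end):
                    ok = False
                    break
                if (idx - form.orf_start) % 3 != j % 3:
                    ok = False
                    subflags[feat.feature_id] = "frameshift"
                    break
            if ok:
                present.append(feat.feature_id)
                continue
            subflags.setdefault(feat.feature_id, "out-of-orf")
        elif any(on_path):
            subflags[feat.feature_id] = "truncated"
        lost.append(feat.feature_id)

    form.features_present = tuple(present)
    form.features_lost = tuple(lost)
    form.lost_flags = subflags
    return present, lost, subflags


def predict_proteins(
    graph: SpliceGraph,
    quant: QuantTable,
    node_seqs: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    features: Sequence[ProteinFeature] = (),
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> tuple[list[ProteinForm], float, list[str]]:
    """Full protein stage for one gene: traversal, translation, feature impact."""
    paths, pruned, flags = weighted_traversal(graph, quant, min_ratio)
    tx_by_id = {t.transcript_id: t for t in transcripts}
    gene_feats = [
        f
        for f in features
        if f.mapping_transcript_id in tx_by_id
        and tx_by_id[f.mapping_transcript_id].gene_id == graph.gene_id
    ]
    forms = []
    for p in paths:
        form = translate_path(graph, p.path, node_seqs, transcripts, ratio=p.weight)
        form.flags = tuple(list(form.flags) + flags)
        if gene_feats:
            feature_impact(form, gene_feats, graph, tx_by_id)
        forms.append(form)
    return forms, pruned, flags
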
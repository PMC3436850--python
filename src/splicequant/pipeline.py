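"""Single-sample and two-sample pipelines tying the stages together.

``run_single`` executes align -> count -> quant -> events -> protein for
one FASTQ; ``run_compare`` aligns two samples against the same graph
database and runs the splice-index / Fisher comparison.  Every output
TSV carries ``#``-prefixed metadata lines recording the package version,
the configuration and the graph-database checksum, so outputs are
reproducible and comparisons across mismatched databases are refused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .annotation_io import (
    ProteinFeature,
    TranscriptModel,
    group_by_gene,
    read_feature_table,
    read_gtf,
    read_reads,
    validate_features,
    write_table,
)
from .compare import (
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_Q_MAX,
    DEFAULT_SI_MIN,
    compare_samples,
)
from .errors import SpliceQuantError, ValidationError
from .events import detect_events, genes_with_active_events, summarize_single_sample
from .protein import DEFAULT_MIN_RATIO, predict_proteins
from .quant import QuantTable, compute_opkm
from .splice_graph import (
    SpliceGraph,
    build_splice_graph,
    graph_db_checksum,
    graph_sequence,
)
from .tiling_align import (
    DEFAULT_KMER,
    DEFAULT_MAX_MISMATCH,
    DEFAULT_MAX_PATHS,
    DEFAULT_MIN_OVERHANG,
    ObservationCounts,
    Tile,
    TileIndex,
    align_reads,
    count_observations,
    generate_tiles,
)


@dataclass
class RunConfig:
    """Run parameters; defaults follow the package's documented conventions."""

    read_len: int = 75
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    min_overhang: int = DEFAULT_MIN_OVERHANG
    min_junction_reads: int = 2
    min_exon_reads: int = 1
    tile_len: Optional[int] = None  # default 2R - 1
    tile_step: Optional[int] = None  # default R - (2*min_overhang - 1)
    kmer: int = DEFAULT_KMER
    max_paths: int = DEFAULT_MAX_PATHS
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    si_min: float = DEFAULT_SI_MIN
    q_max: float = DEFAULT_Q_MAX
    min_ratio: float = DEFAULT_MIN_RATIO
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "read_len", "max_mismatch", "min_overhang", "min_junction_reads",
            "min_exon_reads", "kmer", "pseudocount", "si_min", "q_max",
            "min_ratio",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"config: {name} must be >= 0")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _metadata(config: RunConfig, db_checksum: str, inputs: Mapping[str, str]) -> dict:
    md = {"splicequant_version": __version__, "graph_db_checksum": db_checksum}
    md.update({f"input_{k}": v for k, v in inputs.items()})
    md["config"] = json.dumps(config.to_dict(), sort_keys=True)
    return md


# -- stage helpers ---------------------------------------------------------

def build_graph_db(
    transcripts: Sequence[TranscriptModel], genome
) -> tuple[dict[str, SpliceGraph], dict[str, dict[str, str]]]:
    """One splice graph (plus node sequences) per gene."""
    graphs = {}
    node_seqs = {}
    for gid, txs in sorted(group_by_gene(transcripts).items()):
        g = build_splice_graph(txs)
        graphs[gid] = g
        node_seqs[gid] = graph_sequence(g, genome)
    return graphs, node_seqs


def build_tile_index(
    graphs: Mapping[str, SpliceGraph],
    node_seqs: Mapping[str, Mapping[str, str]],
    config: RunConfig,
    warn=None,
) -> tuple[list[Tile], TileIndex]:
    tiles: list[Tile] = []
    for gid in sorted(graphs):
        tiles.extend(
            generate_tiles(
                graphs[gid],
                node_seqs[gid],
                read_len=config.read_len,
                tile_len=config.tile_len,
                step=config.tile_step,
                min_overhang=config.min_overhang,
                max_paths=config.max_paths,
                warn=warn,
            )
        )
    return tiles, TileIndex(tiles, k=config.kmer)


def align_sample(fastq_path, index: TileIndex, config: RunConfig) -> ObservationCounts:
    return count_observations(
        align_reads(
            read_reads(fastq_path),
            index,
            max_mismatch=config.max_mismatch,
            min_overhang=config.min_overhang,
        )
    )


def quantify(
    counts: ObservationCounts,
    graphs: Mapping[str, SpliceGraph],
    config: RunConfig,
) -> QuantTable:
    return compute_opkm(counts, graphs, config.read_len, config.min_overhang)


# -- full pipelines --------------------------------------------------------

def run_single(
    gtf_path,
    fasta_path,
    fastq_path,
    out_dir,
    config: Optional[RunConfig] = None,
    features_path=None,
) -> dict:
    """Single-sample pipeline; writes report files and returns a summary."""
    import pyfaidx

    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in (gtf_path, fasta_path, fastq_path):
        if not Path(p).exists():
            raise ValidationError(f"input not found: {p}")

    transcripts = read_gtf(gtf_path)
    genome = pyfaidx.Fasta(str(fasta_path))
    graphs, node_seqs = build_graph_db(transcripts, genome)
    db_sum = graph_db_checksum(graphs)
    md_inputs = {
        "gtf": file_checksum(gtf_path),
        "fasta": file_checksum(fasta_path),
        "fastq": file_checksum(fastq_path),
    }

    tiles, index = build_tile_index(graphs, node_seqs, config)
    counts = align_sample(fastq_path, index, config)
    quant = quantify(counts, graphs, config)

    events_by_gene = {gid: detect_events(g) for gid, g in graphs.items()}

    features: list[ProteinFeature] = []
    if features_path:
        features, flagged = validate_features(
            read_feature_table(features_path), transcripts
        )

    tx_by_gene = group_by_gene(transcripts)
    protein_rows = []
    fasta_records = []
    gene_feature_impacts: dict[str, str] = {}
    for gid in sorted(graphs):
        forms, pruned, _flags = predict_proteins(
            graphs[gid], quant, node_seqs[gid], tx_by_gene[gid], features,
            min_ratio=config.min_ratio,
        )
        lost_any = sorted({f for form in forms for f in form.features_lost})
        if lost_any:
            gene_feature_impacts[gid] = ",".join(lost_any)
        for fi, form in enumerate(forms, start=1):
            protein_rows.append(
                {
                    "gene_id": gid,
                    "form": f"{gid}.p{fi}",
                    "path": "|".join(form.path),
                    "ratio": form.ratio,
                    "protein_length": len(form.protein),
                    "flags": ",".join(form.flags),
                    "features_present": ",".join(form.features_present),
                    "features_lost": ",".join(form.features_lost),
                    "pruned_mass": pruned,
                }
            )
            if form.protein:
                fasta_records.append((f"{gid}.p{fi} ratio={form.ratio:.4f}", form.protein))

    summary = summarize_single_sample(
        graphs,
        events_by_gene,
        quant,
        counts,
        min_junction_reads=config.min_junction_reads,
        min_overhang=config.min_overhang,
        min_exon_reads=config.min_exon_reads,
        feature_impacts=gene_feature_impacts,
    )
    md = _metadata(config, db_sum, md_inputs)

    write_table(quant.to_frame(), out / "quant.tsv", md)
    write_table(summary, out / "events.tsv", md)
    write_table(pd.DataFrame(protein_rows), out / "proteins.tsv", md)
    with open(out / "proteins.fasta", "w") as fh:
        for header, seq in fasta_records:
            fh.write(f">{header}\n{seq}\n")

    active_genes = genes_with_active_events(summary)
    gene_rows = []
    for gid in sorted(graphs):
        sub = summary[summary["gene_id"] == gid]
        gene_rows.append(
            {
                "gene_id": gid,
                "gene_opkm": quant.gene_opkm[gid],
                "aligned_reads": counts.gene_totals.get(gid, 0),
                "n_events": len(sub),
                "n_active_events": int(sub["active"].sum()) if len(sub) else 0,
                "multi_splice_form": gid in active_genes,
                "impacted_features": gene_feature_impacts.get(gid, ""),
            }
        )
    write_table(pd.DataFrame(gene_rows), out / "genes.tsv", md)

    return {
        "n_aligned": counts.n_aligned,
        "n_ambiguous": counts.n_ambiguous,
        "n_unaligned": counts.n_unaligned,
        "n_genes": len(graphs),
        "n_tiles": len(tiles),
        "active_genes": active_genes,
        "graph_db_checksum": db_sum,
        "out_dir": str(out),
    }


def run_compare(
    gtf_path,
    fasta_path,
    fastq_a,
    fastq_b,
    out_dir,
    config: Optional[RunConfig] = None,
) -> dict:
    """Two-sample comparison pipeline."""
    import pyfaidx

    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in (gtf_path, fasta_path, fastq_a, fastq_b):
        if not Path(p).exists():
            raise ValidationError(f"input not found: {p}")

    transcripts = read_gtf(gtf_path)
    genome = pyfaidx.Fasta(str(fasta_path))
    graphs, node_seqs = build_graph_db(transcripts, genome)
    db_sum = graph_db_checksum(graphs)
    tiles, index = build_tile_index(graphs, node_seqs, config)

    counts_a = align_sample(fastq_a, index, config)
    counts_b = align_sample(fastq_b, index, config)
    quant_a = quantify(counts_a, graphs, config)
    quant_b = quantify(counts_b, graphs, config)
    events_by_gene = {gid: detect_events(g) for gid, g in graphs.items()}

    comparison = compare_samples(
        quant_a,
        quant_b,
        counts_a,
        counts_b,
        graphs,
        events_by_gene,
        pseudocount=config.pseudocount,
        si_min=config.si_min,
        q_max=config.q_max,
        min_junction_reads=config.min_junction_reads,
        min_overhang=config.min_overhang,
        min_exon_reads=config.min_exon_reads,
    )
    md = _metadata(
        config,
        db_sum,
        {
            "gtf": file_checksum(gtf_path),
            "fasta": file_checksum(fasta_path),
            "fastq_a": file_checksum(fastq_a),
            "fastq_b": file_checksum(fastq_b),
        },
    )
    write_table(comparison, out / "comparison.tsv", md)
    flagged = (
        sorted(comparison.loc[comparison["gene_flagged"], "gene_id"].unique())
        if len(comparison)
        else []
    )
    return {
        "n_aligned_a": counts_a.n_aligned,
        "n_aligned_b": counts_b.n_aligned,
        "flagged_genes": flagged,
        "graph_db_checksum": db_sum,
        "out_dir": str(out),
    }


def run_benchmark(spec=None, base_seed: Optional[int] = None, work_dir=None) -> dict:
    """The simulate -> align -> quant -> traverse -> score chain for one seed.

    Writes FASTA/GTF/FASTQ to a working directory (a temporary one by
    default), re-reads them through the standard readers, and scores
    isoform-concentration recovery against the simulated truth.
    """
    import tempfile

    import numpy as np
    import pyfaidx

    from .annotation_io import write_gtf
    from .protein import weighted_traversal
    from .simulate import (
        DEFAULT_BENCHMARK,
        evaluate_recovery,
        simulate_genome,
        simulate_reads,
        truth_frame,
        write_fasta,
        write_fastq,
    )
    from .simulate import SimSpec  # noqa: F401 (re-export convenience)

    spec = spec or DEFAULT_BENCHMARK
    if base_seed is not None:
        spec = dataclasses.replace(spec, seed=base_seed)
    config = RunConfig(read_len=spec.read_len, seed=spec.seed)

    def _run(tmp: Path) -> dict:
        rng = np.random.default_rng(spec.seed)
        loci = simulate_genome(spec, rng)
        fasta = tmp / "genome.fa"
        gtf = tmp / "models.gtf"
        fastq = tmp / "reads.fastq"
        write_fasta(loci, fasta)
        all_tx = [t for locus in loci for t in locus.transcripts]
        write_gtf(all_tx, gtf)
        write_fastq(simulate_reads(loci, spec, rng), fastq)

        transcripts = read_gtf(gtf)
        genome = pyfaidx.Fasta(str(fasta))
        graphs, node_seqs = build_graph_db(transcripts, genome)
        tiles, index = build_tile_index(graphs, node_seqs, config)
        counts = align_sample(fastq, index, config)
        quant = quantify(counts, graphs, config)

        predictions = {}
        for gid, g in graphs.items():
            paths, pruned, _ = weighted_traversal(g, quant, config.min_ratio)
            predictions[gid] = (paths, pruned)
        per_gene, mean_err = evaluate_recovery(graphs, loci, predictions)
        return {
            "seed": spec.seed,
            "mean_abs_error_pp": mean_err,
            "per_gene": per_gene,
            "truth": truth_frame(loci),
            "n_aligned": counts.n_aligned,
            "n_ambiguous": counts.n_ambiguous,
            "n_unaligned": counts.n_unaligned,
            "n_reads": spec.n_reads,
        }

    if work_dir is not None:
        wd = Path(work_dir)
        wd.mkdir(parents=True, exist_ok=True)
        return _run(wd)
    with tempfile.TemporaryDirectory() as td:
        return _run(Path(td))
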
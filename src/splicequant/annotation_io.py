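"""Input/output for gene models, sequences, reads and protein features.

All genomic coordinates are held internally as 0-based half-open
intervals on a named chromosome; the GTF reader/writer converts to and
from the format's 1-based inclusive convention at the boundary, so the
rest of the package never deals with off-by-one arithmetic.

Exon lists of a :class:`TranscriptModel` are kept in *transcription*
order: ascending genomic coordinates on the ``+`` strand, descending on
``-``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gffutils.feature
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ParseError, ValidationError

STRANDS = ("+", "-")

_READ_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One annotated transcript: exons (and optionally CDS) in transcription order."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: Optional[list[GenomicInterval]] = None

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def validate(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has zero exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id} spans multiple chromosomes/strands"
            )
        by_pos = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_pos, by_pos[1:]):
            if a.end > b.start:
                raise ValidationError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        if self.cds is not None:
            exonic = set()
            for e in self.exons:
                exonic.update(range(e.start, e.end))
            for c in self.cds:
                if not set(range(c.start, c.end)) <= exonic:
                    raise ValidationError(
                        f"transcript {self.transcript_id}: CDS interval "
                        f"{c.start}-{c.end} not contained in exons"
                    )


@dataclass(frozen=True)
class ProteinFeature:
    """A functional annotation on a protein, e.g. a UniProt DOMAIN or SITE.

    Amino-acid coordinates are 1-based inclusive and refer to the protein
    encoded by ``mapping_transcript_id``.
    """

    feature_id: str
    accession: str
    aa_start: int
    aa_end: int
    ftype: str
    description: str
    mapping_transcript_id: str

    def __post_init__(self) -> None:
        if self.aa_start < 1:
            raise ValidationError(
                f"feature {self.feature_id}: aa_start must be >= 1 (1-based)"
            )
        if self.aa_end < self.aa_start:
            raise ValidationError(
                f"feature {self.feature_id}: aa_end < aa_start"
            )


def _transcription_sort(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    rev = exons[0].strand == "-"
    return sorted(exons, key=lambda e: e.start, reverse=rev)


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF file into :class:`TranscriptModel` objects.

    Only ``exon`` and ``CDS`` features are consumed; both must carry
    ``gene_id`` and ``transcript_id`` attributes (Ensembl dialect).
    Coordinates are converted from 1-based inclusive to 0-based half-open
    and exons sorted into transcription order.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise ParseError(f"{path}:{lineno}: malformed GTF line: {exc}") from exc
            if feat.featuretype not in ("exon", "CDS"):
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                tx_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise ParseError(
                    f"{path}:{lineno}: missing {exc} attribute"
                ) from exc
            if feat.end < feat.start:
                raise ParseError(f"{path}:{lineno}: end < start")
            if feat.strand not in STRANDS:
                raise ParseError(f"{path}:{lineno}: strand must be + or -")
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            if tx_id not in genes:
                genes[tx_id] = gene_id
                order.append(tx_id)
            elif genes[tx_id] != gene_id:
                raise ParseError(
                    f"{path}:{lineno}: transcript {tx_id} assigned to two genes"
                )
            (exons if feat.featuretype == "exon" else cds).setdefault(tx_id, []).append(iv)

    models = []
    for tx_id in order:
        if tx_id not in exons:
            raise ValidationError(f"transcript {tx_id} has zero exons")
        model = TranscriptModel(
            transcript_id=tx_id,
            gene_id=genes[tx_id],
            exons=_transcription_sort(exons[tx_id]),
            cds=_transcription_sort(cds[tx_id]) if tx_id in cds else None,
        )
        model.validate()
        models.append(model)
    models.sort(key=lambda m: (m.gene_id, m.transcript_id))
    return models


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF (inverse of :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for tx in sorted(transcripts, key=lambda t: (t.gene_id, t.transcript_id)):
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            records = [("exon", e) for e in tx.exons]
            if tx.cds:
                records += [("CDS", c) for c in tx.cds]
            for ftype, iv in records:
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            "splicequant",
                            ftype,
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def group_by_gene(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    out: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        out.setdefault(tx.gene_id, []).append(tx)
    return out


def read_reads(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream FASTQ records as ``(read_id, sequence, quality)`` tuples.

    Sequences are uppercased; any symbol outside ACGTN is rejected.  N is
    a legal symbol but never matches any base during alignment.
    """
    path = Path(path)
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        idx = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(
                    f"{path}: truncated/malformed FASTQ record #{idx + 1}: {exc}"
                ) from exc
            seq = seq.upper()
            if not _READ_RE.match(seq):
                raise ParseError(
                    f"{path}: record #{idx + 1} ({title.split()[0]}): "
                    "sequence contains symbols outside ACGTN"
                )
            yield title.split()[0], seq, qual
            idx += 1


FEATURE_COLUMNS = [
    "feature_id",
    "accession",
    "aa_start",
    "aa_end",
    "ftype",
    "description",
    "mapping_transcript_id",
]


def read_feature_table(path: str | Path) -> list[ProteinFeature]:
    """Read the protein functional-feature TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    feats = []
    for i, row in df.iterrows():
        try:
            feats.append(
                ProteinFeature(
                    feature_id=row["feature_id"],
                    accession=row["accession"],
                    aa_start=int(row["aa_start"]),
                    aa_end=int(row["aa_end"]),
                    ftype=row["ftype"],
                    description=row["description"],
                    mapping_transcript_id=row["mapping_transcript_id"],
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
    return feats


def validate_features(
    features: Sequence[ProteinFeature],
    transcripts: Sequence[TranscriptModel],
) -> tuple[list[ProteinFeature], list[ProteinFeature]]:
    """Split features into (resolvable, flagged).

    A feature is resolvable when its mapping transcript exists and has an
    annotated CDS; everything else is flagged rather than dropped silently.
    """
    with_cds = {t.transcript_id for t in transcripts if t.cds}
    ok = [f for f in features if f.mapping_transcript_id in with_cds]
    flagged = [f for f in features if f.mapping_transcript_id not in with_cds]
    return ok, flagged


def write_table(
    df: pd.DataFrame, path: str | Path, metadata: Optional[dict] = None
) -> None:
    """Write a TSV with ``#``-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
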
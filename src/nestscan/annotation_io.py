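"""Genome annotation and sequence I/O.

Gene models are represented with explicit coding-exon (CDS) structure so
that coding introns — the intervals between consecutive protein-coding
exons of a transcript — can be enumerated and numbered in translation
order.  Coding-intron numbering is the coordinate system used throughout
the package to describe nested gene structures (e.g. "the intron between
coding exons 6 and 7" of an alpha-catenin gene).

Conventions
-----------
* Internal coordinates are 0-based, half-open ``[start, end)``.
* GFF3 on disk uses the standard 1-based inclusive convention; the
  conversion happens only at the I/O boundary.
* A gene's *canonical transcript* is the transcript with the longest
  total CDS length; ties are broken by lexicographically smallest
  transcript id.
* "Coding exon" means a CDS segment; UTR-only exons do not participate
  in coding-intron numbering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]

_DNA_CHARS = set("ACGTRYSWKMBDHVN")
_RNA_CHARS = set("ACGURYSWKMBDHVN")
_PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZUO*")


class AnnotationError(ValueError):
    """Malformed annotation input (bad GFF3 structure, dangling parents...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over a declared alphabet (DNA, RNA or protein)."""

    id: str
    sequence: str
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.alphabet not in ("DNA", "RNA", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = {"DNA": _DNA_CHARS, "RNA": _RNA_CHARS, "protein": _PROTEIN_CHARS}[
            self.alphabet
        ]
        bad = set(self.sequence.upper()) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} not valid for "
                f"{self.alphabet}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptModel:
    """One transcript: ordered exons plus the CDS segments they carry."""

    transcript_id: str
    exons: list[Interval] = field(default_factory=list)
    cds_segments: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds_segments = sorted(tuple(c) for c in self.cds_segments)
        for name, ivs in (("exons", self.exons), ("cds_segments", self.cds_segments)):
            for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
                if b0 < a1:
                    raise AnnotationError(
                        f"{self.transcript_id}: overlapping {name} "
                        f"({a0},{a1}) vs ({b0},{b1})"
                    )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def span(self) -> Interval:
        ivs = self.exons or self.cds_segments
        return (min(s for s, _ in ivs), max(e for _, e in ivs))


@dataclass
class GeneModel:
    """A gene with its transcripts, strand and genomic span."""

    gene_id: str
    scaffold: str
    strand: str
    span: Interval
    transcripts: list[TranscriptModel] = field(default_factory=list)
    symbol: str = ""
    family_tags: set[str] = field(default_factory=set)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        for tx in self.transcripts:
            s, e = tx.span
            if s < self.span[0] or e > self.span[1]:
                raise AnnotationError(
                    f"{self.gene_id}: transcript {tx.transcript_id} outside gene span"
                )

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    def canonical_transcript(self) -> TranscriptModel:
        if not self.transcripts:
            raise AnnotationError(f"{self.gene_id}: no transcripts")
        return min(self.transcripts, key=lambda t: (-t.cds_length, t.transcript_id))


@dataclass
class GenomeAnnotation:
    """All gene models of one species, with optional scaffold sequences."""

    species: str
    genes: list[GeneModel] = field(default_factory=list)
    sequences: dict[str, SequenceRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def __iter__(self):
        return iter(self.genes)


@dataclass(frozen=True)
class CodingIntron:
    """A coding intron, numbered 1..n-1 in translation order."""

    index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_CODING_BIOTYPES = {"protein_coding"}


def read_gff3(source: str | IO[str], species: str = "") -> GenomeAnnotation:
    """Parse a GFF3 stream/path/string into a :class:`GenomeAnnotation`.

    Expects gene / mRNA / exon / CDS features linked by ``Parent``
    attributes.  1-based inclusive coordinates are converted to 0-based
    half-open.  Genes whose ``biotype`` is not ``protein_coding`` are
    retained with ``biotype="other"``.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    feature_lines = [
        l for l in text.splitlines() if l.strip() and not l.startswith("#")
    ]
    if not feature_lines:
        return GenomeAnnotation(species=species, genes=[])
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises a zoo of exception types
        raise AnnotationError(f"GFF3 parse error: {exc}") from exc

    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        biotype = gf.attributes.get("biotype", ["protein_coding"])[0]
        if biotype not in _CODING_BIOTYPES:
            biotype = "other"
        transcripts = []
        for tf in db.children(gf, featuretype=("mRNA", "transcript")):
            exons = [
                (c.start - 1, c.end) for c in db.children(tf, featuretype="exon")
            ]
            cds = [(c.start - 1, c.end) for c in db.children(tf, featuretype="CDS")]
            transcripts.append(
                TranscriptModel(
                    transcript_id=tf.id, exons=exons, cds_segments=cds
                )
            )
        transcripts.sort(key=lambda t: t.transcript_id)
        genes.append(
            GeneModel(
                gene_id=gf.id,
                scaffold=gf.seqid,
                strand=gf.strand,
                span=(gf.start - 1, gf.end),
                transcripts=transcripts,
                symbol=gf.attributes.get("Name", [gf.id])[0],
                family_tags=set(gf.attributes.get("family_tags", [])),
                biotype=biotype,
            )
        )
    # orphan CDS features are a structural error
    for cf in db.features_of_type("CDS"):
        if not cf.attributes.get("Parent"):
            raise AnnotationError(f"CDS feature {cf.id!r} has no Parent")
    genes.sort(key=lambda g: (g.scaffold, g.span[0], g.gene_id))
    return GenomeAnnotation(species=species, genes=genes)


def write_gff3(annotation: GenomeAnnotation, stream: IO[str] | None = None) -> str:
    """Serialize an annotation to GFF3 with deterministic feature ordering.

    Genes are sorted by (scaffold, start, gene id); each gene is followed
    by its transcripts (sorted by id) and their exon/CDS features sorted
    by start.  Coordinates are re-converted to 1-based inclusive.
    """
    out = stream if stream is not None else io.StringIO()
    out.write("##gff-version 3\n")
    for g in sorted(annotation.genes, key=lambda g: (g.scaffold, g.span[0], g.gene_id)):
        attrs = [f"ID={g.gene_id}", f"Name={g.symbol or g.gene_id}", f"biotype={g.biotype}"]
        if g.family_tags:
            attrs.append("family_tags=" + ",".join(sorted(g.family_tags)))
        _gff_line(out, g.scaffold, "gene", g.span, g.strand, ";".join(attrs))
        for tx in sorted(g.transcripts, key=lambda t: t.transcript_id):
            _gff_line(
                out, g.scaffold, "mRNA", tx.span, g.strand,
                f"ID={tx.transcript_id};Parent={g.gene_id}",
            )
            for s, e in tx.exons:
                _gff_line(
                    out, g.scaffold, "exon", (s, e), g.strand,
                    f"Parent={tx.transcript_id}",
                )
            for s, e in tx.cds_segments:
                _gff_line(
                    out, g.scaffold, "CDS", (s, e), g.strand,
                    f"Parent={tx.transcript_id}",
                )
    return out.getvalue() if stream is None else ""


def _gff_line(out, seqid, ftype, span, strand, attrs) -> None:
    start, end = span
    phase = "0" if ftype == "CDS" else "."
    out.write(
        f"{seqid}\t.\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t{phase}\t{attrs}\n"
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source: str | IO[str], alphabet: str = "DNA") -> list[SequenceRecord]:
    """Read FASTA records; ids must be unique, sequences are upper-cased."""
    handle = io.StringIO(source) if isinstance(source, str) and source.lstrip().startswith(">") else source
    close = False
    if isinstance(handle, str):
        handle = open(handle)
        close = True
    try:
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            records.append(
                SequenceRecord(id=rec.id, sequence=str(rec.seq).upper(), alphabet=alphabet)
            )
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[SequenceRecord], stream: IO[str] | None = None,
                wrap: int = 80) -> str:
    """Write FASTA with fixed-width line wrapping (default 80 columns)."""
    out = stream if stream is not None else io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(out, wrap=wrap)
    writer.write_file(
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    )
    return out.getvalue() if stream is None else ""


# ---------------------------------------------------------------------------
# Coding-intron arithmetic
# ---------------------------------------------------------------------------

def coding_introns(gene: GeneModel) -> list[CodingIntron]:
    """Coding introns of the canonical transcript, in translation order.

    Intron *k* separates coding exons *k* and *k+1* counted from the
    translation start, so on the minus strand the genomic order of
    introns is reversed relative to their indices.  A single-CDS gene
    has no coding introns.
    """
    tx = gene.canonical_transcript()
    cds = tx.cds_segments
    if gene.biotype == "protein_coding" and not cds:
        raise AnnotationError(f"{gene.gene_id}: protein_coding gene without CDS")
    gaps = [
        (a_end, b_start)
        for (_, a_end), (b_start, _) in zip(cds, cds[1:])
    ]
    if gene.strand == "-":
        gaps = gaps[::-1]
    return [CodingIntron(index=i + 1, start=s, end=e) for i, (s, e) in enumerate(gaps)]


def longest_intron(gene: GeneModel) -> CodingIntron:
    """The widest coding intron; ties broken by smallest intron index."""
    introns = coding_introns(gene)
    if not introns:
        raise AnnotationError(
            f"{gene.gene_id}: fewer than 2 coding exons, no coding introns"
        )
    return max(introns, key=lambda iv: (iv.length, -iv.index))
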
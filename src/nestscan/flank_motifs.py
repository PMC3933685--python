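"""Intronic splicing-regulator motif scanning around an exon.

KHDBRS-family RNA binding proteins (T-STAR / SAM68) regulate skipping
of the neurexin AS4 exon by binding AU-rich UWAA repeats (W = U or A,
i.e. UAAA / UUAA) in the introns immediately flanking the exon.  This
module extracts fixed-length flanks around a designated exon of a
transcript (in transcription orientation, so minus-strand genes are
reverse-complemented) and counts motif occurrences on the sense
(pre-mRNA) strand.

By default occurrences are counted overlapping (a run like UUAAA yields
hits at two offsets); a non-overlapping greedy mode is provided since
a plain text search for "repeats" could be read either way.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .annotation_io import GeneModel, SequenceRecord, TranscriptModel

_IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "T", "T": "T",
    "W": "[AT]", "R": "[AG]", "Y": "[CT]", "S": "[CG]", "K": "[GT]",
    "M": "[AC]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif such as UWAA over the RNA/DNA alphabet."""

    pattern: str
    alphabet: str = "RNA"

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError("pattern length must be >= 2")
        bad = set(self.pattern.upper()) - set(_IUPAC_RNA)
        if bad:
            raise ValueError(f"invalid pattern characters: {sorted(bad)}")

    def regex(self) -> re.Pattern:
        return re.compile("".join(_IUPAC_RNA[c] for c in self.pattern.upper()))


@dataclass(frozen=True)
class MotifHitSet:
    """All hit offsets of a motif within one region."""

    region_id: str
    offsets: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.offsets)


@dataclass(frozen=True)
class Flank:
    """One extracted flank with truncation bookkeeping."""

    sequence: str
    requested: int
    truncated: bool

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotides {sorted(bad)}")
    return s


def count_motif(
    sequence: str,
    pattern: str | MotifPattern = "UWAA",
    overlapping: bool = True,
    region_id: str = "",
) -> MotifHitSet:
    """Count motif occurrences (0-based offsets) in a nucleotide sequence.

    T and U are equivalent; matching is case-insensitive.  With
    ``overlapping=True`` (default) every start offset is reported; with
    ``False`` a greedy left-to-right non-overlapping scan is used.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    seq = _normalize(sequence)
    rx = pattern.regex()
    offsets: list[int] = []
    pos = 0
    while True:
        m = rx.search(seq, pos)
        if m is None:
            break
        offsets.append(m.start())
        pos = m.start() + 1 if overlapping else m.end()
    return MotifHitSet(region_id=region_id, offsets=tuple(offsets))


def exon_flanks(
    transcript: TranscriptModel,
    exon_index: int,
    up_len: int = 200,
    down_len: int = 200,
    genome: SequenceRecord | str | None = None,
    strand: str = "+",
) -> tuple[Flank, Flank]:
    """Extract up/downstream flanks of an exon in transcription orientation.

    ``exon_index`` is 1-based in transcription order (strand-aware).
    Flanks are clipped at the neighbouring exon (i.e. to the length of
    the flanking intron) and flagged as truncated; an exon at the
    transcript end has an empty, truncated flank on that side.
    """
    if genome is None:
        raise ValueError("genome sequence required")
    seq = genome.sequence if isinstance(genome, SequenceRecord) else genome
    exons = list(transcript.exons)
    if strand == "-":
        exons = exons[::-1]
    if not (1 <= exon_index <= len(exons)):
        raise IndexError(f"exon index {exon_index} out of range")
    exon = exons[exon_index - 1]

    def intron_between(a, b):  # genomic gap between two exons
        lo = min(a[1], b[1])
        hi = max(a[0], b[0])
        return (lo, hi)

    # upstream = before the exon in transcription order
    up_seq, up_trunc = "", True
    if exon_index > 1:
        gap = intron_between(exons[exon_index - 2], exon)
        ilen = gap[1] - gap[0]
        take = min(up_len, ilen)
        up_trunc = take < up_len
        if strand == "+":
            up_seq = seq[exon[0] - take: exon[0]]
        else:
            up_seq = str(Seq(seq[exon[1]: exon[1] + take]).reverse_complement())
    down_seq, down_trunc = "", True
    if exon_index < len(exons):
        gap = intron_between(exon, exons[exon_index])
        ilen = gap[1] - gap[0]
        take = min(down_len, ilen)
        down_trunc = take < down_len
        if strand == "+":
            down_seq = seq[exon[1]: exon[1] + take]
        else:
            down_seq = str(Seq(seq[exon[0] - take: exon[0]]).reverse_complement())
    return (
        Flank(up_seq, up_len, up_trunc),
        Flank(down_seq, down_len, down_trunc),
    )


def as_rna(seq: str) -> str:
    """Report a genomic (DNA) sequence in RNA context (T -> U)."""
    return _normalize(seq).replace("T", "U")
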
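"""EST-based classification of alternative-exon skipping.

The neurexin AS4 exon encodes a loop segment whose removal (by exon
skipping) is required for LRRTM binding.  Expression evidence for the
skipped isoform can be read off EST alignments against a reference
protein fragment spanning AS4 and its flanking exons: an EST whose
alignment bridges both flanks while the AS4 segment itself is deleted
supports *skipping*; an EST aligning across the AS4 segment supports
*retention*.

The workflow mirrors a protein-space database search re-implemented as
local pairwise alignment (BLOSUM62, affine gaps, gap open -11 /
extend -1).  Hits are filtered before calling: aligned length >= 80 aa,
identity > 30%, and overlap with the AS4 segment or its immediate
junction — this removes short fragments and distant non-neurexin
sequences.

Calling thresholds (``min_flank`` aligned residues required on each
side for a skip call; ``min_cover`` fraction of AS4 for a retain call)
are exposed because the underlying notion of "lacks the exon" admits
partial-coverage edge cases; defaults are 10 aa and 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

GAP_OPEN = -11.0
GAP_EXTEND = -1.0
MIN_ALIGNED_LEN = 80
MIN_IDENTITY = 0.30
DEFAULT_MIN_FLANK = 10
DEFAULT_MIN_COVER = 0.5

_PROTEIN = set("ACDEFGHIKLMNPQRSTVWYX*")
_DNA = set("ACGTN")


@dataclass(frozen=True)
class SpliceReference:
    """Reference protein fragment with the alternatively spliced segment.

    ``as4`` is a half-open interval on the reference, strictly inside it.
    """

    sequence: str
    as4: tuple[int, int]

    def __post_init__(self) -> None:
        s, e = self.as4
        if not (0 < s < e < len(self.sequence)):
            raise ValueError("AS4 segment must lie strictly inside the reference")

    @property
    def as4_length(self) -> int:
        return self.as4[1] - self.as4[0]


@dataclass(frozen=True)
class ESTHit:
    """Best local alignment of one EST against the reference."""

    est_id: str
    ref_interval: tuple[int, int]
    est_interval: tuple[int, int]
    aligned_length: int  # residue-residue columns
    identity: float
    score: float
    ref_blocks: tuple[tuple[int, int], ...]  # aligned reference segments
    frame: int = 0  # 0 for protein input; 1..3 for translated frames


@dataclass(frozen=True)
class SpliceCall:
    est_id: str
    verdict: str  # skip | retain | indeterminate
    reason: str


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _best_alignment(aligner, ref: str, query: str):
    alns = aligner.align(ref, query)
    if len(alns) == 0:
        return None
    # deterministic tie-break: all enumerated alignments share the best
    # score; pick the smallest reference start among the first few paths
    best = None
    for k, aln in enumerate(alns):
        if best is None or aln.aligned[0][0][0] < best.aligned[0][0][0]:
            best = aln
        if k >= 15:
            break
    return best


def align_est(est_seq: str, reference: SpliceReference, est_id: str = "",
              frames: int = 3) -> ESTHit:
    """Best local alignment of an EST (protein or nucleotide) to the reference.

    Nucleotide ESTs are translated in ``frames`` sense frames (3 by
    default, assuming sense-oriented ESTs; pass 6 to also try the
    reverse complement) and the best-scoring frame is kept.
    """
    est_seq = est_seq.strip().upper()
    if not est_seq:
        raise ValueError("empty EST sequence")
    aligner = _make_aligner()
    ref = reference.sequence

    # heuristic: a sequence over {A,C,G,T,N} only is treated as nucleotide
    queries: list[tuple[int, str]]
    if set(est_seq) <= _DNA:
        queries = []
        def tr(s: str) -> str:  # trim to whole codons before translating
            return str(Seq(s[: len(s) - len(s) % 3]).translate(to_stop=False))

        for f in range(min(frames, 3)):
            queries.append((f + 1, tr(est_seq[f:])))
        if frames >= 6:
            rc = str(Seq(est_seq).reverse_complement())
            for f in range(3):
                queries.append((-(f + 1), tr(rc[f:])))
        queries = [(f, q.replace("*", "X")) for f, q in queries if q]
    else:
        queries = [(0, est_seq)]

    best: tuple[float, int, object, str] | None = None
    for frame, q in queries:
        aln = _best_alignment(aligner, ref, q)
        if aln is None:
            continue
        if best is None or aln.score > best[0]:
            best = (aln.score, frame, aln, q)
    if best is None:
        raise ValueError(f"no alignment found for EST {est_id!r}")
    score, frame, aln, query = best

    ref_blocks = tuple((int(s), int(e)) for s, e in aln.aligned[0])
    est_blocks = tuple((int(s), int(e)) for s, e in aln.aligned[1])
    matches = 0
    cols = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, est_blocks):
        cols += re_ - rs
        matches += sum(ref[rs + i] == query[qs + i] for i in range(re_ - rs))
    return ESTHit(
        est_id=est_id,
        ref_interval=(ref_blocks[0][0], ref_blocks[-1][1]),
        est_interval=(est_blocks[0][0], est_blocks[-1][1]),
        aligned_length=cols,
        identity=matches / cols if cols else 0.0,
        score=float(score),
        ref_blocks=ref_blocks,
        frame=frame,
    )


def filter_hits(
    hits: Iterable[ESTHit],
    reference: SpliceReference,
    min_len: int = MIN_ALIGNED_LEN,
    min_identity: float = MIN_IDENTITY,
) -> tuple[list[ESTHit], list[tuple[ESTHit, str]]]:
    """Apply the relevance filters; returns (kept, [(dropped, reason)]).

    Keep iff aligned length >= 80 aa AND identity > 30% AND the aligned
    reference interval overlaps the AS4 segment or abuts its junction.
    """
    a_s, a_e = reference.as4
    kept: list[ESTHit] = []
    dropped: list[tuple[ESTHit, str]] = []
    for h in hits:
        if h.aligned_length < min_len:
            dropped.append((h, f"aligned length {h.aligned_length} < {min_len} aa"))
            continue
        if h.identity <= min_identity:
            dropped.append((h, f"identity {h.identity:.2f} <= {min_identity:.2f}"))
            continue
        r_s, r_e = h.ref_interval
        overlaps = r_s < a_e and r_e > a_s
        abuts = r_e == a_s or r_s == a_e
        if not (overlaps or abuts):
            dropped.append((h, "no overlap with the AS4 segment or its junction"))
            continue
        kept.append(h)
    return kept, dropped


def _as4_aligned_count(hit: ESTHit, reference: SpliceReference) -> int:
    a_s, a_e = reference.as4
    return sum(
        max(0, min(e, a_e) - max(s, a_s)) for s, e in hit.ref_blocks
    )


def call_as4(
    hit: ESTHit,
    reference: SpliceReference,
    min_flank: int = DEFAULT_MIN_FLANK,
    min_cover: float = DEFAULT_MIN_COVER,
) -> SpliceCall:
    """Skip / retain / indeterminate verdict for one filtered hit.

    *skip*: >= ``min_flank`` aligned residues on both sides of AS4 and
    zero aligned residues inside it (the segment is deleted from the
    alignment).  *retain*: >= ``min_cover`` of the AS4 segment aligned.
    Anything else is indeterminate.
    """
    a_s, a_e = reference.as4
    in_as4 = _as4_aligned_count(hit, reference)
    left = sum(max(0, min(e, a_s) - s) for s, e in hit.ref_blocks)
    right = sum(max(0, e - max(s, a_e)) for s, e in hit.ref_blocks)
    if in_as4 == 0 and left >= min_flank and right >= min_flank:
        return SpliceCall(hit.est_id, "skip",
                          f"AS4 deleted; {left}/{right} aa flanks aligned")
    cover = in_as4 / reference.as4_length
    if cover >= min_cover:
        return SpliceCall(hit.est_id, "retain",
                          f"{cover:.0%} of AS4 segment aligned")
    return SpliceCall(hit.est_id, "indeterminate",
                      f"AS4 coverage {cover:.0%}, flanks {left}/{right} aa")


def skip_fraction(calls: Sequence[SpliceCall]) -> dict:
    """Skip fraction among informative (skip or retain) calls.

    Returns counts, the exact rational fraction and the percentage;
    ``fraction`` is None when there are no informative calls.
    """
    n_skip = sum(1 for c in calls if c.verdict == "skip")
    n_retain = sum(1 for c in calls if c.verdict == "retain")
    informative = n_skip + n_retain
    frac = Fraction(n_skip, informative) if informative else None
    return {
        "n_skip": n_skip,
        "n_retain": n_retain,
        "n_informative": informative,
        "n_indeterminate": len(calls) - informative,
        "fraction": frac,
        "percent": round(100 * float(frac)) if frac is not None else None,
    }
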
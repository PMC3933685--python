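"""Degenerate-primer diagnostics: degeneracy, site matching, in-silico
PCR and restriction digestion.

The motivating use case is a degenerate primer pair designed inside the
last (longest) coding exon of the vertebrate *ctnna3* gene:

* a3-F  5'-GGC TGC CAA RAA YYT NAT GAA YGC-3'
* a3-R  5'-GGC TTC TTT KCN GGN GCY TTC AT-3'

Each has degeneracy 64 (number of distinct concrete oligos in the
pool); the expected product on every known *ctnna* gene is 144 bp,
measured inclusively from the 5' end of the forward footprint to the
5' end of the reverse footprint on the opposite strand.  Diagnostic
digests (e.g. HindIII in a frog *ctnna1* product, StuI in *ctnna2*)
distinguish the co-amplified paralog fragments.

Matching semantics: an IUPAC code matches a template base iff the base
belongs to the code's set; if the template itself carries IUPAC codes,
a position matches iff the two base sets intersect.  The per-position
check equals the minimum mismatch count over the exhaustive primer
expansion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

# the published ctnna3 primer pair (spaces removed from the printed 5'->3' form)
A3_F = "GGCTGCCAARAAYYTNATGAAYGC"
A3_R = "GGCTTCTTTKCNGGNGCYTTCAT"

# built-in restriction enzyme table: recognition site and cut offset on
# the top strand (HindIII A^AGCTT -> offset 1; StuI AGG^CCT -> offset 3)
ENZYMES: dict[str, tuple[str, int]] = {
    "HindIII": ("AAGCTT", 1),
    "StuI": ("AGGCCT", 3),
    "EcoRI": ("GAATTC", 1),
    "BamHI": ("GGATCC", 1),
}


class PrimerError(ValueError):
    pass


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-encoded primer, written 5'->3'."""

    name: str
    iupac_sequence: str
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        seq = self.iupac_sequence.upper().replace(" ", "")
        object.__setattr__(self, "iupac_sequence", seq)
        if len(seq) < 10:
            raise PrimerError(f"{self.name}: primer shorter than 10 nt")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise PrimerError(f"{self.name}: invalid IUPAC codes {sorted(bad)}")
        if self.orientation not in ("forward", "reverse"):
            raise PrimerError(f"{self.name}: bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.iupac_sequence)


@dataclass(frozen=True)
class PrimerSite:
    """One annealing site on a template (+ strand coordinates)."""

    template_id: str
    start: int
    end: int
    strand: str  # strand the primer anneals to
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product."""

    template_id: str
    start: int  # 5' end of forward footprint on +
    end: int    # 5' end of reverse footprint on - (exclusive on +)
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


def degeneracy(primer: DegeneratePrimer | str) -> int:
    """Number of distinct concrete sequences in the primer pool
    (product over positions of IUPAC cardinality)."""
    seq = primer.iupac_sequence if isinstance(primer, DegeneratePrimer) else primer.upper().replace(" ", "")
    bad = set(seq) - set(IUPAC_SETS)
    if bad:
        raise PrimerError(f"invalid IUPAC codes {sorted(bad)}")
    return math.prod(len(IUPAC_SETS[c]) for c in seq)


def expand(primer: DegeneratePrimer | str, limit: int = 4096) -> list[str]:
    """Exhaustive, sorted, duplicate-free expansion of a degenerate primer."""
    seq = primer.iupac_sequence if isinstance(primer, DegeneratePrimer) else primer.upper().replace(" ", "")
    d = degeneracy(seq)
    if d > limit:
        raise PrimerError(f"degeneracy {d} exceeds expansion limit {limit}")
    return ["".join(t) for t in itertools.product(*(sorted(IUPAC_SETS[c]) for c in seq))]


def _mismatches(window: str, primer_seq: str) -> int:
    n = 0
    for t, p in zip(window, primer_seq):
        ts = IUPAC_SETS.get(t)
        if ts is None:
            raise PrimerError(f"invalid template base {t!r}")
        if not ts & IUPAC_SETS[p]:
            n += 1
    return n


def match_sites(
    template: str,
    primer: DegeneratePrimer,
    max_mismatch: int = 0,
    template_id: str = "",
) -> list[PrimerSite]:
    """All annealing sites with minimum mismatch count <= ``max_mismatch``.

    Forward primers are scanned along the + strand; reverse primers are
    scanned as their reverse complement along the + strand (they anneal
    to the - strand).  Site coordinates are always on the + strand.
    """
    template = template.upper()
    if len(template) < len(primer):
        return []
    if primer.orientation == "forward":
        probe, strand = primer.iupac_sequence, "+"
    else:
        probe, strand = str(Seq(primer.iupac_sequence).reverse_complement()), "-"
    L = len(probe)
    sites = []
    for i in range(len(template) - L + 1):
        mm = _mismatches(template[i: i + L], probe)
        if mm <= max_mismatch:
            sites.append(PrimerSite(template_id, i, i + L, strand, mm))
    return sites


def predict_amplicons(
    template: str,
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    max_product_len: int = 2000,
    max_mismatch: int = 0,
    template_id: str = "",
) -> list[Amplicon]:
    """Predict PCR products from every valid forward/reverse site pair.

    Product length is inclusive of both primer footprints (5' end of the
    forward site to the 5' end of the reverse site on the opposite
    strand).  Both template orientations are considered, so a template
    and its reverse complement give products of identical lengths.
    """
    fwd = DegeneratePrimer(fwd.name, fwd.iupac_sequence, "forward")
    rev = DegeneratePrimer(rev.name, rev.iupac_sequence, "forward")

    def one_orientation(f: DegeneratePrimer, r: DegeneratePrimer,
                        swap: bool) -> list[Amplicon]:
        f_sites = match_sites(template, f, max_mismatch, template_id)
        r_probe = DegeneratePrimer(r.name, r.iupac_sequence, "reverse")
        r_sites = match_sites(template, r_probe, max_mismatch, template_id)
        out = []
        for fs in f_sites:
            for rs in r_sites:
                if rs.start < fs.end:
                    continue  # primers must point toward each other
                length = rs.end - fs.start
                if length > max_product_len:
                    continue
                fm, rm = (rs.mismatches, fs.mismatches) if swap else (fs.mismatches, rs.mismatches)
                out.append(Amplicon(template_id, fs.start, rs.end, fm, rm))
        return out

    amps = one_orientation(fwd, rev, swap=False) + one_orientation(rev, fwd, swap=True)
    # a product found in both orientations is the same molecule: dedupe
    uniq = {(a.start, a.end): a for a in sorted(amps, key=lambda a: (a.start, a.end))}
    return list(uniq.values())


def digest(
    sequence: str,
    enzymes: Sequence[str],
    enzyme_table: Mapping[str, tuple[str, int]] | None = None,
) -> list[int]:
    """Fragment lengths (5'->3') after cutting with the given enzymes.

    Fragments always sum to the input length.  Unknown enzyme names are
    a configuration error.
    """
    table = dict(ENZYMES if enzyme_table is None else enzyme_table)
    sequence = sequence.upper()
    cuts: set[int] = set()
    for name in enzymes:
        if name not in table:
            raise PrimerError(f"unknown enzyme {name!r}")
        site, offset = table[name]
        start = 0
        while True:
            i = sequence.find(site, start)
            if i < 0:
                break
            cuts.add(i + offset)
            start = i + 1
    positions = [0] + sorted(c for c in cuts if 0 < c < len(sequence)) + [len(sequence)]
    return [b - a for a, b in zip(positions, positions[1:])]


def find_sites(sequence: str, enzyme: str,
               enzyme_table: Mapping[str, tuple[str, int]] | None = None) -> list[int]:
    """0-based start offsets of an enzyme's recognition site."""
    table = dict(ENZYMES if enzyme_table is None else enzyme_table)
    if enzyme not in table:
        raise PrimerError(f"unknown enzyme {enzyme!r}")
    site = table[enzyme][0]
    sequence = sequence.upper()
    out, start = [], 0
    while True:
        i = sequence.find(site, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


@dataclass(frozen=True)
class ConditionReport:
    """Evaluation of a primer pair against the three design conditions."""

    targets_amplify: bool
    controls_less_efficient: bool
    product_geometry_ok: bool
    details: tuple[str, ...]

    @property
    def all_pass(self) -> bool:
        return (self.targets_amplify and self.controls_less_efficient
                and self.product_geometry_ok)


def evaluate_primer_conditions(
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    target_table: Mapping[tuple[str, str], tuple[str, bool]],
    min_product_len: int = 100,
    max_mismatch: int = 3,
    exon_intervals: Mapping[tuple[str, str], tuple[int, int]] | None = None,
) -> ConditionReport:
    """Check a degenerate primer pair against its three design conditions.

    ``target_table`` maps (species, gene) -> (template fragment, is
    intended target).  Conditions: (1) every intended target amplifies;
    (2) in each species, every paralog control needs at least one more
    total mismatch than the best target; (3) products are at least
    ``min_product_len`` bp and, when ``exon_intervals`` is given, both
    primer footprints fall inside the single exon interval.
    """
    if not target_table:
        raise PrimerError("empty target table")
    details: list[str] = []
    best: dict[tuple[str, str], Amplicon | None] = {}
    for key, (template, _) in target_table.items():
        amps = predict_amplicons(template, fwd, rev, max_mismatch=max_mismatch,
                                 template_id=f"{key[0]}:{key[1]}")
        best[key] = min(amps, key=lambda a: a.fwd_mismatches + a.rev_mismatches) if amps else None

    targets = {k for k, (_, is_t) in target_table.items() if is_t}
    cond1 = all(best[k] is not None for k in targets)
    for k in targets:
        if best[k] is None:
            details.append(f"target {k} does not amplify")

    cond2 = True
    for sp in {s for s, _ in target_table}:
        sp_targets = [best[k] for k in targets if k[0] == sp and best[k]]
        if not sp_targets:
            continue
        t_mm = min(a.fwd_mismatches + a.rev_mismatches for a in sp_targets)
        for k, (_, is_t) in target_table.items():
            if k[0] != sp or is_t:
                continue
            a = best[k]
            if a is not None and a.fwd_mismatches + a.rev_mismatches <= t_mm:
                cond2 = False
                details.append(
                    f"control {k} amplifies with {a.fwd_mismatches + a.rev_mismatches}"
                    f" mismatches, not more than target ({t_mm})"
                )

    cond3 = True
    for k, a in best.items():
        if a is None:
            continue
        if a.length < min_product_len:
            cond3 = False
            details.append(f"{k}: product {a.length} bp < {min_product_len} bp")
        if exon_intervals and k in exon_intervals:
            es, ee = exon_intervals[k]
            if not (es <= a.start and a.end <= ee):
                cond3 = False
                details.append(f"{k}: primer sites not within one exon")
    return ConditionReport(cond1, cond2, cond3, tuple(details))
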
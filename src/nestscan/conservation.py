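"""Cross-species conservation of nested gene structures.

Given ortholog presence/absence calls for each (host, nested) gene pair
across a panel of species, a nested structure is:

* **conserved** — both genes present in at least one *reference* species
  (e.g. coelacanth or zebrafish, which diverged before the tetrapod
  lineages under test) AND both present in *every* test species
  (e.g. chicken and clawed frog);
* **lost** — both present in at least one reference species but the
  host, the nested gene, or both are absent in at least one test
  species;
* **not assessable** — the pair cannot be confirmed in any reference
  species (it may simply be young), so no loss call is made.

An ``unknown`` call in a test species is treated as absent, flagged in
the evidence string (absences in the source analysis were verified by
BLAST and synteny; here we only surface the flag).

The module also ships the published set of 19 vertebrate nested gene
structures lost in the clawed frog or chicken lineages (hosts ASTN2,
CACNA2D3, CASK, CENPP, CTNNA1, CTNNA3, ... with their per-species
absence annotations), 12 of which have an LRR-superfamily nested gene.

``synteny_blocks`` reports shared-neighbour synteny: maximal runs of
consecutive genes on one scaffold whose orthologs are consecutive
(up to a gap allowance) in another genome, used to show that a locus
such as frog *lrrtm3* sits in the expected neighbourhood even though
its host gene is gone.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import pandas as pd

REFERENCE_ROLE = "reference"
TEST_ROLE = "test"

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"

# The published loss table: (host, nested, nested_is_LRR,
#   {test species: set of absent gene roles}).
# LRR-superfamily membership of the nested gene follows the gene family
# (LRTM, LRRTM, LRRC, LRRN, LRFN, AMIGO and the small leucine-rich
# proteoglycans ECM2/ASPN/OMD/OGN).
LOSS_TABLE_FROG_CHICKEN: list[tuple[str, str, bool, dict[str, frozenset[str]]]] = [
    ("ASTN2", "TRIM32", False, {"frog": frozenset({"nested"})}),
    ("CACNA2D3", "LRTM1", True, {"frog": frozenset({"host", "nested"})}),
    ("CASK", "GPR82", False, {"frog": frozenset({"nested"})}),
    ("CENPP", "ECM2", True, {"frog": frozenset({"host"})}),
    ("CENPP", "ASPN", True, {"frog": frozenset({"host"})}),
    ("CENPP", "OMD", True, {"frog": frozenset({"host", "nested"})}),
    ("CENPP", "OGN", True, {"frog": frozenset({"host"})}),
    ("CTNNA1", "LRRTM2", True, {"frog": frozenset({"nested"})}),
    ("CTNNA3", "LRRTM3", True, {"frog": frozenset({"host"})}),
    ("FBXL13", "LRRC17", True, {"frog": frozenset({"nested"})}),
    ("FYCO1", "CXCR6", False,
     {"frog": frozenset({"host"}), "chicken": frozenset({"nested"})}),
    ("IMMP2L", "LRRN3", True, {"frog": frozenset({"host"})}),
    ("MED12L", "P2RY13", False, {"frog": frozenset({"host"})}),
    ("MED12L", "P2RY12", False, {"frog": frozenset({"host"})}),
    ("PC", "LRFN4", True, {"chicken": frozenset({"host", "nested"})}),
    ("RNF123", "AMIGO3", True, {"frog": frozenset({"nested"})}),
    ("SND1", "LRRC4", True, {"chicken": frozenset({"host"})}),
    ("SYN1", "TIMP1", False, {"frog": frozenset({"nested"})}),
    ("TFB1M", "CLDN20", False, {"frog": frozenset({"nested"})}),
]


@dataclass
class PresenceMatrix:
    """Presence/absence calls for gene pairs across a species panel.

    ``calls`` maps (pair_index, species, gene_role) -> call where
    gene_role is "host" or "nested" and a call is present/absent/unknown.
    """

    pairs: list[tuple[str, str, bool]]  # (host_family, nested_family, nested_is_LRR)
    species_roles: dict[str, str]  # species -> reference|test|anchor
    calls: dict[tuple[int, str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roles = set(self.species_roles.values())
        if self.pairs and not {REFERENCE_ROLE, TEST_ROLE} <= roles:
            raise ValueError(
                "species roles must include at least one reference and one test species"
            )
        for i in range(len(self.pairs)):
            for sp in self.species_roles:
                for role in ("host", "nested"):
                    self.calls.setdefault((i, sp, role), UNKNOWN)

    def call(self, pair_index: int, species: str, gene_role: str) -> str:
        return self.calls[(pair_index, species, gene_role)]

    def set_call(self, pair_index: int, species: str, gene_role: str, value: str) -> None:
        if value not in (PRESENT, ABSENT, UNKNOWN):
            raise ValueError(f"bad call {value!r}")
        self.calls[(pair_index, species, gene_role)] = value

    @property
    def reference_species(self) -> list[str]:
        return sorted(s for s, r in self.species_roles.items() if r == REFERENCE_ROLE)

    @property
    def test_species(self) -> list[str]:
        return sorted(s for s, r in self.species_roles.items() if r == TEST_ROLE)

    # ---- TSV round trip -------------------------------------------------
    def to_tsv(self, stream: IO[str] | None = None) -> str:
        rows = []
        for i, (h, n, lrr) in enumerate(self.pairs):
            for sp, role in sorted(self.species_roles.items()):
                for gr in ("host", "nested"):
                    rows.append(
                        dict(host_family=h, nested_family=n,
                             nested_is_LRR=int(lrr), species=sp,
                             species_role=role, gene_role=gr,
                             call=self.call(i, sp, gr))
                    )
        df = pd.DataFrame(rows)
        if stream is None:
            return df.to_csv(sep="\t", index=False)
        df.to_csv(stream, sep="\t", index=False)
        return ""

    @classmethod
    def from_tsv(cls, source: str | IO[str]) -> "PresenceMatrix":
        if isinstance(source, str) and "\t" in source:
            source = io.StringIO(source)
        df = pd.read_csv(source, sep="\t")
        pairs: list[tuple[str, str, bool]] = []
        index: dict[tuple[str, str], int] = {}
        roles: dict[str, str] = {}
        for h, n, lrr in df[["host_family", "nested_family", "nested_is_LRR"]].itertuples(index=False):
            if (h, n) not in index:
                index[(h, n)] = len(pairs)
                pairs.append((h, n, bool(lrr)))
        for sp, role in df[["species", "species_role"]].itertuples(index=False):
            roles[sp] = role
        m = cls(pairs=pairs, species_roles=roles)
        for row in df.itertuples(index=False):
            m.set_call(index[(row.host_family, row.nested_family)],
                       row.species, row.gene_role, row.call)
        return m


@dataclass(frozen=True)
class ConservationCall:
    """Verdict for one pair: conserved / lost / not_assessable."""

    host_family: str
    nested_family: str
    nested_is_LRR: bool
    status: str  # conserved | lost | not_assessable
    loss_category: str  # nested_absent | host_absent | both_absent | none
    evidence: str

    @property
    def pair_id(self) -> str:
        return f"{self.host_family}/{self.nested_family}"


def classify_conservation(matrix: PresenceMatrix) -> list[ConservationCall]:
    """Classify every pair in the matrix as conserved, lost or not assessable.

    Reference rule is OR (present in coelacanth *or* zebrafish suffices);
    test rule is AND (must be present in chicken *and* frog to count as
    conserved).  Unknown calls in test species count as absent and are
    flagged ``(unverified)`` in the evidence string.
    """
    refs = matrix.reference_species
    tests = matrix.test_species
    if not refs or not tests:
        raise ValueError("need at least one reference and one test species")
    calls: list[ConservationCall] = []
    for i, (host, nested, lrr) in enumerate(matrix.pairs):
        ref_ok = any(
            matrix.call(i, sp, "host") == PRESENT
            and matrix.call(i, sp, "nested") == PRESENT
            for sp in refs
        )
        if not ref_ok:
            calls.append(
                ConservationCall(host, nested, lrr, "not_assessable", "none",
                                 "pair not confirmed in any reference species")
            )
            continue
        missing_roles: set[str] = set()
        notes: list[str] = []
        for sp in tests:
            for gr in ("host", "nested"):
                c = matrix.call(i, sp, gr)
                if c == PRESENT:
                    continue
                missing_roles.add(gr)
                flag = " (unverified)" if c == UNKNOWN else ""
                notes.append(f"{gr} absent in {sp}{flag}")
        if not missing_roles:
            calls.append(
                ConservationCall(host, nested, lrr, "conserved", "none",
                                 "both genes present in all test species")
            )
        else:
            category = (
                "both_absent" if missing_roles == {"host", "nested"}
                else f"{next(iter(missing_roles))}_absent"
            )
            calls.append(
                ConservationCall(host, nested, lrr, "lost", category,
                                 "; ".join(notes))
            )
    return calls


def summarize(calls: Sequence[ConservationCall]) -> dict:
    """Integer summary: totals, assessable, lost, LRR-nested lost, categories."""
    lost = [c for c in calls if c.status == "lost"]
    summary = {
        "n_pairs": len(calls),
        "n_assessable": sum(1 for c in calls if c.status != "not_assessable"),
        "n_conserved": sum(1 for c in calls if c.status == "conserved"),
        "n_lost": len(lost),
        "n_lost_LRR_nested": sum(1 for c in lost if c.nested_is_LRR),
        "n_nested_absent": sum(1 for c in lost if c.loss_category == "nested_absent"),
        "n_host_absent": sum(1 for c in lost if c.loss_category == "host_absent"),
        "n_both_absent": sum(1 for c in lost if c.loss_category == "both_absent"),
    }
    return summary


def loss_table_matrix(
    reference_species: Sequence[str] = ("coelacanth", "zebrafish"),
    test_species: Sequence[str] = ("chicken", "frog"),
) -> PresenceMatrix:
    """The published 19-pair frog/chicken loss table as a PresenceMatrix.

    Every pair is present in the reference species (that is the table's
    inclusion criterion); test-species absences follow the table's
    explanation column.
    """
    roles = {sp: REFERENCE_ROLE for sp in reference_species}
    roles.update({sp: TEST_ROLE for sp in test_species})
    pairs = [(h, n, lrr) for h, n, lrr, _ in LOSS_TABLE_FROG_CHICKEN]
    m = PresenceMatrix(pairs=pairs, species_roles=roles)
    for i, (_, _, _, absences) in enumerate(LOSS_TABLE_FROG_CHICKEN):
        for sp in roles:
            for gr in ("host", "nested"):
                m.set_call(i, sp, gr, PRESENT)
        for sp, missing in absences.items():
            for gr in missing:
                m.set_call(i, sp, gr, ABSENT)
    return m


# ---------------------------------------------------------------------------
# Shared-neighbour synteny blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntenyBlock:
    """A run of consecutive genes in A with consecutive orthologs in B."""

    genes_a: tuple[str, ...]
    genes_b: tuple[str, ...]
    contains_focal: bool
    flanks_focal: bool


def synteny_blocks(
    gene_order_a: Sequence[str],
    gene_order_b: Sequence[str],
    ortholog_map: Mapping[str, str],
    focal_gene: str,
    max_gap: int = 0,
) -> list[SyntenyBlock]:
    """Find shared-neighbour blocks between two ordered gene lists.

    A block is a maximal run of consecutive genes in ``gene_order_a``
    whose orthologs occupy consecutive positions (allowing up to
    ``max_gap`` skipped genes, in either consistent direction) in
    ``gene_order_b``.  Unmapped genes in A (no ortholog in B) are
    tolerated inside a block up to ``max_gap`` in a row.  Only blocks
    with at least two mapped genes are reported.
    """
    if focal_gene not in gene_order_a:
        raise KeyError(f"focal gene {focal_gene!r} not in gene_order_a")
    pos_b = {g: i for i, g in enumerate(gene_order_b)}
    mapped = [
        (i, g, pos_b.get(ortholog_map.get(g)))
        for i, g in enumerate(gene_order_a)
    ]

    blocks: list[SyntenyBlock] = []
    cur: list[tuple[int, str, int]] = []  # (a_index, gene, b_index), mapped only
    direction = 0
    skipped = 0

    def flush() -> None:
        nonlocal cur, direction, skipped
        if len(cur) >= 2:
            a_idx = [i for i, _, _ in cur]
            genes_a = tuple(gene_order_a[a_idx[0]: a_idx[-1] + 1])
            genes_b = tuple(ortholog_map[g] for _, g, _ in cur)
            focal_i = gene_order_a.index(focal_gene)
            contains = a_idx[0] <= focal_i <= a_idx[-1]
            flanks = not contains and (focal_i == a_idx[0] - 1 or focal_i == a_idx[-1] + 1)
            blocks.append(SyntenyBlock(genes_a, genes_b, contains, flanks))
        cur, direction, skipped = [], 0, 0

    for i, g, bi in mapped:
        if bi is None:
            skipped += 1
            if cur and skipped > max_gap:
                flush()
            continue
        if not cur:
            cur = [(i, g, bi)]
            skipped = 0
            continue
        prev_bi = cur[-1][2]
        step = bi - prev_bi
        gap = abs(step) - 1
        ok = gap <= max_gap and step != 0 and (
            direction == 0 or (step > 0) == (direction > 0)
        )
        if ok:
            if direction == 0:
                direction = 1 if step > 0 else -1
            cur.append((i, g, bi))
            skipped = 0
        else:
            flush()
            cur = [(i, g, bi)]
    flush()
    return blocks
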
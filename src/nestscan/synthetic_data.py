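"""Synthetic data generators with recorded ground truth.

Every pipeline stage in this package is exercised against generated
inputs whose true structure is known, emulating the biology of the
nested *lrrtm*/α-catenin gene system: host genes of 17 coding exons
whose designated intron (by default the one between coding exons 6 and
7) is the largest and carries an opposite-strand nested gene; lineage
events that delete the nested gene (and collapse the intron, as in the
clawed-frog *ctnna1* whose intron 6 is only 434 bp), delete the host
while leaving the nested gene amid intact neighbours (frog *lrrtm3*),
shrink the intron around a retained nested gene, or tandem-duplicate
the free-standing *lrrtm4*-like gene head-to-tail (teleost fishes).

Determinism: every generator takes a mandatory seed; one
``numpy.random.SeedSequence`` per scenario is split into independent
substreams so adding one planted feature never perturbs the others.
Motif and primer planting uses backgrounds that exclude the planted
pattern alphabet (or are verified free of spurious sites) so planted
counts are exact.

Intron and gene sizes default to desk scale (kilobases, not the real
50–450 kb introns): the structure, not the magnitude, is what the
downstream algorithms consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import (
    GeneModel,
    GenomeAnnotation,
    SequenceRecord,
    TranscriptModel,
)
from .conservation import (
    ABSENT,
    PRESENT,
    PresenceMatrix,
    REFERENCE_ROLE,
    TEST_ROLE,
)
from .primer_insilico import (
    IUPAC_SETS,
    DegeneratePrimer,
    match_sites,
)
from .splice_est import SpliceReference

_AA = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

EVENT_KINDS = ("lose_nested", "lose_host", "shrink_intron", "tandem_duplicate")


@dataclass(frozen=True)
class Event:
    """A planted lineage event: what happened to which pair in which species.

    ``pair_index`` is ignored for ``tandem_duplicate`` (it targets the
    free-standing, non-nested gene).
    """

    species: str
    kind: str
    pair_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigError(f"unknown event kind {self.kind!r}")


@dataclass
class ScenarioConfig:
    """Parameters of one multi-species annotation scenario.

    Defaults emulate the amniote condition: three host/nested pairs of
    17-coding-exon hosts, the designated large intron being intron 6,
    plus one free-standing non-nested gene.
    """

    seed: int
    species: list[str] = field(default_factory=lambda: ["human", "chicken", "frog"])
    n_pairs: int = 3
    host_coding_exons: int = 17
    host_exon_len: int = 150
    intron_len_range: tuple[int, int] = (300, 900)
    large_intron_index: int = 6
    large_intron_len: int = 6000
    nested_coding_exons: int = 2
    nested_first_exon_cds: int = 4
    nested_cds_len: int = 800
    nested_utr_len: int = 100
    neighbors_per_side: int = 2
    shrunken_intron_len: int = 434
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not 1 <= self.large_intron_index <= self.host_coding_exons - 1:
            raise ConfigError("large_intron_index out of range")
        seen: set[tuple[str, str, int]] = set()
        per_pair: dict[tuple[str, int], set[str]] = {}
        for ev in self.events:
            if ev.species not in self.species:
                raise ConfigError(f"event species {ev.species!r} not in species list")
            key = (ev.species, ev.kind, ev.pair_index)
            if key in seen:
                raise ConfigError(f"duplicate event {key}")
            seen.add(key)
            kinds = per_pair.setdefault((ev.species, ev.pair_index), set())
            kinds.add(ev.kind)
            if {"lose_nested", "lose_host"} <= kinds or \
               {"lose_nested", "shrink_intron"} <= kinds:
                raise ConfigError(
                    f"contradictory events on pair {ev.pair_index} in {ev.species}"
                )


# canonical symbols for the first three pairs and the free gene
_HOST_SYMBOLS = ["CTNNA2", "CTNNA1", "CTNNA3"]
_NESTED_SYMBOLS = ["LRRTM1", "LRRTM2", "LRRTM3"]
FREE_GENE_SYMBOL = "LRRTM4"


def _pair_symbols(p: int) -> tuple[str, str]:
    if p < 3:
        return _HOST_SYMBOLS[p], _NESTED_SYMBOLS[p]
    return f"HOST{p + 1}", f"NEST{p + 1}"


@dataclass
class TruthTable:
    """Ground truth for everything a scenario generated."""

    nested_pairs: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict)
    presence: dict[tuple[int, str, str], str] = field(default_factory=dict)
    free_gene_copies: dict[str, int] = field(default_factory=dict)
    intron_lengths: dict[tuple[str, int], int] = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _build_host(
    gene_id: str, symbol: str, scaffold: str, start: int,
    cfg: ScenarioConfig, rng: np.random.Generator,
    large_len: int,
) -> tuple[GeneModel, tuple[int, int]]:
    """Host gene on +; returns (gene, large intron interval)."""
    introns = [
        int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1]))
        for _ in range(cfg.host_coding_exons - 1)
    ]
    introns[cfg.large_intron_index - 1] = large_len
    cds = []
    pos = start
    large_iv = (0, 0)
    for i in range(cfg.host_coding_exons):
        cds.append((pos, pos + cfg.host_exon_len))
        pos += cfg.host_exon_len
        if i < cfg.host_coding_exons - 1:
            if i == cfg.large_intron_index - 1:
                large_iv = (pos, pos + introns[i])
            pos += introns[i]
    tx = TranscriptModel(transcript_id=f"{gene_id}.t1", exons=list(cds),
                         cds_segments=list(cds))
    gene = GeneModel(gene_id=gene_id, scaffold=scaffold, strand="+",
                     span=(start, pos), transcripts=[tx], symbol=symbol,
                     biotype="protein_coding")
    return gene, large_iv


def _build_nested(
    gene_id: str, symbol: str, scaffold: str, intron: tuple[int, int],
    cfg: ScenarioConfig, rng: np.random.Generator, strand: str = "-",
) -> GeneModel:
    """Nested gene centred in the host intron, opposite strand by default.

    Mirrors the *lrrtm* layout: a tiny first coding exon carrying the
    start codon plus one extra nucleotide, and a second coding exon with
    the bulk of the open reading frame.
    """
    total_cds = cfg.nested_cds_len
    n_exons = cfg.nested_coding_exons
    gene_len = total_cds + (n_exons - 1) * 200 + 2 * cfg.nested_utr_len
    ilen = intron[1] - intron[0]
    if gene_len + 2 >= ilen:
        raise ConfigError(
            f"nested gene ({gene_len} bp) does not fit in intron ({ilen} bp)"
        )
    start = intron[0] + 1 + int(rng.integers(0, ilen - gene_len - 2))
    # lay out in genomic order; translation order handled by strand
    exons, cds = [], []
    pos = start + cfg.nested_utr_len
    if n_exons == 1:
        cds.append((pos, pos + total_cds))
        pos += total_cds
    else:
        big = total_cds - cfg.nested_first_exon_cds
        # on '-', the first coding exon in translation order is rightmost
        sizes = [big, cfg.nested_first_exon_cds] if strand == "-" else \
                [cfg.nested_first_exon_cds, big]
        for i, sz in enumerate(sizes):
            cds.append((pos, pos + sz))
            pos += sz
            if i < n_exons - 1:
                pos += 200
    # exons: first exon includes 5' UTR, last includes 3' UTR (genomic sense)
    exons = [list(iv) for iv in cds]
    exons[0][0] = start
    exons[-1][1] = cds[-1][1] + cfg.nested_utr_len
    end = exons[-1][1]
    tx = TranscriptModel(transcript_id=f"{gene_id}.t1",
                         exons=[tuple(e) for e in exons],
                         cds_segments=cds)
    return GeneModel(gene_id=gene_id, scaffold=scaffold, strand=strand,
                     span=(start, end), transcripts=[tx], symbol=symbol,
                     family_tags={"LRR-superfamily"}, biotype="protein_coding")


def _single_exon_gene(gene_id: str, symbol: str, scaffold: str, start: int,
                      length: int, strand: str = "+") -> GeneModel:
    tx = TranscriptModel(transcript_id=f"{gene_id}.t1",
                         exons=[(start, start + length)],
                         cds_segments=[(start, start + length)])
    return GeneModel(gene_id=gene_id, scaffold=scaffold, strand=strand,
                     span=(start, start + length), transcripts=[tx],
                     symbol=symbol, biotype="protein_coding")


def make_species_set(
    config: ScenarioConfig,
) -> tuple[list[GenomeAnnotation], TruthTable]:
    """Generate one :class:`GenomeAnnotation` per species, plus ground truth.

    Per pair: a scaffold carrying neighbour genes, the host gene with
    its designated large intron, and (unless deleted by an event) the
    opposite-strand nested gene.  One extra scaffold carries the
    free-standing non-nested gene (tandem-duplicated where the event
    says so).
    """
    root = np.random.SeedSequence(config.seed)
    species_seeds = root.spawn(len(config.species))
    truth = TruthTable(events=list(config.events))
    annotations: list[GenomeAnnotation] = []

    ev_index: dict[tuple[str, int], str] = {}
    dup_species = set()
    for ev in config.events:
        if ev.kind == "tandem_duplicate":
            dup_species.add(ev.species)
        else:
            ev_index[(ev.species, ev.pair_index)] = ev.kind

    for sp, sp_seed in zip(config.species, species_seeds):
        rng = np.random.default_rng(sp_seed)
        genes: list[GeneModel] = []
        sequences: dict[str, SequenceRecord] = {}
        truth.nested_pairs[sp] = []
        for p in range(config.n_pairs):
            host_sym, nested_sym = _pair_symbols(p)
            scaffold = f"{sp}_scaffold_{p + 1}"
            event = ev_index.get((sp, p))
            cursor = 1000
            for k in range(config.neighbors_per_side):
                g = _single_exon_gene(f"{sp}_nb{p}_{k}", f"NB{p}_{k}",
                                      scaffold, cursor, 1500)
                genes.append(g)
                cursor = g.span[1] + 800

            host_present = event != "lose_host"
            nested_present = event != "lose_nested"
            large_len = config.large_intron_len
            if event == "lose_nested":
                large_len = config.shrunken_intron_len
            elif event == "shrink_intron":
                gene_len = (config.nested_cds_len
                            + (config.nested_coding_exons - 1) * 200
                            + 2 * config.nested_utr_len)
                large_len = gene_len + 2 * 40  # compact intron, gene still fits

            host_id = f"{sp}_{host_sym.lower()}"
            nested_id = f"{sp}_{nested_sym.lower()}"
            if host_present:
                host, large_iv = _build_host(host_id, host_sym, scaffold,
                                             cursor, config, rng, large_len)
                genes.append(host)
                truth.intron_lengths[(host_id, config.large_intron_index)] = large_len
                if nested_present:
                    nested = _build_nested(nested_id, nested_sym, scaffold,
                                           large_iv, config, rng)
                    genes.append(nested)
                    truth.nested_pairs[sp].append(
                        (host_id, nested_id, config.large_intron_index)
                    )
                cursor = host.span[1] + 800
            elif nested_present:
                # host lost: nested gene survives amid the neighbours
                g = _build_nested(nested_id, nested_sym, scaffold,
                                  (cursor, cursor + config.large_intron_len),
                                  config, rng)
                genes.append(g)
                cursor = cursor + config.large_intron_len + 800
            for k in range(config.neighbors_per_side):
                g = _single_exon_gene(f"{sp}_nb{p}_d{k}", f"NB{p}_d{k}",
                                      scaffold, cursor, 1500)
                genes.append(g)
                cursor = g.span[1] + 800
            sequences[scaffold] = SequenceRecord(
                scaffold, _random_dna(rng, cursor + 500), "DNA"
            )
            truth.presence[(p, sp, "host")] = PRESENT if host_present else ABSENT
            truth.presence[(p, sp, "nested")] = PRESENT if nested_present else ABSENT

        # free-standing non-nested gene (lrrtm4 analog)
        scaffold = f"{sp}_scaffold_free"
        n_copies = 2 if sp in dup_species else 1
        cursor = 1000
        for c in range(n_copies):
            g = _single_exon_gene(
                f"{sp}_{FREE_GENE_SYMBOL.lower()}" + (f"_{c + 1}" if n_copies > 1 else ""),
                FREE_GENE_SYMBOL, scaffold, cursor, 2400
            )
            genes.append(g)
            cursor = g.span[1] + 300  # head-to-tail
        truth.free_gene_copies[sp] = n_copies
        sequences[scaffold] = SequenceRecord(
            scaffold, _random_dna(rng, cursor + 500), "DNA"
        )

        genes.sort(key=lambda g: (g.scaffold, g.span[0], g.gene_id))
        annotations.append(
            GenomeAnnotation(species=sp, genes=genes, sequences=sequences)
        )
    return annotations, truth


# ---------------------------------------------------------------------------
# Random annotations for oracle tests
# ---------------------------------------------------------------------------

def make_random_annotation(seed: int, n_genes: int = 30,
                           n_scaffolds: int = 3) -> GenomeAnnotation:
    """A random but structurally valid annotation for stress tests.

    About a third of genes are dropped inside another gene's intron (on
    either strand), so containment relations of both kinds occur; some
    genes are non-coding.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    intron_slots: list[tuple[str, int, int]] = []
    for i in range(n_genes):
        scaffold = f"scf{int(rng.integers(1, n_scaffolds + 1))}"
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "protein_coding" if rng.random() < 0.85 else "other"
        nest_here = intron_slots and rng.random() < 0.35
        if nest_here:
            idx = int(rng.integers(0, len(intron_slots)))
            scf, lo, hi = intron_slots[idx]
            scaffold = scf
            width = hi - lo
            glen = int(rng.integers(50, max(60, width)))
            glen = min(glen, width - 2)
            start = lo + 1 + int(rng.integers(0, max(1, width - glen - 1)))
        else:
            start = int(rng.integers(0, 50_000))
            glen = int(rng.integers(200, 8000))
        n_exons = int(rng.integers(1, 6))
        cuts = sorted(rng.choice(np.arange(1, max(2, glen)), size=min(2 * n_exons - 2, glen - 2), replace=False).tolist()) if n_exons > 1 else []
        bounds = [0] + cuts + [glen]
        cds = []
        for k in range(0, len(bounds) - 1, 2):
            s, e = bounds[k], bounds[k + 1]
            if e > s:
                cds.append((start + s, start + e))
        if not cds:
            cds = [(start, start + glen)]
        tx = TranscriptModel(transcript_id=f"g{i}.t1", exons=list(cds),
                             cds_segments=list(cds) if biotype == "protein_coding" else list(cds))
        gene = GeneModel(gene_id=f"g{i}", scaffold=scaffold, strand=strand,
                         span=(cds[0][0], cds[-1][1]), transcripts=[tx],
                         symbol=f"G{i}", biotype=biotype)
        genes.append(gene)
        for (a, b), (c, _) in zip(cds, cds[1:]):
            if c - b > 60:
                intron_slots.append((scaffold, b, c))
    genes.sort(key=lambda g: (g.scaffold, g.span[0], g.gene_id))
    return GenomeAnnotation(species=f"random{seed}", genes=genes)


# ---------------------------------------------------------------------------
# Presence matrices with planted truth
# ---------------------------------------------------------------------------

def make_presence_matrix(
    n_pairs: int,
    seed: int,
    reference_species: Sequence[str] = ("coelacanth", "zebrafish"),
    test_species: Sequence[str] = ("chicken", "frog"),
    p_lost: float = 0.3,
    p_not_assessable: float = 0.2,
    p_lrr: float = 0.5,
) -> tuple[PresenceMatrix, list[str]]:
    """Random presence matrix with a planted status per pair.

    Returns the matrix and the list of true statuses
    (conserved / lost / not_assessable), in pair order.  No unknown
    calls are generated.
    """
    if not 0 <= p_lost + p_not_assessable <= 1:
        raise ConfigError("probabilities must sum to <= 1")
    rng = np.random.default_rng(seed)
    roles = {sp: REFERENCE_ROLE for sp in reference_species}
    roles.update({sp: TEST_ROLE for sp in test_species})
    pairs = [(f"HOST{i}", f"NEST{i}", bool(rng.random() < p_lrr))
             for i in range(n_pairs)]
    m = PresenceMatrix(pairs=pairs, species_roles=roles)
    statuses: list[str] = []
    for i in range(n_pairs):
        u = rng.random()
        status = ("lost" if u < p_lost
                  else "not_assessable" if u < p_lost + p_not_assessable
                  else "conserved")
        statuses.append(status)
        for sp in roles:
            for gr in ("host", "nested"):
                m.set_call(i, sp, gr, PRESENT)
        if status == "not_assessable":
            # no reference species has both genes present
            for sp in reference_species:
                gr = "host" if rng.random() < 0.5 else "nested"
                m.set_call(i, sp, gr, ABSENT)
        elif status == "lost":
            sp = test_species[int(rng.integers(0, len(test_species)))]
            roles_missing = [["nested"], ["host"], ["host", "nested"]][
                int(rng.integers(0, 3))
            ]
            for gr in roles_missing:
                m.set_call(i, sp, gr, ABSENT)
    return m, statuses


def make_survey_matrix_synthetic(
    n_total: int = 91,
    n_assessable: int = 63,
    seed: int = 20140224,
) -> PresenceMatrix:
    """Synthetic stand-in for the 91-pair nested-gene survey.

    The full catalogue of the 91 human/mouse different-strand nested
    gene pairs behind the survey is not bundled here; this stand-in
    reproduces its marginal structure exactly — 91 pairs of which 63
    have orthologs in zebrafish and/or coelacanth, 19 of those lost in
    frog or chicken (the 19 known pairs, transcribed verbatim) and 44
    conserved — with synthetic names for the pairs whose identities are
    not individually known here.
    """
    from .conservation import LOSS_TABLE_FROG_CHICKEN, loss_table_matrix

    rng = np.random.default_rng(seed)
    m = loss_table_matrix()
    n_lost = len(LOSS_TABLE_FROG_CHICKEN)
    n_conserved = n_assessable - n_lost
    n_young = n_total - n_assessable
    next_id = 1
    for _ in range(n_conserved):
        m.pairs.append((f"SYNHOST{next_id:03d}", f"SYNNEST{next_id:03d}", False))
        i = len(m.pairs) - 1
        for sp in m.species_roles:
            for gr in ("host", "nested"):
                m.set_call(i, sp, gr, PRESENT)
        next_id += 1
    for _ in range(n_young):
        m.pairs.append((f"SYNHOST{next_id:03d}", f"SYNNEST{next_id:03d}", False))
        i = len(m.pairs) - 1
        for sp in m.species_roles:
            role = m.species_roles[sp]
            for gr in ("host", "nested"):
                if role == REFERENCE_ROLE:
                    m.set_call(i, sp, gr, ABSENT)
                else:
                    m.set_call(i, sp, gr,
                               PRESENT if rng.random() < 0.5 else ABSENT)
        next_id += 1
    return m


# ---------------------------------------------------------------------------
# Flank sequences with planted motifs
# ---------------------------------------------------------------------------

def make_flank_sequences(
    plan: Mapping[str, int],
    seed: int,
    flank_len: int = 200,
) -> tuple[dict[str, str], dict[str, int]]:
    """Flank sequences with exactly the planted number of UWAA motifs.

    ``plan`` maps region names (e.g. "up", "down") to motif counts.  The
    background is C/G-only so no spurious U(A/U)AA match can arise; each
    planted motif is TWAA (DNA sense) followed by a C/G spacer.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    for region, k in plan.items():
        if k < 0:
            raise ConfigError("motif counts must be >= 0")
        if 4 * k + (k + 1) > flank_len:
            raise ConfigError(f"{k} motifs do not fit in {flank_len} nt")
        bg_total = flank_len - 4 * k
        # k+1 background chunks, each >= 1
        chunks = np.ones(k + 1, dtype=int)
        extra = bg_total - (k + 1)
        for _ in range(extra):
            chunks[int(rng.integers(0, k + 1))] += 1
        parts = []
        for j in range(k + 1):
            parts.append("".join(rng.choice(list("CG"), size=chunks[j])))
            if j < k:
                w = "A" if rng.random() < 0.5 else "T"
                parts.append("T" + w + "AA")
        seqs[region] = "".join(parts)
        assert len(seqs[region]) == flank_len
    return seqs, dict(plan)


# ---------------------------------------------------------------------------
# EST pools
# ---------------------------------------------------------------------------

def make_splice_reference(seed: int = 0, length: int = 160,
                          as4: tuple[int, int] = (65, 95)) -> SpliceReference:
    """A random protein-space reference fragment with an AS4 segment."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_AA), size=length))
    return SpliceReference(sequence=seq, as4=as4)


def make_ests(
    reference: SpliceReference,
    p_skip: float,
    n: int,
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[str]]:
    """EST pool covering the AS4 junction, with true skip/retain labels.

    Each EST is a reference subsequence spanning AS4 with generous
    flanks; with probability ``p_skip`` the AS4 segment is deleted;
    residues are substituted at ``error_rate``.  Windows are drawn so
    that every EST passes the length/identity/overlap filters, making
    the pool fully informative for fraction estimation.
    """
    if not 0 <= p_skip <= 1:
        raise ConfigError("p_skip must be in [0, 1]")
    rng = np.random.default_rng(seed)
    a_s, a_e = reference.as4
    L = len(reference.sequence)
    as4_len = a_e - a_s
    # guarantee >= 80 aligned residues even when AS4 is deleted
    max_start = max(0, min(a_s - 25, (L - as4_len - 80) // 2))
    ests: list[tuple[str, str]] = []
    labels: list[str] = []
    for i in range(n):
        start = int(rng.integers(0, max_start + 1))
        end = int(rng.integers(min(L, a_e + 40), L + 1))
        skip = bool(rng.random() < p_skip)
        if skip:
            seq = reference.sequence[start:a_s] + reference.sequence[a_e:end]
        else:
            seq = reference.sequence[start:end]
        if error_rate > 0:
            chars = list(seq)
            for j in range(len(chars)):
                if rng.random() < error_rate:
                    choices = [c for c in _AA if c != chars[j]]
                    chars[j] = choices[int(rng.integers(0, len(choices)))]
            seq = "".join(chars)
        ests.append((f"est{i:04d}", seq))
        labels.append("skip" if skip else "retain")
    return ests, labels


# ---------------------------------------------------------------------------
# Primer templates
# ---------------------------------------------------------------------------

def _concrete(primer: DegeneratePrimer, rng: np.random.Generator) -> str:
    return "".join(
        sorted(IUPAC_SETS[c])[int(rng.integers(0, len(IUPAC_SETS[c])))]
        for c in primer.iupac_sequence
    )


def _inject_mismatches(site: str, probe_iupac: str, k: int,
                       rng: np.random.Generator) -> str:
    """Mutate k distinct positions of a planted site to bases outside the
    probe's IUPAC set at that position."""
    site = list(site)
    positions = rng.choice(len(site), size=k, replace=False)
    for p in positions:
        allowed = IUPAC_SETS[probe_iupac[p]]
        outside = sorted(set("ACGT") - allowed)
        if not outside:  # N position: cannot mismatch, pick another
            raise ConfigError("cannot inject mismatch at an N position")
        site[p] = outside[int(rng.integers(0, len(outside)))]
    return "".join(site)


def make_primer_template(
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    product_len: int = 144,
    mismatches: tuple[int, int] = (0, 0),
    seed: int = 0,
    margin: int = 50,
    core_insert: str = "",
) -> tuple[str, dict]:
    """Template with one planted amplicon of the requested product length.

    The forward footprint and the reverse-complemented reverse footprint
    are planted ``product_len`` apart (outer-edge distance); the middle
    is random background, optionally carrying ``core_insert`` (e.g. a
    restriction site) at its centre.  Requested mismatch counts are
    injected at recorded positions.  The template is verified free of
    spurious primer sites at the injected mismatch level (rejection
    sampling on the background).
    """
    from Bio.Seq import Seq

    inner = product_len - len(fwd) - len(rev)
    if inner < len(core_insert) or inner < 0:
        raise ConfigError("product length too short for the primer pair")
    root = np.random.SeedSequence(seed)
    for attempt, sub in enumerate(root.spawn(50)):
        rng = np.random.default_rng(sub)
        f_site = _concrete(fwd, rng)
        r_site_rc = str(Seq(_concrete(rev, rng)).reverse_complement())
        if mismatches[0]:
            f_site = _inject_mismatches(f_site, fwd.iupac_sequence,
                                        mismatches[0], rng)
        if mismatches[1]:
            rc_probe = str(Seq(rev.iupac_sequence).reverse_complement())
            r_site_rc = _inject_mismatches(r_site_rc, rc_probe,
                                           mismatches[1], rng)
        mid_len = inner - len(core_insert)
        left = mid_len // 2
        middle = (_random_dna(rng, left) + core_insert
                  + _random_dna(rng, mid_len - left))
        template = (_random_dna(rng, margin) + f_site + middle + r_site_rc
                    + _random_dna(rng, margin))
        mm = max(mismatches)
        f_hits = match_sites(template, DegeneratePrimer(fwd.name, fwd.iupac_sequence, "forward"), mm)
        r_hits = match_sites(template, DegeneratePrimer(rev.name, rev.iupac_sequence, "reverse"), mm)
        want_f = (margin, margin + len(fwd))
        want_r = (margin + product_len - len(rev), margin + product_len)
        if ([(h.start, h.end) for h in f_hits] == [want_f]
                and [(h.start, h.end) for h in r_hits] == [want_r]):
            truth = {
                "fwd_site": want_f,
                "rev_site": want_r,
                "fwd_mismatches": mismatches[0],
                "rev_mismatches": mismatches[1],
                "product_len": product_len,
            }
            return template, truth
    raise ConfigError("could not generate a spurious-site-free template")


# ---------------------------------------------------------------------------
# Proteins of designed charge composition
# ---------------------------------------------------------------------------

def make_charged_protein(
    target_pi: float,
    length: int = 230,
    seed: int = 0,
    model: str = "emboss",
) -> str:
    """A protein sequence whose isoelectric point is close to ``target_pi``.

    A neutral leucine-rich backbone (L/S/N/A/G/T — the residue classes
    that dominate LRR consensus positions) is salted with K, D and H
    counts chosen by grid search to put the computed pI as close to the
    target as integer composition allows (histidine's mid-range pKa
    gives fine control between the Asp and N-terminus plateaus).
    Residue order is shuffled deterministically; pI depends on
    composition only.
    """
    from .protein_charge import PKA_TABLES, isoelectric_point

    pka = PKA_TABLES[model]
    max_charged = min(45, length // 4)
    n_k, n_d, n_h = np.meshgrid(
        np.arange(max_charged + 1), np.arange(max_charged + 1), np.arange(9),
        indexing="ij",
    )

    def q(p: float):
        return (n_k / (1 + 10.0 ** (p - pka["K"]))
                + n_h / (1 + 10.0 ** (p - pka["H"]))
                + 1 / (1 + 10.0 ** (p - pka["nterm"]))
                - n_d / (1 + 10.0 ** (pka["D"] - p))
                - 1 / (1 + 10.0 ** (pka["cterm"] - p)))

    # shortlist compositions nearly neutral at the target pH, then rank
    # them by the exact pI of the corresponding sequence composition
    flat = np.abs(q(target_pi)).ravel()
    best: tuple[float, str] | None = None
    for idx in np.argsort(flat)[:25]:
        k, d, h = np.unravel_index(idx, n_k.shape)
        probe = "K" * int(n_k[k, d, h]) + "D" * int(n_d[k, d, h]) \
            + "H" * int(n_h[k, d, h])
        probe += "G" * (length - len(probe))
        err = abs(isoelectric_point(probe, model) - target_pi)
        if best is None or err < best[0]:
            best = (err, probe)
    counts = {r: best[1].count(r) for r in "KDH"}
    rng = np.random.default_rng(seed)
    n_charged = sum(counts.values())
    backbone = rng.choice(list("LSNAGT"), size=length - n_charged)
    residues = (list(backbone) + ["K"] * counts["K"] + ["D"] * counts["D"]
                + ["H"] * counts["H"])
    rng.shuffle(residues)
    return "".join(residues)
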
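# Methods

This note documents the models, conventions and design choices behind
each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Gene models and coding introns

Internal coordinates are 0-based half-open; GFF3 on disk is 1-based
inclusive, converted only at the I/O boundary. Parsing uses gffutils
(in-memory database); writing is deterministic (genes sorted by
scaffold, start, id; children by id and start), which makes
`read ∘ write` idempotent and byte-stable — a property the test suite
relies on for round-trip and determinism checks.

When a gene has several transcripts, the **canonical transcript** is
the one with the longest total CDS, ties broken by lexicographically
smallest transcript id. Published analyses of this kind typically use
single curated models per gene; a fixed, documented rule is the
reproducible generalisation. "Coding exon" means a CDS segment:
UTR-only exons never participate in intron numbering. Coding introns
are numbered 1..n−1 in translation order, so on the minus strand the
genomic order of introns is the reverse of their indices. Ties for the
longest intron go to the smallest index.

## Nested-pair detection

A pair (host, nested) is emitted iff the nested gene's whole span —
including UTR exons — lies strictly inside one coding intron of the
host's canonical transcript, on the same scaffold. Decisions taken
where the notion of "totally inside" needed sharpening:

* **Strict containment**: a nested gene touching a CDS boundary is
  rejected. This guarantees zero overlap between the nested gene and
  any host coding base, which is checked exhaustively on synthetics.
* **Whole-gene rule**: the nested gene's UTR exons must also fit. A
  gene whose UTR pokes into a host exon is an overlapping gene, not a
  nested one.
* Containment is evaluated against the canonical transcript only; a
  host may yield several pairs (one per nested gene).
* Genes with unknown biotypes are kept as `other` and excluded from
  candidacy when `require_protein_coding` is set.

Host introns are indexed in an interval tree per scaffold; detection is
O((genes + pairs)·log introns) and is validated against an O(n²)
brute-force containment oracle on 100 random annotation sets.

## Conservation classification

The reference rule is OR (present in coelacanth *or* zebrafish); the
test rule is AND (present in chicken *and* clawed frog). Pairs absent
in all reference species are *not assessable* rather than lost — they
may simply be young — mirroring the 63-of-91 gate in the published
survey. An `unknown` call in a test species is treated as absent but
flagged `(unverified)` in the evidence string: the original analysis
verified absences by BLAST and synteny, which is out of scope here, so
the flag is surfaced instead.

A lost pair gets one aggregate `loss_category`
(`nested_absent` / `host_absent` / `both_absent`) plus a per-species
evidence string. A pair that lost its host in one test species and its
nested gene in another is `both_absent`, with both facts in the
evidence — the per-species detail is never collapsed away.

The 19-row frog/chicken loss table is transcribed as an in-package
constant, with LRR-superfamily membership assigned by gene family
(LRTM, LRRTM, LRRC, LRRN, LRFN, AMIGO, and the small leucine-rich
proteoglycans ECM2/ASPN/OMD/OGN): 12 of the 19 nested genes. The full
91-pair survey catalogue is not bundled, so
`make_survey_matrix_synthetic` builds a labelled synthetic stand-in
that reproduces its marginal counts (91 total, 63 assessable, 19 lost)
around the real 19 rows.

### Synteny blocks

`synteny_blocks` implements a shared-neighbour definition: a maximal
run of consecutive genes in list A whose orthologs occupy consecutive
positions in list B, in a consistent direction, allowing up to
`max_gap` interlopers (skipped B genes, or unmapped A genes). Blocks of
fewer than two mapped genes are not reported. This is deliberately a
simplification of sliding-window paralogon detection — enough to show
that a focal gene (e.g. an orphaned *lrrtm3*) sits between two blocks
syntenic to the expected regions.

## Flank motifs

Flanks are extracted in transcription orientation (minus-strand genes
reverse-complemented) and clipped at the neighbouring exon, i.e. to the
length of the flanking intron, with a truncation flag; a terminal exon
has an empty, flagged flank. Motif matching treats T≡U and is
case-insensitive; `W` expands to {A, U}. The default counts
**overlapping** occurrences (UUAAA contains two UWAA hits) because a
plain text search for repeats does not define the alternative; the
greedy non-overlapping mode is exposed as a flag. Motifs are counted on
the sense (pre-mRNA) strand only, since KHDBRS-family regulators bind
the transcript.

## EST skip/retain classification

Database search is replaced by local pairwise alignment
(`Bio.Align.PairwiseAligner`, BLOSUM62, gap open −11 / extend −1 —
standard protein-search defaults). Nucleotide ESTs are translated in 3
sense frames by default (ESTs are assumed sense-oriented; a 6-frame
flag exists) and the best-scoring frame kept. Tie-break among
co-optimal alignments: smallest reference start among the first
enumerated paths.

Relevance filters: aligned length ≥ 80 aa, identity > 30% (both over
residue-residue columns), and the aligned reference envelope must
overlap the AS4 segment or abut its junction. Calling thresholds —
`min_flank = 10` aligned residues required on each side of AS4 for a
*skip* call (with zero aligned residues inside the segment), and
`min_cover = 0.5` of the segment for a *retain* call — quantify a
criterion the source analysis left informal; both are exposed as
parameters. The skip fraction is reported as an exact rational plus a
rounded percentage, with indeterminate calls excluded.

## In-silico PCR

Degeneracy is the product of per-position IUPAC cardinalities and is
verified against exhaustive expansion wherever feasible. Matching uses
base-set membership, which equals the minimum mismatch count over the
expansion because positions are independent. **Product length is
inclusive of both primer footprints** (5′ end of the forward site to
the 5′ end of the reverse site on the opposite strand); this convention
reproduces the printed 144 bp product of the ctnna3 primer pair and is
fixed throughout. Both template orientations are scanned, so a template
and its reverse complement yield identical product lengths. Restriction
digestion uses a small built-in table (site + top-strand cut offset,
e.g. HindIII A^AGCTT, StuI AGG^CCT), extensible by passing a custom
table; fragment lengths always sum to the input length. Melting
temperature and annealing thermodynamics are out of scope (wet-lab
territory), as is primer design itself: the package only *evaluates*
given primers against the three design conditions (targets amplify;
paralog controls need ≥1 extra mismatch; product ≥ 100 bp within one
exon).

## Protein charge

The default pKa set is the EMBOSS table (N-term 8.6, C-term 3.6,
K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1); a Sillero table is
included and custom tables can be supplied. Published pI values from
other software differ by up to a few tenths of a pH unit purely from
the pKa table, hence the ±0.3 tolerance used when comparing to printed
values. Cysteine is ionizable by default (free-thiol assumption); a
flag disables it for disulfide-bonded domains. X/B/Z/U/O residues are
excluded from the charge sum with a warning. Bisection runs until
|charge| < tol (default 1e−4) or the pH interval collapses; with a
tight tol the result matches a 1e−4-step grid scan within 2e−4. Domain
boundaries (e.g. the LRR region minus signal peptide and hinge) are
always an explicit input, never inferred from sequence.

## Synthetic generators

`make_species_set` emulates the structure of the vertebrate system:
per pair, a scaffold with flanking neighbour genes, a host of 17 coding
exons whose designated intron (index 6) is the largest, and a two-exon
opposite-strand nested gene whose first coding exon carries just the
start codon plus one nucleotide; a separate scaffold carries the
free-standing non-nested gene. Events: `lose_nested` deletes the nested
gene and collapses the intron to 434 bp; `lose_host` deletes the host
leaving the nested gene amid intact neighbours; `shrink_intron`
compacts the intron around a retained nested gene (lamprey-style);
`tandem_duplicate` copies the free gene head-to-tail. Intron sizes are
desk scale (kilobases, default large intron 6 kb, not the real
50–450 kb): downstream algorithms consume structure, not magnitude.

Backgrounds for motif planting are C/G-only and each planted TWAA is
followed by a C/G spacer, so planted counts are provably exact; primer
templates use random ACGT backgrounds verified free of spurious sites
at the relevant mismatch level (rejection sampling on a split seed
stream). EST windows always span the AS4 junction with ≥80 residues
remaining after deletion, so generated pools are fully informative.
Determinism is absolute: one `SeedSequence` per scenario, split into
substreams per species/feature, giving byte-identical GFF3 and FASTA
for identical configs.

Where the original input sequences are not bundled (LRR-domain
sequences, the full 91-pair survey, PCR fragment sequences, AS4 flank
sequences), the package uses synthetic stand-ins labelled as such,
designed to reproduce the reported values (pI targets via
`make_charged_protein`, which grid-searches K/D/H composition on a
neutral LRR-like backbone; 144 bp templates with the diagnostic
HindIII/StuI insert; flanks with 1/3 planted motifs). Passing tests
therefore demonstrate the *algorithms* reproduce the printed numbers
given inputs with the stated properties — not that the original
biological sequences were re-derived.

## What passing tests do not show

* Real genome annotations are messier than the generator: overlapping
  isoforms, trans-spliced or partial models, assembly gaps. The
  detector handles only well-formed gene/mRNA/exon/CDS hierarchies.
* Conservation calls are only as good as the input presence matrix;
  the package does not do ortholog inference, BLAST verification, or
  synteny-based absence confirmation.
* The EST classifier is tested against its own generator's error model
  (uniform substitutions); real ESTs carry indels, vector sequence and
  chimeras.
* Desk-scale simulation sizes were chosen to keep the full suite fast
  (hundreds of random annotations of ≤50 genes, EST pools of 500,
  1000-sequence digest battery) while still exercising every code
  path against an independent oracle.
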
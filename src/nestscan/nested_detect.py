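"""Detection of nested gene structures.

A *nested* gene is situated totally inside another gene — here, strictly
inside one coding intron of the host's canonical transcript, so that the
nested gene is flanked by protein-coding exons of the host on both
sides.  The classic vertebrate example is an *lrrtm* gene lying on the
opposite strand inside the large intron between coding exons 6 and 7 of
an alpha-catenin (*ctnna*) gene.

Containment is strict at both ends: a nested gene touching a host CDS
boundary is rejected.  The whole nested gene span (including UTR exons)
must fit inside the intron.  One host may carry several nested genes in
the same or different introns; each is reported as its own pair.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import (
    GeneModel,
    GenomeAnnotation,
    coding_introns,
)


@dataclass(frozen=True)
class NestedPair:
    """A detected host/nested gene relationship."""

    host_id: str
    nested_id: str
    strand_relation: str  # "different_strand" | "same_strand"
    host_intron_index: int
    host_intron_length: int
    nested_coding_exon_count: int
    flanked_by_coding_exons: bool = True


def find_nested_pairs(
    annotation: GenomeAnnotation,
    require_different_strand: bool = True,
    require_protein_coding: bool = True,
) -> list[NestedPair]:
    """Find all genes strictly contained in a coding intron of another gene.

    Parameters mirror the selection applied to catalogued vertebrate
    nested genes: ``require_different_strand`` keeps only opposite-strand
    pairs, ``require_protein_coding`` demands both genes be protein
    coding.  Output is sorted by (host_id, nested_id).
    """
    # index coding introns of candidate hosts per scaffold
    trees: dict[str, IntervalTree] = {}
    for host in annotation.genes:
        if host.biotype != "protein_coding" or not host.transcripts:
            continue
        for intron in coding_introns(host):
            if intron.length <= 1:
                continue
            trees.setdefault(host.scaffold, IntervalTree()).addi(
                intron.start, intron.end, (host, intron)
            )

    pairs: list[NestedPair] = []
    for nested in annotation.genes:
        tree = trees.get(nested.scaffold)
        if tree is None:
            continue
        if require_protein_coding and nested.biotype != "protein_coding":
            continue
        ns, ne = nested.span
        for hit in tree.overlap(ns, ne):
            host, intron = hit.data
            if host.gene_id == nested.gene_id:
                continue
            if not (ns > intron.start and ne < intron.end):
                continue  # strict containment only
            if require_different_strand and host.strand == nested.strand:
                continue
            if nested.transcripts:
                n_cds = len(nested.canonical_transcript().cds_segments)
            else:
                n_cds = 0
            pairs.append(
                NestedPair(
                    host_id=host.gene_id,
                    nested_id=nested.gene_id,
                    strand_relation=(
                        "different_strand"
                        if host.strand != nested.strand
                        else "same_strand"
                    ),
                    host_intron_index=intron.index,
                    host_intron_length=intron.length,
                    nested_coding_exon_count=n_cds,
                )
            )
    pairs.sort(key=lambda p: (p.host_id, p.nested_id))
    return pairs


def pair_metrics(pair: NestedPair, annotation: GenomeAnnotation) -> dict:
    """Per-pair report row: intron and nested gene sizes, intron index."""
    host = annotation.gene(pair.host_id)
    nested = annotation.gene(pair.nested_id)
    introns = {iv.index: iv for iv in coding_introns(host)}
    intron = introns[pair.host_intron_index]
    return {
        "host_id": host.gene_id,
        "nested_id": nested.gene_id,
        "host_intron_index": pair.host_intron_index,
        "host_intron_length": intron.length,
        "nested_gene_length": nested.length,
        "nested_coding_exon_count": pair.nested_coding_exon_count,
        "strand_relation": pair.strand_relation,
    }


def intron_metrics(
    annotation: GenomeAnnotation, host_id: str, intron_index: int
) -> dict:
    """Report on one coding intron of one gene, whether or not it hosts
    a nested gene (e.g. the unusually short 434 bp intron of clawed-frog
    *ctnna1*, which lost its nested gene)."""
    host = annotation.gene(host_id)
    intron = {iv.index: iv for iv in coding_introns(host)}[intron_index]
    nested_ids = sorted(
        g.gene_id
        for g in annotation.genes
        if g.gene_id != host_id
        and g.scaffold == host.scaffold
        and g.span[0] > intron.start
        and g.span[1] < intron.end
    )
    return {
        "host_id": host_id,
        "intron_index": intron_index,
        "intron_length": intron.length,
        "nested_gene_ids": nested_ids,
        "nested_present": bool(nested_ids),
    }


def pairs_table(pairs: list[NestedPair]) -> pd.DataFrame:
    """NestedPair list as a tidy DataFrame (one row per pair)."""
    columns = list(NestedPair.__dataclass_fields__)
    return pd.DataFrame([asdict(p) for p in pairs], columns=columns)
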
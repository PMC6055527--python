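"""Candidate alternative-junction discovery around somatic mutations.

An alternative junction is an intron inferred from spliced reads (CIGAR N
spans) whose nearer boundary lies within a window of the mutation, supported
by enough distinct high-mapping-quality fragments.  Candidates matching an
annotated intron or falling in HLA loci are then removed, and survivors are
annotated with the nearest canonical intron for downstream scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .alignments import AlignmentSource, fragment_name, read_introns, usable
from .intervals import GenomicInterval, boundary_distance
from .io import JunctionIndex, MutationRecord


@dataclass
class CandidateJunction:
    """An intron inferred from spliced reads near one mutation."""

    intron: GenomicInterval
    supporting_fragment_ids: frozenset
    distance_to_mutation: int
    is_canonical: bool = False
    nearest_canonical_intron: Optional[GenomicInterval] = None
    gene: Optional[str] = None

    @property
    def unique_read_support(self) -> int:
        return len(self.supporting_fragment_ids)

    def key(self) -> tuple:
        return (self.intron.chrom, self.intron.start, self.intron.end)


def discover_candidate_junctions(
    alignments: AlignmentSource,
    mutation: MutationRecord,
    window: int = 20,
    min_reads: int = 5,
    min_mapq: int = 20,
    exclude_duplicates: bool = True,
) -> list[CandidateJunction]:
    """All distinct introns whose nearer boundary is within ``window`` bp of
    the mutation, each supported by >= ``min_reads`` distinct fragments with
    mapping quality >= ``min_mapq``.

    Mates of one fragment are counted once; secondary/supplementary and
    (by default) duplicate-marked records are ignored.  Output is sorted by
    (chrom, start, end) so identical inputs give identical output.
    """
    if mutation.chrom not in alignments.references:
        raise ValueError(
            f"mutation contig {mutation.chrom!r} absent from "
            f"{alignments.original_path}"
        )
    pos0 = mutation.pos0
    # Any read spanning a junction with an in-window boundary aligns a base
    # within window+1 bp of the mutation, so this fetch region is sufficient.
    margin = window + 2
    support: dict[tuple[int, int], set] = {}
    for read in alignments.fetch(mutation.chrom, pos0 - margin, pos0 + margin + 1):
        if not usable(read, min_mapq, exclude_duplicates):
            continue
        for start, end in read_introns(read):
            if boundary_distance(mutation.pos, start, end) <= window:
                support.setdefault((start, end), set()).add(fragment_name(read))

    out = []
    for (start, end) in sorted(support):
        frags = support[(start, end)]
        if len(frags) < min_reads:
            continue
        out.append(
            CandidateJunction(
                intron=GenomicInterval(mutation.chrom, start, end),
                supporting_fragment_ids=frozenset(frags),
                distance_to_mutation=boundary_distance(mutation.pos, start, end),
            )
        )
    return out


def filter_canonical_and_hla(
    candidates: list[CandidateJunction],
    index: JunctionIndex,
    mutation: MutationRecord,
) -> list[CandidateJunction]:
    """Drop candidates that match an annotated intron exactly or overlap an
    HLA locus; annotate survivors with gene and nearest canonical intron.

    The nearest canonical intron prefers a same-gene intron sharing one
    boundary with the candidate (the cryptic-donor/acceptor geometry, where
    only one end moved), falling back to the nearest by boundary distance.
    """
    survivors = []
    for cand in candidates:
        iv = cand.intron
        if index.is_canonical(iv.chrom, iv.start, iv.end):
            survivors.append(replace(cand, is_canonical=True))
            continue
        if index.overlaps_hla(iv):
            continue
        genes = index.genes_at(mutation.chrom, mutation.pos0) or \
            index.genes_overlapping(iv.chrom, iv.start, iv.end)
        gene = mutation.gene if mutation.gene in index.gene_intervals else (
            genes[0] if genes else None
        )
        nearest = index.nearest_canonical(
            iv.chrom, iv.start, iv.end, genes=[gene] if gene else genes or None
        )
        survivors.append(
            replace(cand, gene=gene, nearest_canonical_intron=nearest)
        )
    return [c for c in survivors if not c.is_canonical]
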
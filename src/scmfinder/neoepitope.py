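"""Mutant-protein reconstruction and candidate neoepitope enumeration.

An alternative junction replaces the canonical intron in a transcript model;
the altered transcript is translated from the (possibly shifted) CDS start
to the first stop codon, giving in-frame deletions for frame-preserving
events and novel C-termini for frameshifts.  Candidate neoepitopes are all
8–11-mer windows of the mutant protein absent from the wild-type protein of
the same transcript; MHC binding affinity is consumed from a precomputed
external-predictor table (peptide, HLA allele, nM) rather than predicted
here, with peptides missing from the table retained as affinity-unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .intervals import GenomicInterval, reverse_complement, splice_with_intron
from .io import MutationRecord, ReferenceGenome

EPITOPE_LENGTHS = (8, 9, 10, 11)
DEFAULT_AFFINITY_NM = 500.0


@dataclass
class TranscriptModel:
    """Exon structure plus CDS location for one coding transcript.

    ``exons`` are genomic (start, end) pairs in genomic order; ``cds_start``
    and ``cds_end`` are genomic 0-based half-open bounds of the coding span.
    Minus-strand transcripts are translated on the reverse complement with
    exons traversed 3'->5' genomically.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list
    cds_start: int
    cds_end: Optional[int] = None
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons

    def spliced(self, seq_by_pos, exons: Optional[list] = None) -> str:
        exons = self.exons if exons is None else exons
        s = "".join(seq_by_pos(a, b) for a, b in exons)
        return reverse_complement(s) if self.strand == "-" else s

    def coding_exons(self, exons: Optional[list] = None) -> list:
        """Exon pieces restricted to [cds_start, cds_end)."""
        lo = self.cds_start
        hi = self.cds_end if self.cds_end is not None else float("inf")
        out = []
        for s, e in (self.exons if exons is None else exons):
            a, b = max(s, lo), min(e, hi)
            if a < b:
                out.append((a, b))
        return out


@dataclass(frozen=True)
class Epitope:
    sequence: str
    length: int
    position: int  # 0-based start in the mutant protein
    affinity_nm: Optional[float] = None
    allele: Optional[str] = None


@dataclass
class EpitopeSet:
    peptides: list
    novel_only: bool = True

    def sequences(self) -> set:
        return {e.sequence for e in self.peptides}

    def __len__(self) -> int:
        return len(self.peptides)


@dataclass
class MutantTranslation:
    protein: str
    wt_protein: str
    frameshift: bool
    note: Optional[str] = None


def _translate(cds: str) -> str:
    usable = cds[: len(cds) - len(cds) % 3]
    return str(Seq(usable).translate(to_stop=True))


def _genome_fetcher(ref: ReferenceGenome, chrom: str, mutation: Optional[MutationRecord]):
    """Plus-strand sequence accessor with the mutation substituted in
    (substitutions and simple exon-internal deletions; the junction change
    itself dominates the transcript effect for other shapes)."""

    def fetch(a: int, b: int) -> str:
        seq = ref.fetch(chrom, a, b, "+")
        if mutation is None or mutation.chrom != chrom:
            return seq
        if mutation.is_snv and a <= mutation.pos0 < b:
            off = mutation.pos0 - a
            return seq[:off] + mutation.alt_allele + seq[off + 1 :]
        if (
            mutation.alt_allele == "-"
            and a <= mutation.pos0
            and mutation.pos0 + len(mutation.ref_allele) <= b
        ):
            off = mutation.pos0 - a
            return seq[:off] + seq[off + len(mutation.ref_allele):]
        return seq

    return fetch


def translate_mutant(
    transcript: TranscriptModel,
    junction: GenomicInterval,
    mutation: Optional[MutationRecord],
    ref: ReferenceGenome,
) -> MutantTranslation:
    """Protein translated from the transcript with ``junction`` spliced in.

    The alternative intron supersedes whatever canonical splicing covered its
    span; translation runs from the CDS start to the first stop.  If the
    junction removes the CDS start, an empty protein is returned with the
    reason recorded.  A junction identical to a canonical intron reproduces
    the wild-type protein.
    """
    span_lo, span_hi = transcript.exons[0][0], transcript.exons[-1][1]
    if junction.chrom != transcript.chrom or not (
        span_lo <= junction.start and junction.end <= span_hi
    ):
        raise ValueError(
            f"junction {junction} outside transcript {transcript.transcript_id}"
        )
    wt_fetch = _genome_fetcher(ref, transcript.chrom, None)
    mut_fetch = _genome_fetcher(ref, transcript.chrom, mutation)

    wt_coding = transcript.coding_exons()
    wt_cds = transcript.spliced(wt_fetch, wt_coding)
    wt_protein = _translate(wt_cds)

    alt_exons = splice_with_intron(transcript.exons, (junction.start, junction.end))
    alt_coding = transcript.coding_exons(alt_exons)
    if transcript.strand == "-":
        start_kept = any(s <= transcript.cds_end - 1 < e for s, e in alt_exons) if transcript.cds_end else False
    else:
        start_kept = any(s <= transcript.cds_start < e for s, e in alt_exons)
    if not alt_coding or not start_kept:
        return MutantTranslation(
            protein="",
            wt_protein=wt_protein,
            frameshift=False,
            note="CDS start removed by alternative splicing",
        )
    mut_cds = transcript.spliced(mut_fetch, alt_coding)
    protein = _translate(mut_cds)
    wt_len = sum(e - s for s, e in wt_coding)
    mut_len = sum(e - s for s, e in alt_coding)
    frameshift = (wt_len - mut_len) % 3 != 0
    return MutantTranslation(
        protein=protein,
        wt_protein=wt_protein,
        frameshift=frameshift,
    )


def read_affinity_table(path) -> dict:
    """TSV with columns peptide, allele, affinity_nm -> {(peptide, allele): nM}."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str})
    required = {"peptide", "allele", "affinity_nm"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"affinity table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return {
        (row.peptide, row.allele): float(row.affinity_nm)
        for row in df.itertuples()
    }


def enumerate_novel_epitopes(
    mut_protein: str,
    wt_protein: str,
    lengths: Sequence[int] = EPITOPE_LENGTHS,
    affinity_table: Optional[Mapping] = None,
    threshold_nm: float = DEFAULT_AFFINITY_NM,
) -> EpitopeSet:
    """All windows of ``lengths`` from the mutant protein absent from the
    wild type, optionally filtered to predicted binders.

    With an affinity table, a peptide is kept when its best affinity across
    alleles is <= ``threshold_nm``; peptides absent from the table are kept
    with unknown affinity (the predictor simply has not seen them).
    """
    if not mut_protein or not wt_protein:
        raise ValueError("proteins must be non-empty")
    best: dict = {}
    if affinity_table:
        for (peptide, allele), nm in affinity_table.items():
            cur = best.get(peptide)
            if cur is None or nm < cur[0]:
                best[peptide] = (float(nm), allele)
    peptides = []
    for length in lengths:
        for i in range(len(mut_protein) - length + 1):
            window = mut_protein[i : i + length]
            if window in wt_protein:
                continue
            if affinity_table is not None and window in best:
                nm, allele = best[window]
                if nm > threshold_nm:
                    continue
                peptides.append(Epitope(window, length, i, nm, allele))
            else:
                peptides.append(Epitope(window, length, i))
    return EpitopeSet(peptides=peptides, novel_only=True)


def epitopes_to_dataframe(epitopes: EpitopeSet, event_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peptide": e.sequence,
                "length": e.length,
                "position": e.position,
                "affinity_nm": e.affinity_nm,
                "allele": e.allele,
                "event": event_id,
            }
            for e in epitopes.peptides
        ]
    )


def write_protein_fasta(proteins: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in proteins.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
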
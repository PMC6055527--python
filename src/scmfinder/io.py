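"""Readers and writers for mutation tables, annotation, and reference sequence.

Mutation tables are MAF-like TSV (MC3 column names by default, remappable via
a column map).  Annotation is GTF in the Ensembl attribute dialect
(``gene_name``, ``transcript_id``); it is digested into a
:class:`JunctionIndex` of canonical introns, gene intervals, and HLA loci.
Reference sequence comes from an indexed FASTA.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gffutils
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .intervals import GenomicInterval, reverse_complement

log = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^[ACGTN-]+$")


class MafError(ValueError):
    """A mutation table could not be read (missing columns, no valid rows)."""


class AnnotationError(ValueError):
    """The transcript annotation could not be digested."""


class VariantClass(str, Enum):
    MISSENSE = "missense"
    SILENT = "silent"
    SPLICE_SITE = "splice_site"
    NONSENSE = "nonsense"
    INDEL = "indel"
    NONCODING = "noncoding"
    OTHER = "other"


#: MAF Variant_Classification values -> internal class.  Values already in
#: internal form (e.g. from our own writer) map onto themselves.
VARIANT_CLASS_MAP = {
    "missense_mutation": VariantClass.MISSENSE,
    "missense": VariantClass.MISSENSE,
    "silent": VariantClass.SILENT,
    "synonymous": VariantClass.SILENT,
    "splice_site": VariantClass.SPLICE_SITE,
    "splice_region": VariantClass.SPLICE_SITE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "nonsense": VariantClass.NONSENSE,
    "nonstop_mutation": VariantClass.NONSENSE,
    "frame_shift_del": VariantClass.INDEL,
    "frame_shift_ins": VariantClass.INDEL,
    "in_frame_del": VariantClass.INDEL,
    "in_frame_ins": VariantClass.INDEL,
    "indel": VariantClass.INDEL,
    "3'utr": VariantClass.NONCODING,
    "5'utr": VariantClass.NONCODING,
    "3'flank": VariantClass.NONCODING,
    "5'flank": VariantClass.NONCODING,
    "intron": VariantClass.NONCODING,
    "igr": VariantClass.NONCODING,
    "rna": VariantClass.NONCODING,
    "noncoding": VariantClass.NONCODING,
    "other": VariantClass.OTHER,
}

#: Default column map for MC3-style MAF files: field name -> column header.
DEFAULT_MAF_COLUMNS = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "variant_class": "Variant_Classification",
    "t_ref_count": "t_ref_count",
    "t_alt_count": "t_alt_count",
}

_OPTIONAL_FIELDS = ("t_ref_count", "t_alt_count")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation from a MAF-like table.

    ``pos`` is the 1-based reference position of the first variant base, as in
    the input table; ``pos0`` gives the 0-based equivalent used internally.
    ``ref_allele``/``alt_allele`` use ``-`` for the empty side of a pure
    insertion or deletion.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass = VariantClass.OTHER
    t_ref_count: Optional[int] = None
    t_alt_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("ref_allele", "alt_allele"):
            allele = getattr(self, name)
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"{name} {allele!r} does not match [ACGTN-]+")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele equals alt_allele")
        for name in _OPTIONAL_FIELDS:
            count = getattr(self, name)
            if count is not None and count < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele != "-"
            and self.alt_allele != "-"
        )

    @property
    def dna_vaf(self) -> Optional[float]:
        if self.t_ref_count is None or self.t_alt_count is None:
            return None
        total = self.t_ref_count + self.t_alt_count
        return self.t_alt_count / total if total else None

    def key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref_allele, self.alt_allele)


def _parse_variant_class(raw: str) -> VariantClass:
    return VARIANT_CLASS_MAP.get(str(raw).strip().lower(), VariantClass.OTHER)


def _parse_count(raw) -> Optional[int]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip()
    if text in ("", ".", "NA", "nan", "None"):
        return None
    return int(float(text))


def _row_to_record(row: pd.Series, cols: dict) -> MutationRecord:
    kwargs = {
        "sample_id": str(row[cols["sample_id"]]),
        "gene": str(row[cols["gene"]]),
        "chrom": str(row[cols["chrom"]]),
        "pos": int(str(row[cols["pos"]]).strip()),
        "ref_allele": str(row[cols["ref_allele"]]).strip().upper(),
        "alt_allele": str(row[cols["alt_allele"]]).strip().upper(),
        "variant_class": _parse_variant_class(row[cols["variant_class"]]),
    }
    for name in _OPTIONAL_FIELDS:
        col = cols.get(name)
        if col is not None and col in row.index:
            kwargs[name] = _parse_count(row[col])
    rec = MutationRecord(**kwargs)
    vaf = rec.dna_vaf
    if vaf is not None and not (0.0 <= vaf <= 1.0):
        raise ValueError(f"DNA VAF {vaf} outside [0,1]")
    return rec


def read_mutations(
    path,
    column_map: Optional[dict] = None,
    errors: Optional[list] = None,
) -> list[MutationRecord]:
    """Read a MAF-like TSV into :class:`MutationRecord` objects.

    Rows violating the record invariants are skipped; a ``(row_index,
    message)`` diagnostic is appended to ``errors`` when a list is supplied
    (and logged either way).  Raises :class:`MafError` when a required column
    is missing, or when the file has rows but none parse.
    """
    cols = dict(DEFAULT_MAF_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = [cols[f] for f in cols if f not in _OPTIONAL_FIELDS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MafError(f"{path}: missing required column(s) {missing}")
    records: list[MutationRecord] = []
    n_bad = 0
    for idx, row in df.iterrows():
        try:
            records.append(_row_to_record(row, cols))
        except (ValueError, KeyError) as exc:
            n_bad += 1
            msg = f"row {idx}: {exc}"
            log.warning("%s: skipping %s", path, msg)
            if errors is not None:
                errors.append((int(idx), str(exc)))
    if len(df) and not records:
        raise MafError(f"{path}: no parseable mutation rows ({n_bad} rejected)")
    return records


def read_mutation_batches(
    path,
    batch_size: int = 200,
    column_map: Optional[dict] = None,
    errors: Optional[list] = None,
) -> Iterator[list[MutationRecord]]:
    """Yield mutations in chunks of at most ``batch_size`` records.

    Chunking mirrors how large cohort tables are split for batched
    processing; the default chunk of 200 mutations keeps per-batch alignment
    traffic bounded.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    records = read_mutations(path, column_map=column_map, errors=errors)
    for i in range(0, len(records), batch_size):
        yield records[i : i + batch_size]


def write_mutations(records: Iterable[MutationRecord], path) -> None:
    """Write records as MAF-like TSV (round-trips through read_mutations)."""
    cols = DEFAULT_MAF_COLUMNS
    rows = []
    for rec in records:
        rows.append(
            {
                cols["sample_id"]: rec.sample_id,
                cols["gene"]: rec.gene,
                cols["chrom"]: rec.chrom,
                cols["pos"]: rec.pos,
                cols["ref_allele"]: rec.ref_allele,
                cols["alt_allele"]: rec.alt_allele,
                cols["variant_class"]: rec.variant_class.value,
                cols["t_ref_count"]: rec.t_ref_count,
                cols["t_alt_count"]: rec.t_alt_count,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Junction index
# ---------------------------------------------------------------------------

#: Gene symbols beginning with this prefix are treated as HLA loci.  The
#: choice of symbol-prefix matching (rather than a fixed locus list) is a
#: config-visible convention.
HLA_GENE_PREFIX = "HLA-"


@dataclass
class JunctionIndex:
    """Canonical introns, gene extents, and HLA loci from an annotation.

    Canonical-intron lookup is exact on ``(chrom, start, end)`` and ignores
    strand; gene queries go through per-chromosome interval trees.
    """

    canonical_introns: set = field(default_factory=set)
    gene_intervals: dict = field(default_factory=dict)
    hla_intervals: list = field(default_factory=list)
    introns_by_gene: dict = field(default_factory=dict)
    _lookup: set = field(default_factory=set, repr=False)
    _gene_trees: dict = field(default_factory=dict, repr=False)

    def finalize(self) -> "JunctionIndex":
        self._lookup = {(c, s, e) for (c, s, e, _strand) in self.canonical_introns}
        self._gene_trees = {}
        for gene, iv in self.gene_intervals.items():
            tree = self._gene_trees.setdefault(iv.chrom, IntervalTree())
            tree[iv.start : iv.end] = gene
        return self

    def is_canonical(self, chrom: str, start: int, end: int) -> bool:
        return (chrom, start, end) in self._lookup

    def overlaps_hla(self, interval: GenomicInterval) -> bool:
        return any(interval.overlaps(h) for h in self.hla_intervals)

    def genes_at(self, chrom: str, pos0: int) -> list[str]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree[pos0])

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree[start:end])

    def gene_strand(self, gene: str) -> str:
        iv = self.gene_intervals.get(gene)
        return iv.strand if iv is not None else "."

    def nearest_canonical(
        self, chrom: str, start: int, end: int, genes: Optional[Iterable[str]] = None
    ) -> Optional[GenomicInterval]:
        """Closest canonical intron, preferring same-gene introns sharing a
        boundary with the query, then nearest by boundary distance."""
        if genes:
            pool = []
            for g in genes:
                for s, e in self.introns_by_gene.get(g, ()):
                    iv = self.gene_intervals[g]
                    if iv.chrom == chrom:
                        pool.append((s, e, iv.strand))
        else:
            pool = [
                (s, e, strand)
                for (c, s, e, strand) in self.canonical_introns
                if c == chrom
            ]
        if not pool:
            return None
        shared = [(s, e, st) for (s, e, st) in pool if s == start or e == end]
        candidates = shared if shared else pool

        def dist(entry):
            s, e, _ = entry
            return (min(abs(s - start), abs(e - end), abs(s - end), abs(e - start)), s, e)

        s, e, strand = min(candidates, key=dist)
        return GenomicInterval(chrom, s, e, strand)


def _create_gff_db(gtf_path):
    return gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )


def build_junction_index(gtf_path) -> JunctionIndex:
    """Digest a GTF into a :class:`JunctionIndex`.

    Every gap between consecutive exons of a transcript becomes one canonical
    intron (deduplicated across transcripts).  Transcripts with overlapping
    exons are skipped with a warning; an annotation with no exons is an error.
    """
    try:
        db = _create_gff_db(gtf_path)
    except gffutils.exceptions.EmptyInputError as exc:
        raise AnnotationError(f"{gtf_path}: empty annotation") from exc
    by_transcript: dict[str, list] = {}
    tx_meta: dict[str, tuple] = {}
    n_exons = 0
    for feat in db.features_of_type("exon"):
        n_exons += 1
        tx = feat.attributes.get("transcript_id", [None])[0]
        gene = (
            feat.attributes.get("gene_name", [None])[0]
            or feat.attributes.get("gene_id", [None])[0]
            or "?"
        )
        if tx is None:
            log.warning("exon without transcript_id at %s:%s-%s skipped",
                        feat.seqid, feat.start, feat.end)
            continue
        by_transcript.setdefault(tx, []).append((feat.start - 1, feat.end))
        tx_meta[tx] = (feat.seqid, gene, feat.strand)
    if n_exons == 0:
        raise AnnotationError(f"{gtf_path}: annotation contains no exon features")

    index = JunctionIndex()
    gene_bounds: dict[str, list] = {}
    for tx, exons in by_transcript.items():
        chrom, gene, strand = tx_meta[tx]
        exons = sorted(exons)
        overlapping = any(
            exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)
        )
        if overlapping:
            log.warning("transcript %s has overlapping exons; skipped", tx)
            continue
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 < s2:
                index.canonical_introns.add((chrom, e1, s2, strand))
                index.introns_by_gene.setdefault(gene, set()).add((e1, s2))
        bounds = gene_bounds.setdefault(gene, [chrom, exons[0][0], exons[-1][1], strand])
        bounds[1] = min(bounds[1], exons[0][0])
        bounds[2] = max(bounds[2], exons[-1][1])

    for gene, (chrom, start, end, strand) in gene_bounds.items():
        iv = GenomicInterval(chrom, start, end, strand)
        index.gene_intervals[gene] = iv
        if gene.startswith(HLA_GENE_PREFIX):
            index.hla_intervals.append(iv)
    index.introns_by_gene = {
        g: sorted(s) for g, s in index.introns_by_gene.items()
    }
    return index.finalize()


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------


class ReferenceGenome:
    """Indexed-FASTA access with strand-aware fetches."""

    def __init__(self, path):
        self.path = str(path)
        self._fa = pysam.FastaFile(self.path)

    @property
    def contigs(self) -> tuple:
        return tuple(self._fa.references)

    def contig_length(self, chrom: str) -> int:
        if chrom not in self._fa.references:
            raise KeyError(f"unknown contig {chrom!r}")
        return self._fa.get_reference_length(chrom)

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        length = self.contig_length(chrom)
        if start < 0 or end > length or start >= end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} out of bounds (contig length {length})"
            )
        seq = self._fa.fetch(chrom, start, end).upper()
        return reverse_complement(seq) if strand == "-" else seq

    def close(self) -> None:
        self._fa.close()


def fetch_sequence(ref: ReferenceGenome, interval: GenomicInterval, strand: Optional[str] = None) -> str:
    """Uppercase sequence of ``interval``; minus strand reverse-complements."""
    use = strand if strand is not None else interval.strand
    if use == ".":
        use = "+"
    return ref.fetch(interval.chrom, interval.start, interval.end, use)


def ensure_faidx(path) -> str:
    """Create a FASTA index alongside ``path`` if absent; return the path."""
    path = str(path)
    if not Path(path + ".fai").exists():
        pysam.faidx(path)
    return path
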
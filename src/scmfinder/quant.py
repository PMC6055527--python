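"""Junction allele fraction (JAF), spliced-in JAF, and splice-in/out class.

JAF is the fraction of fragments at the junction locus that span the
alternative junction.  "The locus" is anchored at the exonic base
immediately adjacent to the junction boundary nearer the mutation; the
denominator counts deduplicated fragments with an aligned base or an N skip
at that anchor, so JAF behaves as a local exon-inclusion fraction.  The
spliced-in JAF is, among alternative-junction fragments, the fraction whose
reads carry the mutant allele — defined only for splice-in events whose
mutation is reachable by junction-supporting fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .alignments import (
    AlignmentSource,
    anchor_coverage,
    base_at,
    fragment_name,
    read_introns,
    usable,
)
from .intervals import GenomicInterval
from .io import MutationRecord

SPLICE_IN = "splice_in"
SPLICE_OUT = "splice_out"


def classify_in_out(junction: GenomicInterval, mutation: MutationRecord) -> str:
    """splice_out when the mutation base lies inside the new intron
    (half-open: first intronic base in, first exonic base after the intron
    out); splice_in otherwise (mutation retained in the new exon)."""
    return (
        SPLICE_OUT
        if junction.start <= mutation.pos0 < junction.end
        else SPLICE_IN
    )


def junction_anchor(junction: GenomicInterval, mutation: MutationRecord) -> int:
    """0-based position of the exonic base flanking the junction boundary
    nearer the mutation."""
    d_start = abs(mutation.pos - junction.start)
    d_end = abs(mutation.pos - junction.end)
    return junction.start - 1 if d_start <= d_end else junction.end


@dataclass
class JunctionQuant:
    """Per-(sample, junction) usage quantification."""

    alt_junction_reads: int
    locus_depth: int
    jaf: Optional[float]
    anchor0: int
    filtered: bool = False
    filter_reason: Optional[str] = None
    in_out: Optional[str] = None
    spliced_in_reads_with_mut: Optional[int] = None
    spliced_in_jaf: Optional[float] = None


def compute_jaf(
    alignments: AlignmentSource,
    junction: GenomicInterval,
    mutation: MutationRecord,
    min_mapq: int = 20,
    jaf_min: float = 0.05,
    exclude_duplicates: bool = True,
) -> JunctionQuant:
    """JAF at the anchor base; events below ``jaf_min`` are marked filtered."""
    anchor0 = junction_anchor(junction, mutation)
    covering, supporting = anchor_coverage(
        alignments,
        junction.chrom,
        anchor0,
        junction=(junction.start, junction.end),
        min_mapq=min_mapq,
        exclude_duplicates=exclude_duplicates,
    )
    depth = len(covering)
    alt = len(supporting)
    if depth == 0:
        return JunctionQuant(
            alt_junction_reads=0,
            locus_depth=0,
            jaf=None,
            anchor0=anchor0,
            filtered=True,
            filter_reason="no coverage at junction locus",
            in_out=classify_in_out(junction, mutation),
        )
    jaf = alt / depth
    quant = JunctionQuant(
        alt_junction_reads=alt,
        locus_depth=depth,
        jaf=jaf,
        anchor0=anchor0,
        in_out=classify_in_out(junction, mutation),
    )
    if jaf < jaf_min:
        quant.filtered = True
        quant.filter_reason = f"jaf {jaf:.4f} < {jaf_min}"
    return quant


def spliced_in_jaf(
    alignments: AlignmentSource,
    junction: GenomicInterval,
    mutation: MutationRecord,
    min_mapq: int = 20,
    exclude_duplicates: bool = True,
) -> tuple[Optional[float], Optional[int], Optional[int]]:
    """(fraction, n_with_mut, n_junction_fragments) for a splice-in event.

    The numerator counts junction-supporting fragments with a read aligning
    the alternate allele over the mutation base; the denominator is all
    junction-supporting fragments.  Returns ``(None, None, n)`` when no
    junction fragment reaches the mutation (undefined rather than zero: at
    long mutation-junction distances the fragment simply cannot observe
    both), and ``None`` throughout for non-SNV mutations, whose allele cannot
    be read off a single aligned base.
    """
    if classify_in_out(junction, mutation) != SPLICE_IN:
        raise ValueError("spliced-in JAF is defined only for splice-in events")
    if not mutation.is_snv:
        return None, None, None
    pos0 = mutation.pos0
    lo = min(junction.start - 1, pos0)
    hi = max(junction.end + 1, pos0 + 1)
    by_fragment: dict[str, dict] = {}
    for read in alignments.fetch(junction.chrom, lo, hi):
        if not usable(read, min_mapq, exclude_duplicates):
            continue
        rec = by_fragment.setdefault(
            fragment_name(read), {"supports": False, "allele": None}
        )
        if (junction.start, junction.end) in read_introns(read):
            rec["supports"] = True
        allele = base_at(read, pos0)
        if allele is not None:
            rec["allele"] = allele
    junction_frags = {k: v for k, v in by_fragment.items() if v["supports"]}
    n_junction = len(junction_frags)
    observed = {k: v for k, v in junction_frags.items() if v["allele"] is not None}
    if not observed:
        return None, None, n_junction
    n_mut = sum(1 for v in junction_frags.values() if v["allele"] == mutation.alt_allele)
    return n_mut / n_junction, n_mut, n_junction
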
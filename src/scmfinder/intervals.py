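"""Genomic interval primitives and the package-wide coordinate convention.

All internal coordinates are 0-based, half-open.  Mutation tables (MAF-like,
1-based inclusive) are converted at the I/O boundary.  An intron is identified
by ``(chrom, start, end)`` where ``start`` is the first intronic base and
``end`` is one past the last intronic base; a CIGAR ``N`` span maps onto this
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


def splice_with_intron(exons, intron):
    """Exon chain after splicing with ``intron`` in place of whatever
    canonical intron(s) covered that span.

    ``exons``: [(start, end)] in genomic order; ``intron``: (start, end) or
    None for the unmodified chain.  Canonical gaps overlapped by the new
    intron are first exonified (the new intron supersedes them), then the new
    intron is cut out — this handles alternative boundaries on either side of
    the canonical ones.
    """
    if intron is None:
        return [tuple(x) for x in exons]
    segs = sorted(tuple(x) for x in exons)
    filled = [list(segs[0])]
    for s, e in segs[1:]:
        gap = (filled[-1][1], s)
        if intron[0] < gap[1] and gap[0] < intron[1]:
            filled[-1][1] = e
        else:
            filled.append([s, e])
    out = []
    a0, a1 = intron
    for s, e in filled:
        if e <= a0 or s >= a1:
            out.append((s, e))
        else:
            if s < a0:
                out.append((s, a0))
            if e > a1:
                out.append((a1, e))
    return out


def boundary_distance(pos1: int, start: int, end: int) -> int:
    """Distance in bp from a mutation to the nearer boundary of an intron.

    ``pos1`` is the 1-based mutation coordinate; ``start``/``end`` are the
    half-open intron coordinates.  Numerically this measures from the mutation
    base to the reference base immediately 5' of each splice point (the last
    exonic base for the start boundary, the last intronic base for the end
    boundary), which anchors the +/- window on the mutation the way splice
    regions are conventionally counted.
    """
    return min(abs(pos1 - start), abs(pos1 - end))
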
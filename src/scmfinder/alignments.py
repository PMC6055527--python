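"""Region-queryable access to spliced alignments.

Inputs may be SAM text or BAM.  Region queries need a coordinate-sorted,
indexed file, so SAM (and unindexed BAM) inputs are converted once into a
sorted, indexed BAM in a temporary cache that lives for the process.  All
read-level filtering rules shared by discovery, quantification, and control
counting live here: mapping-quality threshold, exclusion of secondary,
supplementary, unmapped and (by default) duplicate-marked records, and
fragment-level deduplication by query name so a mate pair is counted once.
"""

from __future__ import annotations

import atexit
import shutil
import tempfile
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

_CACHE_DIR: Optional[str] = None
_PREPARED: dict = {}


def _cache_dir() -> str:
    global _CACHE_DIR
    if _CACHE_DIR is None:
        _CACHE_DIR = tempfile.mkdtemp(prefix="scmfinder-aln-")
        atexit.register(shutil.rmtree, _CACHE_DIR, ignore_errors=True)
    return _CACHE_DIR


def prepare_alignments(path) -> str:
    """Return the path of a sorted, indexed BAM equivalent to ``path``.

    SAM input is sorted and indexed into the process cache; BAM input is
    indexed in place if possible, otherwise cached likewise.  Conversion is
    memoized on (resolved path, mtime).
    """
    src = Path(path).resolve()
    if not src.exists():
        raise FileNotFoundError(str(src))
    key = (str(src), src.stat().st_mtime_ns)
    hit = _PREPARED.get(key)
    if hit is not None:
        return hit
    if src.suffix == ".bam" and Path(str(src) + ".bai").exists():
        _PREPARED[key] = str(src)
        return str(src)
    out = str(Path(_cache_dir()) / f"{len(_PREPARED):05d}_{src.stem}.bam")
    pysam.sort("-o", out, str(src))
    pysam.index(out)
    _PREPARED[key] = out
    return out


class AlignmentSource:
    """One sample's spliced alignments, opened for region queries."""

    def __init__(self, path, sample_id: Optional[str] = None):
        self.original_path = str(path)
        self.path = prepare_alignments(path)
        self.sample_id = sample_id or Path(self.original_path).stem
        self._af = pysam.AlignmentFile(self.path, "rb")

    @property
    def references(self) -> tuple:
        return tuple(self._af.references)

    def fetch(self, chrom: str, start: int, end: int) -> Iterator:
        if chrom not in self._af.references:
            raise ValueError(
                f"contig {chrom!r} absent from alignments {self.original_path}"
            )
        return self._af.fetch(chrom, max(0, start), end)

    def close(self) -> None:
        self._af.close()

    def __repr__(self) -> str:
        return f"AlignmentSource({self.sample_id!r}, {self.original_path!r})"


def as_source(obj) -> AlignmentSource:
    return obj if isinstance(obj, AlignmentSource) else AlignmentSource(obj)


def usable(read, min_mapq: int, exclude_duplicates: bool = True) -> bool:
    """Shared read-level eligibility rule for all counting operations."""
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if exclude_duplicates and read.is_duplicate:
        return False
    return read.mapping_quality >= min_mapq


def read_introns(read) -> list[tuple[int, int]]:
    """Half-open reference spans of every CIGAR N operation in ``read``."""
    spans = []
    pos = read.reference_start
    for op, length in read.cigartuples or ():
        if op == 3:  # N
            spans.append((pos, pos + length))
        if op in (0, 2, 3, 7, 8):  # consumes reference: M, D, N, =, X
            pos += length
    return spans


def fragment_name(read) -> str:
    return read.query_name


def junction_support(
    source: AlignmentSource,
    chrom: str,
    start: int,
    end: int,
    min_mapq: int = 20,
    exclude_duplicates: bool = True,
) -> set[str]:
    """Names of distinct fragments with an N span exactly matching the intron."""
    frags: set[str] = set()
    for read in source.fetch(chrom, start, start + 1):
        if not usable(read, min_mapq, exclude_duplicates):
            continue
        if (start, end) in read_introns(read):
            frags.add(fragment_name(read))
    return frags


def anchor_coverage(
    source: AlignmentSource,
    chrom: str,
    anchor0: int,
    junction: Optional[tuple[int, int]] = None,
    min_mapq: int = 20,
    exclude_duplicates: bool = True,
) -> tuple[set[str], set[str]]:
    """Fragments covering the anchor base, split into (all, junction-supporting).

    A fragment covers the anchor when any of its reads has an aligned base
    there or skips across it with an N span; it is junction-supporting when
    any of its reads carries an N span equal to ``junction``.
    """
    covering: set[str] = set()
    supporting: set[str] = set()
    for read in source.fetch(chrom, anchor0, anchor0 + 1):
        if not usable(read, min_mapq, exclude_duplicates):
            continue
        name = fragment_name(read)
        if _touches(read, anchor0):
            covering.add(name)
        if junction is not None and junction in read_introns(read):
            supporting.add(name)
    # A junction-supporting read always aligns exon bases flanking the intron,
    # so supporting fragments are a subset of covering fragments; enforce it.
    supporting &= covering
    return covering, supporting


def _touches(read, pos0: int) -> bool:
    """True if the read has an aligned base or an N span at ``pos0``."""
    ref = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 3, 7, 8):  # M, N, =, X
            if ref <= pos0 < ref + length:
                return True
        if op in (0, 2, 3, 7, 8):
            ref += length
    return False


def base_at(read, pos0: int) -> Optional[str]:
    """The read base aligned at reference position ``pos0``, if any."""
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            seq = read.query_sequence
            return seq[qpos].upper() if seq else None
    return None
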
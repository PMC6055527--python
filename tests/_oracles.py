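"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's alignment/statistics code paths:
SAM records are re-parsed from text with a regex CIGAR walk, quantiles are
recomputed by sorting and rank search, and factorized splice scores are
recomputed by direct table arithmetic.
"""

import math
import re

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_n_spans(pos0: int, cigar: str) -> list:
    spans = []
    ref = pos0
    for length, op in _CIGAR_RE.findall(cigar):
        length = int(length)
        if op == "N":
            spans.append((ref, ref + length))
        if op in "MDN=X":
            ref += length
    return spans


def bruteforce_candidates(
    sam_path: str,
    chrom: str,
    pos1: int,
    window: int = 20,
    min_reads: int = 5,
    min_mapq: int = 20,
) -> dict:
    """(intron_start, intron_end) -> unique fragment support, from raw SAM text."""
    support: dict = {}
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            qname, flag, rname = fields[0], int(fields[1]), fields[2]
            pos0, mapq, cigar = int(fields[3]) - 1, int(fields[4]), fields[5]
            if rname != chrom or cigar == "*":
                continue
            if flag & (0x4 | 0x100 | 0x400 | 0x800):
                continue
            if mapq < min_mapq:
                continue
            for s, e in cigar_n_spans(pos0, cigar):
                if min(abs(pos1 - s), abs(pos1 - e)) <= window:
                    support.setdefault((s, e), set()).add(qname)
    return {k: len(v) for k, v in support.items() if len(v) >= min_reads}


def quantile_by_rank_search(counts, q: float) -> int:
    """Smallest order statistic whose rank exceeds q*n (clamped to the max)."""
    ordered = sorted(counts)
    n = len(ordered)
    rank = 1
    while rank <= n and rank <= q * n:
        rank += 1
    rank = min(rank, n)
    return ordered[rank - 1]


def score_by_table_arithmetic(kmer: str, model) -> float:
    """Recompute a splice score straight from the raw model dictionaries."""
    pc = model.pseudocount
    cons = "".join(kmer[i] for i in model.consensus_positions)
    if cons in model.consensus_probs:
        mp, bp = model.consensus_probs[cons]
    else:
        mp, bp = 0.0, math.prod(model.background[b] for b in cons)
    total = math.log2(mp + pc) - math.log2(bp + pc)
    for table in model.tables:
        sub = "".join(kmer[i] for i in table.positions)
        p = table.probs.get(sub, 0.0)
        q_bg = math.prod(model.background[b] for b in sub)
        total += table.sign * (math.log2(p + pc) - math.log2(q_bg + pc))
    return total
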
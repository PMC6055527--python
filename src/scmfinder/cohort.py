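"""Control-cohort support counts, percentile thresholds, and verdicts.

For each candidate junction, supporting-read counts are tallied across a
cohort of control samples (same cancer cohort, lacking a mutation in the
gene of interest) using the same fragment-dedup and mapping-quality rules as
case discovery.  The empirical 5%/95% thresholds of that frequency
distribution drive two decisions: the top-5% case filter (the case sample's
support must exceed the 95th percentile, or, when the junction is entirely
unseen in controls, simply reach the discovery support minimum), and a
per-sample expression verdict (no_expression / low / average / high).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .alignments import AlignmentSource, junction_support
from .intervals import GenomicInterval


class Verdict(str, Enum):
    NO_EXPRESSION = "no_expression"
    LOW = "low"
    AVERAGE = "average"
    HIGH = "high"


def nearest_rank_quantile(counts: Sequence[int], q: float) -> int:
    """Empirical quantile without interpolation.

    Returns the order statistic at 0-based index ``floor(q*n)``, clamped to
    the last element — i.e. the smallest value whose rank exceeds ``q*n``.
    Control counts are small integers, so interpolation would fabricate
    thresholds no sample ever shows.
    """
    if not counts:
        raise ValueError("empty count multiset")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile {q} outside [0,1]")
    ordered = sorted(counts)
    idx = min(int(math.floor(q * len(ordered))), len(ordered) - 1)
    return ordered[idx]


@dataclass(frozen=True)
class ControlStats:
    """Distribution of one junction's support across control samples."""

    counts: tuple
    q05: int
    q95: int

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("ControlStats needs at least one control sample")
        if not (min(self.counts) <= self.q05 <= self.q95 <= max(self.counts)):
            raise ValueError("quantiles must lie within the observed counts")

    @property
    def n_controls(self) -> int:
        return len(self.counts)

    @property
    def all_zero(self) -> bool:
        return max(self.counts) == 0

    @classmethod
    def from_counts(
        cls, counts: Iterable[int], low: float = 0.05, high: float = 0.95
    ) -> "ControlStats":
        counts = tuple(int(c) for c in counts)
        if any(c < 0 for c in counts):
            raise ValueError("negative control count")
        return cls(
            counts=counts,
            q05=nearest_rank_quantile(counts, low),
            q95=nearest_rank_quantile(counts, high),
        )


def control_support_counts(
    junction: GenomicInterval,
    control_alignments: Sequence[AlignmentSource],
    min_mapq: int = 20,
    exclude_duplicates: bool = True,
    low: float = 0.05,
    high: float = 0.95,
) -> ControlStats:
    """Per-control unique-fragment support for ``junction`` -> ControlStats.

    Raises ``ValueError`` on an empty control set: the filter cannot be
    evaluated without at least one control sample.
    """
    if not control_alignments:
        raise ValueError("control cohort is empty; cannot evaluate filter")
    counts = []
    for src in control_alignments:
        if junction.chrom not in src.references:
            counts.append(0)
            continue
        frags = junction_support(
            src,
            junction.chrom,
            junction.start,
            junction.end,
            min_mapq=min_mapq,
            exclude_duplicates=exclude_duplicates,
        )
        counts.append(len(frags))
    return ControlStats.from_counts(counts, low=low, high=high)


def case_passes_top5(
    case_count: int, stats: ControlStats, min_reads: int = 5
) -> bool:
    """Case support must strictly exceed the controls' 95th percentile.

    When no control shows the junction at all, the percentile is degenerate
    (q95 = 0) and any case support at the discovery minimum already separates
    the case from the entire cohort, so the test reduces to
    ``case_count >= min_reads``.
    """
    if case_count < 0:
        raise ValueError("case_count must be non-negative")
    if stats.all_zero:
        return case_count >= min_reads
    return case_count > stats.q95


def expression_verdict(count: int, stats: ControlStats) -> Verdict:
    """Classify one sample's junction support against the control cohort."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if stats.q05 == 0 and stats.q95 == 0 and count == 0:
        return Verdict.NO_EXPRESSION
    if count > stats.q95:
        return Verdict.HIGH
    if count < stats.q05:
        return Verdict.LOW
    return Verdict.AVERAGE
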
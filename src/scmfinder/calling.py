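"""Per-mutation orchestration of the full calling workflow, review rules,
recurrence aggregation, and tabular output.

For each mutation: discover candidate junctions near the mutation, drop
annotated and HLA junctions, quantify junction usage (JAF filter), compare
case support against the control cohort (top-5% filter), score the created
and nearest canonical splice sites, and classify splice-in/out.  Review is
rule-based: a mutation with exactly one surviving junction is a Pass, with
more than one is Complex (multiple alternative products), and with none is
NoSupport.  Every input mutation lands exactly once in the calls or the
audit trail, with the first failing filter recorded per candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .alignments import AlignmentSource, as_source
from .cohort import (
    ControlStats,
    Verdict,
    case_passes_top5,
    control_support_counts,
    expression_verdict,
)
from .discovery import (
    CandidateJunction,
    discover_candidate_junctions,
    filter_canonical_and_hla,
)
from .intervals import GenomicInterval
from .io import JunctionIndex, MutationRecord, ReferenceGenome
from .quant import JunctionQuant, compute_jaf, spliced_in_jaf
from .scoring import (
    ACCEPTOR,
    DONOR,
    ScorePair,
    SpliceModel,
    UNSCOREABLE,
    compare_scores,
)

log = logging.getLogger(__name__)

PASS = "Pass"
COMPLEX = "Complex"
NO_SUPPORT = "NoSupport"


@dataclass
class PipelineConfig:
    """Tunable thresholds of the calling workflow (defaults are the
    discovery settings the method is defined with)."""

    window: int = 20
    min_reads: int = 5
    min_mapq: int = 20
    jaf_min: float = 0.05
    low_quantile: float = 0.05
    top_quantile: float = 0.95
    batch_size: int = 200
    exclude_duplicates: bool = True
    control_scope: str = "gene"  # or "site": which samples count as controls
    flag_homologous: bool = False
    homologous_mapq: int = 50
    homologous_max_fraction: float = 0.5

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """key=value config file mirroring the CLI flags."""
        kwargs: dict = {}
        casts = {f.name: type(getattr(cls(), f.name)) for f in cls.__dataclass_fields__.values()}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in casts:
                    raise ValueError(f"unknown config key {key!r}")
                typ = casts[key]
                kwargs[key] = (val.lower() in ("1", "true", "yes")) if typ is bool else typ(val)
        return cls(**kwargs)


@dataclass
class JunctionCallDetail:
    """Everything measured for one surviving (mutation, junction) pair."""

    junction: CandidateJunction
    quant: JunctionQuant
    control: ControlStats
    verdict: Verdict
    score_alt: Optional[ScorePair] = None
    score_canonical: Optional[ScorePair] = None
    preference_class: str = UNSCOREABLE
    minus3_context: Optional[str] = None
    homology_flagged: bool = False

    @property
    def distance_same_as_canonical(self) -> Optional[int]:
        """bp offset between the created boundary and its canonical twin."""
        near = self.junction.nearest_canonical_intron
        if near is None:
            return None
        iv = self.junction.intron
        return min(abs(iv.start - near.start), abs(iv.end - near.end))


@dataclass
class SCMCall:
    """A mutation with at least one junction surviving all filters."""

    mutation: MutationRecord
    details: list
    review: str

    @property
    def junction(self) -> CandidateJunction:
        return self.details[0].junction


@dataclass
class AuditRecord:
    """Why a mutation produced no call (or why candidates were dropped)."""

    mutation: MutationRecord
    review: str
    reasons: list  # [(junction key or None, reason)]

    @property
    def first_reason(self) -> str:
        return self.reasons[0][1] if self.reasons else "no candidate junction"


@dataclass
class CallSet:
    calls: list
    audit: list

    def passes(self) -> list:
        return [c for c in self.calls if c.review == PASS]


def _control_samples_for(
    mutation: MutationRecord,
    control_sources: Mapping[str, AlignmentSource],
    mutations_by_sample: Mapping[str, list],
    scope: str,
) -> list:
    """Controls are cohort samples lacking the mutation — at gene level by
    default (any mutation in the same gene disqualifies), or at site level
    (only the identical variant disqualifies)."""
    out = []
    for sample_id, src in control_sources.items():
        if sample_id == mutation.sample_id:
            continue
        muts = mutations_by_sample.get(sample_id, ())
        if scope == "gene":
            clash = any(m.gene == mutation.gene for m in muts)
        else:
            clash = any(
                (m.chrom, m.pos, m.ref_allele, m.alt_allele)
                == (mutation.chrom, mutation.pos, mutation.ref_allele, mutation.alt_allele)
                for m in muts
            )
        if not clash:
            out.append(src)
    return out


def _created_side(
    junction: GenomicInterval, mutation: MutationRecord, strand: str
) -> tuple[str, int, str]:
    """(site kind, boundary coordinate, boundary end) of the created site —
    the junction boundary nearer the mutation."""
    d_start = abs(mutation.pos - junction.start)
    d_end = abs(mutation.pos - junction.end)
    boundary_end = "start" if d_start <= d_end else "end"
    boundary = junction.start if boundary_end == "start" else junction.end
    if strand == "-":
        side = ACCEPTOR if boundary_end == "start" else DONOR
    else:
        side = DONOR if boundary_end == "start" else ACCEPTOR
    return side, boundary, boundary_end


def _homology_fraction(
    source: AlignmentSource, cand: CandidateJunction, config: PipelineConfig
) -> float:
    """Fraction of junction-supporting fragments mapping below a high
    mapping-quality bar; a large fraction hints at a highly homologous
    region where junction evidence is unreliable."""
    from .alignments import junction_support

    iv = cand.intron
    all_frags = junction_support(
        source, iv.chrom, iv.start, iv.end, min_mapq=config.min_mapq,
        exclude_duplicates=config.exclude_duplicates,
    )
    confident = junction_support(
        source, iv.chrom, iv.start, iv.end, min_mapq=config.homologous_mapq,
        exclude_duplicates=config.exclude_duplicates,
    )
    if not all_frags:
        return 0.0
    return 1.0 - len(confident) / len(all_frags)


def call_scms(
    mutations: Sequence[MutationRecord],
    case_alignments: Mapping[str, object],
    control_alignments: Mapping[str, object],
    index: JunctionIndex,
    models: Mapping[str, SpliceModel],
    ref: ReferenceGenome,
    config: Optional[PipelineConfig] = None,
) -> CallSet:
    """Run the full workflow over ``mutations``.

    ``case_alignments`` / ``control_alignments`` map sample id to an
    alignment path or :class:`AlignmentSource`.  Per-mutation failures are
    isolated into the audit trail; broken global inputs raise.
    """
    config = config or PipelineConfig()
    case_sources = {k: as_source(v) for k, v in case_alignments.items()}
    control_sources = {k: as_source(v) for k, v in control_alignments.items()}
    mutations_by_sample: dict = {}
    for m in mutations:
        mutations_by_sample.setdefault(m.sample_id, []).append(m)

    calls: list = []
    audit: list = []
    control_cache: dict = {}
    for mutation in mutations:
        try:
            result = _call_one(
                mutation,
                case_sources,
                control_sources,
                mutations_by_sample,
                index,
                models,
                ref,
                config,
                control_cache,
            )
        except Exception as exc:  # noqa: BLE001 - per-mutation isolation
            log.exception("mutation %s failed", mutation.key())
            audit.append(
                AuditRecord(mutation, NO_SUPPORT, [(None, f"error: {exc}")])
            )
            continue
        if isinstance(result, SCMCall):
            calls.append(result)
        else:
            audit.append(result)
    return CallSet(calls=calls, audit=audit)


def _call_one(
    mutation,
    case_sources,
    control_sources,
    mutations_by_sample,
    index,
    models,
    ref,
    config,
    control_cache,
):
    source = case_sources.get(mutation.sample_id)
    if source is None:
        return AuditRecord(
            mutation, NO_SUPPORT, [(None, "no alignments for sample")]
        )
    candidates = discover_candidate_junctions(
        source,
        mutation,
        window=config.window,
        min_reads=config.min_reads,
        min_mapq=config.min_mapq,
        exclude_duplicates=config.exclude_duplicates,
    )
    reasons: list = []
    if not candidates:
        return AuditRecord(mutation, NO_SUPPORT, [(None, "no candidate junction")])

    survivors = filter_canonical_and_hla(candidates, index, mutation)
    surviving_keys = {c.key() for c in survivors}
    for cand in candidates:
        if cand.key() not in surviving_keys:
            iv = cand.intron
            why = (
                "canonical junction"
                if index.is_canonical(iv.chrom, iv.start, iv.end)
                else "HLA locus"
            )
            reasons.append((cand.key(), why))

    details: list = []
    for cand in survivors:
        quant = compute_jaf(
            source,
            cand.intron,
            mutation,
            min_mapq=config.min_mapq,
            jaf_min=config.jaf_min,
            exclude_duplicates=config.exclude_duplicates,
        )
        if quant.filtered:
            reasons.append((cand.key(), quant.filter_reason))
            continue
        controls = _control_samples_for(
            mutation, control_sources, mutations_by_sample, config.control_scope
        )
        if not controls:
            reasons.append((cand.key(), "empty control cohort"))
            continue
        cache_key = (cand.key(), tuple(sorted(s.sample_id for s in controls)))
        stats = control_cache.get(cache_key)
        if stats is None:
            stats = control_support_counts(
                cand.intron,
                controls,
                min_mapq=config.min_mapq,
                exclude_duplicates=config.exclude_duplicates,
                low=config.low_quantile,
                high=config.top_quantile,
            )
            control_cache[cache_key] = stats
        case_count = cand.unique_read_support
        if not case_passes_top5(case_count, stats, min_reads=config.min_reads):
            reasons.append(
                (cand.key(), f"control cohort expresses junction (q95={stats.q95})")
            )
            continue
        detail = JunctionCallDetail(
            junction=cand,
            quant=quant,
            control=stats,
            verdict=expression_verdict(case_count, stats),
        )
        _annotate_scores(detail, mutation, index, models, ref)
        if quant.in_out == "splice_in":
            frac, n_mut, _n = spliced_in_jaf(
                source, cand.intron, mutation,
                min_mapq=config.min_mapq,
                exclude_duplicates=config.exclude_duplicates,
            )
            quant.spliced_in_jaf = frac
            quant.spliced_in_reads_with_mut = n_mut
        if config.flag_homologous:
            frac = _homology_fraction(source, cand, config)
            detail.homology_flagged = frac > config.homologous_max_fraction
        details.append(detail)

    if not details:
        return AuditRecord(mutation, NO_SUPPORT, reasons)
    review = PASS if len(details) == 1 else COMPLEX
    return SCMCall(mutation=mutation, details=details, review=review)


def _annotate_scores(detail, mutation, index, models, ref):
    cand = detail.junction
    near = cand.nearest_canonical_intron
    if near is None:
        return
    strand = near.strand if near.strand != "." else (
        index.gene_strand(cand.gene) if cand.gene else "+"
    )
    if strand == ".":
        strand = "+"
    side, alt_boundary, boundary_end = _created_side(
        cand.intron, mutation, strand
    )
    canonical_boundary = near.start if boundary_end == "start" else near.end
    alt_pair, can_pair, preference = compare_scores(
        side,
        cand.intron.chrom,
        alt_boundary,
        canonical_boundary,
        strand,
        mutation,
        ref,
        models,
    )
    detail.score_alt = alt_pair
    detail.score_canonical = can_pair
    detail.preference_class = preference
    if side == ACCEPTOR and alt_pair is not None:
        from .scoring import classify_minus3_context, extract_site_kmers

        pair = extract_site_kmers(
            side, cand.intron.chrom, alt_boundary, strand, ref, mutation
        )
        if pair.mut_kmer is not None:
            context, _label = classify_minus3_context(pair.ref_kmer, pair.mut_kmer)
            detail.minus3_context = context


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass
class RecurrenceTable:
    """Gene-level recurrence, annotation-class breakdown, and clusters of
    nearby mutations creating the same junction."""

    gene_counts: dict
    class_breakdown: dict
    clusters: list  # [ (gene, intron key, [mutation keys]) ] with >= 2 members
    per_cancer_type: Optional[pd.DataFrame] = None
    summary: dict = field(default_factory=dict)


def review_and_aggregate(
    calls: Iterable[SCMCall],
    sample_metadata: Optional[Mapping[str, str]] = None,
    cluster_bp: int = 5,
) -> RecurrenceTable:
    """Aggregate Pass calls: per-gene counts, conventional-annotation
    breakdown, clusters of mutations within +/- ``cluster_bp`` bp creating
    the identical alternative intron, and an optional gene x cancer-type
    matrix from sample metadata."""
    passes = [c for c in calls if c.review == PASS]
    gene_counts: dict = {}
    class_breakdown: dict = {}
    by_junction: dict = {}
    for call in passes:
        gene = call.mutation.gene
        gene_counts[gene] = gene_counts.get(gene, 0) + 1
        cls = call.mutation.variant_class.value
        class_breakdown[cls] = class_breakdown.get(cls, 0) + 1
        by_junction.setdefault((gene, call.junction.key()), []).append(call.mutation)

    clusters = []
    for (gene, jkey), muts in by_junction.items():
        if len(muts) < 2:
            continue
        ordered = sorted(muts, key=lambda m: m.pos)
        block = [ordered[0]]
        for m in ordered[1:]:
            if m.pos - block[-1].pos <= cluster_bp:
                block.append(m)
            else:
                if len(block) >= 2:
                    clusters.append((gene, jkey, [b.key() for b in block]))
                block = [m]
        if len(block) >= 2:
            clusters.append((gene, jkey, [b.key() for b in block]))

    per_type = None
    if sample_metadata is not None:
        rows = [
            {
                "gene": c.mutation.gene,
                "cancer_type": sample_metadata.get(c.mutation.sample_id, "NA"),
            }
            for c in passes
        ]
        if rows:
            per_type = (
                pd.DataFrame(rows)
                .value_counts()
                .unstack(fill_value=0)
            )
    n_genes = len(gene_counts)
    multi = sum(1 for v in gene_counts.values() if v >= 2)
    summary = {
        "n_pass": len(passes),
        "n_genes": n_genes,
        "n_genes_multi": multi,
        "n_clusters": len(clusters),
    }
    return RecurrenceTable(
        gene_counts=gene_counts,
        class_breakdown=class_breakdown,
        clusters=clusters,
        per_cancer_type=per_type,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def calls_to_dataframe(callset: CallSet) -> pd.DataFrame:
    rows = []
    for call in callset.calls:
        for detail in call.details:
            m = call.mutation
            iv = detail.junction.intron
            rows.append(
                {
                    "sample": m.sample_id,
                    "gene": m.gene,
                    "chrom": m.chrom,
                    "pos": m.pos,
                    "ref": m.ref_allele,
                    "alt": m.alt_allele,
                    "variant_class": m.variant_class.value,
                    "review": call.review,
                    "intron_start": iv.start,
                    "intron_end": iv.end,
                    "support": detail.junction.unique_read_support,
                    "distance": detail.junction.distance_to_mutation,
                    "jaf": detail.quant.jaf,
                    "spliced_in_jaf": detail.quant.spliced_in_jaf,
                    "in_out": detail.quant.in_out,
                    "depth": detail.quant.locus_depth,
                    "control_q95": detail.control.q95,
                    "n_controls": detail.control.n_controls,
                    "verdict": detail.verdict.value,
                    "alt_ref_score": getattr(detail.score_alt, "ref_score", None),
                    "alt_mut_score": getattr(detail.score_alt, "mut_score", None),
                    "canonical_ref_score": getattr(detail.score_canonical, "ref_score", None),
                    "canonical_mut_score": getattr(detail.score_canonical, "mut_score", None),
                    "preference_class": detail.preference_class,
                    "minus3_context": detail.minus3_context,
                    "homology_flagged": detail.homology_flagged,
                }
            )
    return pd.DataFrame(rows)


def audit_to_dataframe(callset: CallSet) -> pd.DataFrame:
    rows = []
    for rec in callset.audit:
        m = rec.mutation
        rows.append(
            {
                "sample": m.sample_id,
                "gene": m.gene,
                "chrom": m.chrom,
                "pos": m.pos,
                "review": rec.review,
                "first_reason": rec.first_reason,
                "all_reasons": "; ".join(
                    f"{k}:{r}" if k else r for k, r in rec.reasons
                ),
            }
        )
    return pd.DataFrame(rows)


def write_calls_tsv(callset: CallSet, path) -> None:
    calls_to_dataframe(callset).to_csv(path, sep="\t", index=False)


def write_audit_tsv(callset: CallSet, path) -> None:
    audit_to_dataframe(callset).to_csv(path, sep="\t", index=False)


def write_junctions_bed12(callset: CallSet, path) -> None:
    """BED12 of alternative junctions: one record per surviving junction,
    two 1 bp blocks at the flanking exonic bases, score = supporting reads."""
    with open(path, "w") as fh:
        for call in callset.calls:
            for detail in call.details:
                iv = detail.junction.intron
                chrom_start = iv.start - 1
                chrom_end = iv.end + 1
                name = f"{call.mutation.gene}|{call.mutation.sample_id}|{call.review}"
                score = min(1000, detail.junction.unique_read_support)
                block_starts = f"0,{iv.end - chrom_start}"
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            iv.chrom,
                            chrom_start,
                            chrom_end,
                            name,
                            score,
                            ".",
                            chrom_start,
                            chrom_end,
                            "0,0,0",
                            2,
                            "1,1",
                            block_starts,
                        )
                    )
                    + "\n"
                )
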
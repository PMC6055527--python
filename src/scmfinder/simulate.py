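"""Self-contained synthetic test worlds with declared splicing truth.

A world is a mini-genome of multi-exon genes (canonical GT donors / AG
acceptors), a matching GTF, a mutation table, and per-sample spliced
paired-end SAM alignments.  Each truth event embeds a mutation that creates
or strengthens an alternative splice site with a declared junction allele
fraction (JAF), depth, and control-cohort layout, covering the canonical
geometries: an exonic mutation strengthening a cryptic donor (splice-in), a
-3 acceptor change in an aGag repeat creating a junction 2 nt from the
canonical one (splice-out), an intronic +3 donor change (splice-out), and an
in-frame 30 nt donor-shortening event in a coding gene.  Decoy genes carry
mutations with no splicing effect, including some placed next to canonical
junctions to exercise the annotation filter.

Reads are error-free by default: junction discovery is CIGAR-driven, so
base noise only matters for allele-aware quantities, and an optional
substitution-error rate exercises those.  Alignments are emitted as SAM
text for diffability; the alignment layer sorts/indexes on demand.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .intervals import splice_with_intron
from .io import MutationRecord, VariantClass, ensure_faidx, write_mutations

DEFAULT_EVENT_KINDS = (
    "donor_exonic",
    "acceptor_minus3",
    "donor_intronic",
    "inframe_del",
)

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

_ALT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}


class GenerationError(ValueError):
    """Requested world parameters cannot be embedded."""


# ---------------------------------------------------------------------------
# World description
# ---------------------------------------------------------------------------


@dataclass
class SimGene:
    name: str
    chrom: str
    strand: str
    exons: list  # [(start, end)] 0-based half-open, genomic order
    cds_start: Optional[int] = None  # genomic, 0-based
    wt_protein: Optional[str] = None

    @property
    def introns(self) -> list:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def span(self) -> tuple:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class TruthEvent:
    """One injected splice-site-creating mutation and its ground truth."""

    event_id: str
    kind: str
    sample: str
    gene: str
    chrom: str
    mutation_pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    variant_class: str
    canonical_intron: tuple
    alternative_intron: tuple
    in_out: str
    anchor0: int
    true_jaf: float
    depth: int
    n_controls: int
    control_contamination: float

    def mutation_record(self) -> MutationRecord:
        t_alt = max(1, round(60 * min(self.true_jaf, 1.0) / 2))
        return MutationRecord(
            sample_id=self.sample,
            gene=self.gene,
            chrom=self.chrom,
            pos=self.mutation_pos,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            variant_class=VariantClass(self.variant_class),
            t_ref_count=60 - t_alt,
            t_alt_count=t_alt,
        )


@dataclass
class DecoyMutation:
    sample: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    near_canonical: bool = False

    def mutation_record(self) -> MutationRecord:
        return MutationRecord(
            sample_id=self.sample,
            gene=self.gene,
            chrom=self.chrom,
            pos=self.pos,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            variant_class=VariantClass.MISSENSE,
            t_ref_count=40,
            t_alt_count=20,
        )


@dataclass
class WorldParams:
    """Study-condition knobs for one synthetic world.

    Defaults mirror the discovery setting the pipeline is built for: deep
    junction coverage (100 fragments at the locus), an alternative junction
    used by half the transcripts, and a modest mutation-free control cohort.
    """

    n_events: int = 4
    event_kinds: Optional[Sequence[str]] = None  # cycled over DEFAULT_EVENT_KINDS
    jafs: Sequence[float] = (0.5,)
    depth: int = 100
    n_cases: int = 1
    n_controls: int = 10
    control_contamination: float = 0.0
    control_depth: int = 50
    n_decoy_genes: int = 0
    decoys_per_gene: int = 0
    decoy_depth: int = 40
    exon_lengths: Sequence[int] = (300, 240, 300)
    intron_lengths: Sequence[int] = (120, 130)
    intergenic: int = 300
    chrom: str = "chrS"


@dataclass
class World:
    outdir: str
    genome_path: str
    gtf_path: str
    maf_path: str
    manifest_path: str
    chrom: str
    contig_seq: str
    genes: list
    events: list
    decoys: list
    case_samples: list
    control_samples: list
    control_depth: int = 50
    decoy_depth: int = 40

    @property
    def canonical_introns(self) -> set:
        out = set()
        for g in self.genes:
            for s, e in g.introns:
                out.add((g.chrom, s, e, g.strand))
        return out

    def gene(self, name: str) -> SimGene:
        return next(g for g in self.genes if g.name == name)

    def mutations(self) -> list:
        recs = [e.mutation_record() for e in self.events]
        recs += [d.mutation_record() for d in self.decoys]
        return recs


# ---------------------------------------------------------------------------
# Truth-set generation
# ---------------------------------------------------------------------------


def _splice_segments(exons: list, alt_intron: Optional[tuple]) -> list:
    return splice_with_intron(exons, alt_intron)


def _spliced_sequence(seq: str, segments: list) -> str:
    return "".join(seq[s:e] for s, e in segments)


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate(to_stop=True))
    return prot


def generate_truth_set(params: WorldParams, seed: int, outdir) -> World:
    """Build a deterministic world under ``outdir`` (FASTA/GTF/MAF/manifest).

    Event kinds are cycled, JAFs are cycled, and events are dealt round-robin
    to case samples.  Raises :class:`GenerationError` when the geometry cannot
    be embedded (e.g. an alternative intron that would not fit its exon).
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kinds = list(params.event_kinds or DEFAULT_EVENT_KINDS)
    if params.n_events < 0 or params.n_cases < 1 or params.n_controls < 0:
        raise GenerationError("invalid cohort sizes")
    exon_lens = list(params.exon_lengths)
    intron_lens = list(params.intron_lengths)
    if len(intron_lens) != len(exon_lens) - 1:
        raise GenerationError("need one fewer intron length than exon lengths")
    if min(intron_lens) < 20:
        raise GenerationError("alternative/canonical introns shorter than 20 nt")

    n_genes = params.n_events + params.n_decoy_genes
    gene_len = sum(exon_lens) + sum(intron_lens)
    total = params.intergenic + n_genes * (gene_len + params.intergenic)
    seq = list("".join(rng.choice(list("ACGT"), size=total)))

    genes: list = []
    events: list = []
    decoys: list = []
    case_samples = [f"case{i + 1:02d}" for i in range(params.n_cases)]
    control_samples = [f"control{i + 1:02d}" for i in range(params.n_controls)]

    cursor = params.intergenic
    for gi in range(n_genes):
        start = cursor
        cursor += gene_len + params.intergenic
        exons = []
        p = start
        for ei, el in enumerate(exon_lens):
            exons.append((p, p + el))
            p += el
            if ei < len(intron_lens):
                p += intron_lens[ei]
        is_event_gene = gi < params.n_events
        name = f"GENE{gi + 1:03d}" if is_event_gene else f"DECOY{gi - params.n_events + 1:03d}"
        gene = SimGene(name=name, chrom=params.chrom, strand="+", exons=exons)
        # canonical splice dinucleotides
        for (d, a) in gene.introns:
            seq[d], seq[d + 1] = "G", "T"
            seq[a - 2], seq[a - 1] = "A", "G"
        if is_event_gene:
            kind = kinds[gi % len(kinds)]
            jaf = params.jafs[gi % len(params.jafs)]
            sample = case_samples[gi % len(case_samples)]
            event = _embed_event(
                seq, gene, kind, gi, sample, jaf, params
            )
            events.append(event)
        else:
            # decoy mutations: interior exonic plus one near the canonical donor
            d, a = gene.introns[0]
            positions = []
            interior = list(range(exons[0][0] + 60, d - 60, 7))
            n_interior = max(0, params.decoys_per_gene - 1)
            positions.extend((p0, False) for p0 in interior[:n_interior])
            if params.decoys_per_gene > 0:
                positions.append((d - 10, True))  # within the +/-20 bp window
            for p0, near in positions[: params.decoys_per_gene]:
                ref = seq[p0]
                decoys.append(
                    DecoyMutation(
                        sample="",  # assigned below
                        gene=name,
                        chrom=params.chrom,
                        pos=p0 + 1,
                        ref_allele=ref,
                        alt_allele=_ALT_BASE[ref],
                        near_canonical=near,
                    )
                )
        genes.append(gene)

    for i, dec in enumerate(decoys):
        dec.sample = case_samples[i % len(case_samples)]

    contig = "".join(seq)

    # ---- write files ----
    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        fh.write(f">{params.chrom}\n")
        for i in range(0, len(contig), 60):
            fh.write(contig[i : i + 60] + "\n")
    ensure_faidx(genome_path)

    gtf_path = outdir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        for g in genes:
            for s, e in g.exons:
                attrs = (
                    f'gene_id "{g.name}"; gene_name "{g.name}"; '
                    f'transcript_id "{g.name}.t1";'
                )
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )

    world = World(
        outdir=str(outdir),
        genome_path=str(genome_path),
        gtf_path=str(gtf_path),
        maf_path=str(outdir / "mutations.maf"),
        manifest_path=str(outdir / "truth.json"),
        chrom=params.chrom,
        contig_seq=contig,
        genes=genes,
        events=events,
        decoys=decoys,
        case_samples=case_samples,
        control_samples=control_samples,
        control_depth=params.control_depth,
        decoy_depth=params.decoy_depth,
    )
    write_mutations(world.mutations(), world.maf_path)
    _write_manifest(world)
    _check_world(world)
    return world


def _embed_event(
    seq: list, gene: SimGene, kind: str, gi: int, sample: str, jaf: float, params: WorldParams
) -> TruthEvent:
    if not 0.0 < jaf <= 1.0:
        raise GenerationError(f"true_jaf {jaf} outside (0,1]")
    d, a = gene.introns[0]
    exon1_start = gene.exons[0][0]
    common = dict(
        event_id=f"ev{gi + 1:03d}",
        kind=kind,
        sample=sample,
        gene=gene.name,
        chrom=gene.chrom,
        canonical_intron=(d, a),
        true_jaf=jaf,
        depth=params.depth,
        n_controls=params.n_controls,
        control_contamination=params.control_contamination,
    )
    if kind in ("donor_exonic", "inframe_del"):
        delta = 12 if kind == "donor_exonic" else 30
        dp = d - delta
        if dp - 3 <= exon1_start:
            raise GenerationError("alternative donor does not fit in exon")
        seq[dp], seq[dp + 1] = "G", "T"  # pre-existing cryptic GT
        seq[dp - 3 : dp] = list("CTG")
        if kind == "donor_exonic":
            # strengthen the exonic donor context: CTG -> CAG at -2
            pos0, ref, alt, vclass = dp - 2, "T", "A", "missense"
        else:
            # truly silent third-codon-position change: CTG -> CTA (Leu)
            pos0, ref, alt, vclass = dp - 1, "G", "A", "silent"
            _make_coding(seq, gene, dp)
        event = TruthEvent(
            mutation_pos=pos0 + 1,
            ref_allele=ref,
            alt_allele=alt,
            variant_class=vclass,
            alternative_intron=(dp, a),
            in_out="splice_in",
            anchor0=dp - 1,
            **common,
        )
    elif kind == "acceptor_minus3":
        # reference a,G,a,g at alternative-acceptor -4..-1; G>C at -3 kills the
        # canonical AG and activates the acceptor 2 nt downstream
        seq[a - 2 : a + 2] = list("AGAG")
        event = TruthEvent(
            mutation_pos=a,  # 1-based of 0-based a-1
            ref_allele="G",
            alt_allele="C",
            variant_class="splice_site",
            alternative_intron=(d, a + 2),
            in_out="splice_out",
            anchor0=a + 2,
            **common,
        )
    elif kind == "donor_intronic":
        dp = d - 9
        if dp - 3 <= exon1_start:
            raise GenerationError("alternative donor does not fit in exon")
        seq[dp], seq[dp + 1] = "G", "T"
        seq[dp + 2] = "C"
        event = TruthEvent(
            mutation_pos=dp + 3,  # intron +3 of the new intron
            ref_allele="C",
            alt_allele="A",
            variant_class="missense",
            alternative_intron=(dp, a),
            in_out="splice_out",
            anchor0=dp - 1,
            **common,
        )
    else:
        raise GenerationError(f"unknown event kind {kind!r}")
    return event


def _make_coding(seq: list, gene: SimGene, dp: int) -> None:
    """Give ``gene`` a CDS in frame with the alternative donor at ``dp``."""
    exon1_start = gene.exons[0][0]
    cds_start = exon1_start + 30 + ((dp - (exon1_start + 30)) % 3)
    segments = _splice_segments(gene.exons, None)
    tx_positions = [p for s, e in segments for p in range(s, e)]
    i0 = tx_positions.index(cds_start)
    coding_positions = tx_positions[i0:]
    n_codons = len(coding_positions) // 3 - 4  # leave room for the stop
    rng = np.random.default_rng(zlib.crc32(gene.name.encode()) % (2**31))
    for ci in range(n_codons):
        codon = "ATG" if ci == 0 else _NONSTOP_CODONS[
            int(rng.integers(len(_NONSTOP_CODONS)))
        ]
        for k in range(3):
            seq[coding_positions[3 * ci + k]] = codon[k]
    stop_positions = coding_positions[3 * n_codons : 3 * n_codons + 3]
    for k, b in enumerate("TAA"):
        seq[stop_positions[k]] = b
    # re-assert the cryptic-donor motif clobbered by the codon fill
    seq[dp], seq[dp + 1] = "G", "T"
    seq[dp - 3 : dp] = list("CTG")
    gene.cds_start = cds_start
    gene.wt_protein = _translate("".join(seq[p] for p in coding_positions))


def _check_world(world: World) -> None:
    from .intervals import boundary_distance

    for ev in world.events:
        s, e = ev.alternative_intron
        if (s, e) == tuple(ev.canonical_intron):
            raise GenerationError("alternative intron equals canonical intron")
        if e - s < 20:
            raise GenerationError("alternative intron shorter than 20 nt")
        if boundary_distance(ev.mutation_pos, s, e) > 20:
            raise GenerationError("mutation farther than 20 bp from its junction")
        ref = world.contig_seq[ev.mutation_pos - 1]
        if ref != ev.ref_allele:
            raise GenerationError(
                f"{ev.event_id}: reference base {ref} != declared {ev.ref_allele}"
            )


def _write_manifest(world: World) -> None:
    payload = {
        "chrom": world.chrom,
        "case_samples": world.case_samples,
        "control_samples": world.control_samples,
        "genes": [
            {
                "name": g.name,
                "chrom": g.chrom,
                "strand": g.strand,
                "exons": g.exons,
                "cds_start": g.cds_start,
                "wt_protein": g.wt_protein,
            }
            for g in world.genes
        ],
        "events": [asdict(e) for e in world.events],
        "decoys": [asdict(d) for d in world.decoys],
    }
    with open(world.manifest_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class CoverageUnit:
    """A block of fragments anchored on one locus in one sample."""

    unit_id: str
    gene: str
    anchor0: int
    depth: int
    jaf: float = 0.0
    alt_intron: Optional[tuple] = None
    mapq: int = 60
    jaf_mode: str = "binomial"  # or "exact"


def _personal_sequence(world: World, sample: str) -> str:
    seq = list(world.contig_seq)
    for ev in world.events:
        if ev.sample == sample and len(ev.ref_allele) == 1 and len(ev.alt_allele) == 1:
            seq[ev.mutation_pos - 1] = ev.alt_allele
    for dec in world.decoys:
        if dec.sample == sample:
            seq[dec.pos - 1] = dec.alt_allele
    return "".join(seq)


def _path_coord(segments: list, g: int) -> int:
    t = 0
    for s, e in segments:
        if s <= g < e:
            return t + (g - s)
        t += e - s
    raise GenerationError(f"position {g} not exonic in path {segments}")


def _read_blocks(segments: list, t_start: int, length: int) -> list:
    blocks = []
    t = 0
    remaining = length
    for s, e in segments:
        seg_len = e - s
        if t + seg_len <= t_start:
            t += seg_len
            continue
        offset = max(0, t_start - t)
        take = min(seg_len - offset, remaining)
        if take > 0:
            blocks.append((s + offset, take))
            remaining -= take
        t += seg_len
        if remaining == 0:
            break
    if remaining:
        raise GenerationError("read extends past transcript end")
    return blocks


def _cigar(blocks: list) -> str:
    parts = []
    for i, (s, ln) in enumerate(blocks):
        if i:
            gap = s - (blocks[i - 1][0] + blocks[i - 1][1])
            parts.append(f"{gap}N")
        parts.append(f"{ln}M")
    return "".join(parts)


def default_units(world: World, rng: np.random.Generator) -> dict:
    """sample -> [CoverageUnit] for the world's declared cohort design.

    Cases get their events at the declared JAF and coverage over their decoy
    loci; controls get canonical-only coverage at every event locus except
    where the contamination draw puts the alternative junction in a control.
    """
    units: dict = {s: [] for s in world.case_samples + world.control_samples}
    for ev in world.events:
        units[ev.sample].append(
            CoverageUnit(
                unit_id=ev.event_id,
                gene=ev.gene,
                anchor0=ev.anchor0,
                depth=ev.depth,
                jaf=ev.true_jaf,
                alt_intron=tuple(ev.alternative_intron),
            )
        )
        for ctrl in world.control_samples:
            contaminated = (
                ev.control_contamination > 0
                and rng.random() < ev.control_contamination
            )
            units[ctrl].append(
                CoverageUnit(
                    unit_id=f"{ev.event_id}.{ctrl}",
                    gene=ev.gene,
                    anchor0=ev.anchor0,
                    depth=max(1, world.control_depth),
                    jaf=ev.true_jaf if contaminated else 0.0,
                    alt_intron=tuple(ev.alternative_intron) if contaminated else None,
                )
            )
    for dec in world.decoys:
        units[dec.sample].append(
            CoverageUnit(
                unit_id=f"decoy.{dec.gene}.{dec.pos}",
                gene=dec.gene,
                anchor0=dec.pos - 1,
                depth=world.decoy_depth,
                jaf=0.0,
            )
        )
    return units


def simulate_alignments(
    world: World,
    outdir,
    seed: int,
    units: Optional[dict] = None,
    read_len: int = 100,
    fragment_len: int = 250,
    base_error_rate: float = 0.0,
    junction_overhang: int = 8,
) -> dict:
    """Write one coordinate-sorted SAM per sample; return sample -> path.

    Every fragment of a unit covers its anchor base with read 1; the fragment
    follows the alternative transcript with probability ``jaf`` (or an exact
    count under ``jaf_mode='exact'``), in which case read 1 spans the new
    junction with at least ``junction_overhang`` matched bases on each side.
    Reads take their sequence from the sample's personal genome, so
    mutation-bearing samples emit mutant alleles on the alternative junction
    reads.
    """
    if fragment_len < read_len:
        raise GenerationError("fragment shorter than read")
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    units = units if units is not None else default_units(world, rng)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": world.chrom, "LN": len(world.contig_seq)}],
    }
    paths = {}
    for sample in sorted(units):
        personal = _personal_sequence(world, sample)
        records = []
        for unit in units[sample]:
            records.extend(
                _unit_reads(
                    world, unit, sample, personal, rng, read_len, fragment_len,
                    base_error_rate, junction_overhang,
                )
            )
        records.sort(key=lambda r: (r["pos"], r["qname"], r["flag"]))
        path = outdir / f"{sample}.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for rec in records:
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = rec["qname"]
                seg.flag = rec["flag"]
                seg.reference_id = 0
                seg.reference_start = rec["pos"]
                seg.mapping_quality = rec["mapq"]
                seg.cigarstring = rec["cigar"]
                seg.next_reference_id = 0
                seg.next_reference_start = rec["pnext"]
                seg.template_length = rec["tlen"]
                seg.query_sequence = rec["seq"]
                seg.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(rec["seq"])
                )
                out.write(seg)
        paths[sample] = str(path)
    return paths


def _unit_reads(
    world: World,
    unit: CoverageUnit,
    sample: str,
    personal: str,
    rng: np.random.Generator,
    read_len: int,
    fragment_len: int,
    base_error_rate: float,
    overhang: int,
) -> list:
    gene = world.gene(unit.gene)
    can_segs = _splice_segments(gene.exons, None)
    alt_segs = (
        _splice_segments(gene.exons, unit.alt_intron) if unit.alt_intron else None
    )
    if unit.jaf > 0 and alt_segs is None:
        raise GenerationError("jaf > 0 requires an alternative intron")
    if unit.jaf_mode == "exact":
        n_alt = round(unit.jaf * unit.depth)
    else:
        n_alt = int(rng.binomial(unit.depth, unit.jaf)) if unit.jaf > 0 else 0

    records = []
    for i in range(unit.depth):
        is_alt = i < n_alt
        segs = alt_segs if is_alt else can_segs
        pathlen = sum(e - s for s, e in segs)
        t_a = _path_coord(segs, unit.anchor0)
        lo = max(0, t_a - read_len + 1)
        hi = min(t_a, pathlen - fragment_len)
        if is_alt:
            t_j = _path_coord(segs, unit.alt_intron[1])  # first base after junction
            lo = max(lo, t_j + overhang - read_len)
            hi = min(hi, t_j - overhang)
        if lo > hi:
            raise GenerationError(
                f"unit {unit.unit_id}: cannot place read over anchor "
                f"(lo={lo} > hi={hi})"
            )
        start1 = int(rng.integers(lo, hi + 1))
        start2 = start1 + fragment_len - read_len
        if start2 + read_len > pathlen:
            start2 = pathlen - read_len
        qname = f"{sample}.{unit.unit_id}.{i}"
        blocks1 = _read_blocks(segs, start1, read_len)
        blocks2 = _read_blocks(segs, start2, read_len)
        seq1 = "".join(personal[s : s + ln] for s, ln in blocks1)
        seq2 = "".join(personal[s : s + ln] for s, ln in blocks2)
        if base_error_rate > 0:
            seq1 = _with_errors(seq1, rng, base_error_rate)
            seq2 = _with_errors(seq2, rng, base_error_rate)
        pos1, pos2 = blocks1[0][0], blocks2[0][0]
        end2 = blocks2[-1][0] + blocks2[-1][1]
        records.append(
            {
                "qname": qname,
                "flag": 99,
                "pos": pos1,
                "mapq": unit.mapq,
                "cigar": _cigar(blocks1),
                "pnext": pos2,
                "tlen": end2 - pos1,
                "seq": seq1,
            }
        )
        records.append(
            {
                "qname": qname,
                "flag": 147,
                "pos": pos2,
                "mapq": unit.mapq,
                "cigar": _cigar(blocks2),
                "pnext": pos1,
                "tlen": -(end2 - pos1),
                "seq": seq2,
            }
        )
    return records


def _with_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _ALT_BASE[out[i]]
    return "".join(out)


# ---------------------------------------------------------------------------
# Hand-crafted SAM files for precise boundary fixtures
# ---------------------------------------------------------------------------


class SamBuilder:
    """Build small SAM files with exact read placement and flags."""

    def __init__(self, contigs: dict):
        """``contigs``: name -> length or name -> sequence."""
        self.contigs = {
            name: (len(v) if isinstance(v, str) else int(v))
            for name, v in contigs.items()
        }
        self.seqs = {
            name: v for name, v in contigs.items() if isinstance(v, str)
        }
        self.reads: list = []

    def add_read(
        self,
        name: str,
        chrom: str,
        blocks: list,
        mapq: int = 60,
        flag: Optional[int] = None,
        duplicate: bool = False,
        secondary: bool = False,
        mate: Optional[int] = None,
        seq: Optional[str] = None,
    ) -> "SamBuilder":
        """``blocks``: [(ref_start, length), ...] in genomic order; gaps
        between blocks become N operations."""
        f = 0 if flag is None else flag
        if mate == 1:
            f |= 0x1 | 0x40
        elif mate == 2:
            f |= 0x1 | 0x80 | 0x10
        if duplicate:
            f |= 0x400
        if secondary:
            f |= 0x100
        total = sum(ln for _, ln in blocks)
        if seq is None:
            contig_seq = self.seqs.get(chrom)
            if contig_seq:
                seq = "".join(contig_seq[s : s + ln] for s, ln in blocks)
            else:
                seq = "A" * total
        self.reads.append(
            {
                "qname": name,
                "flag": f,
                "chrom": chrom,
                "pos": blocks[0][0],
                "mapq": mapq,
                "cigar": _cigar(blocks),
                "seq": seq,
            }
        )
        return self

    def add_spliced_fragment(
        self,
        name: str,
        chrom: str,
        intron: tuple,
        flank: int = 30,
        mapq: int = 60,
        **kw,
    ) -> "SamBuilder":
        s, e = intron
        return self.add_read(
            name, chrom, [(s - flank, flank), (e, flank)], mapq=mapq, **kw
        )

    def write(self, path) -> str:
        names = list(self.contigs)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": self.contigs[n]} for n in names],
        }
        reads = sorted(self.reads, key=lambda r: (names.index(r["chrom"]), r["pos"]))
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for rec in reads:
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = rec["qname"]
                seg.flag = rec["flag"]
                seg.reference_id = names.index(rec["chrom"])
                seg.reference_start = rec["pos"]
                seg.mapping_quality = rec["mapq"]
                seg.cigarstring = rec["cigar"]
                seg.query_sequence = rec["seq"]
                seg.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(rec["seq"])
                )
                out.write(seg)
        return str(path)
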
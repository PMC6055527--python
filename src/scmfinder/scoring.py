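"""Maximum-entropy-style splice-site scoring of reference vs mutant k-mers.

A donor site is scored on a 9-mer (3 exonic + 6 intronic bases) and an
acceptor on a 23-mer (20 intronic + 3 exonic bases).  A model factorizes the
k-mer probability into (a) the intronic consensus dinucleotide (donor +1/+2,
acceptor -2/-1), scored by consensus frequencies, and (b) a product/ratio of
probability tables over sub-windows of the remaining positions — the same
shape of factorization used by maximum-entropy splice models, so both a full
joint table (donor-style) and overlapping sub-model ratios (acceptor-style)
are expressible.  The score is log2(P_model / P_background) in bits.

Models live in a plain-text format (one block per table) so miniature test
models can be built programmatically and published model tables can be
converted in offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence

from .intervals import GenomicInterval, reverse_complement
from .io import MutationRecord, ReferenceGenome

DONOR = "donor"
ACCEPTOR = "acceptor"

#: k-mer geometry per site kind: (kmer_length, exonic bases 5' of the splice
#: point for donors / 3' for acceptors, consensus k-mer indices).
DONOR_KMER_LEN = 9
ACCEPTOR_KMER_LEN = 23
DONOR_EXONIC = 3          # donor k-mer = 3 exonic + 6 intronic
ACCEPTOR_INTRONIC = 20    # acceptor k-mer = 20 intronic + 3 exonic
DONOR_CONSENSUS = (3, 4)       # intron +1,+2 (GT)
ACCEPTOR_CONSENSUS = (18, 19)  # intron -2,-1 (AG)

_BASES = "ACGT"


class UnscoreableKmer(ValueError):
    """The k-mer cannot be scored (non-ACGT base such as N)."""


@dataclass
class SubTable:
    """Probability table over a sub-window of non-consensus k-mer positions.

    ``sign`` is +1 for product terms and -1 for ratio (denominator) terms,
    which is how overlapping acceptor sub-models combine.
    """

    positions: tuple
    probs: dict
    sign: int = 1

    def validate(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        total = math.fsum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"table over positions {self.positions} sums to {total}, not 1"
            )
        width = len(self.positions)
        if any(len(k) != width for k in self.probs):
            raise ValueError("table key width does not match positions")


@dataclass
class SpliceModel:
    """Factorized splice-site model (see module docstring)."""

    site_kind: str
    kmer_length: int
    consensus_positions: tuple
    consensus_probs: dict  # substring -> (model probability, background probability)
    tables: list = field(default_factory=list)
    background: dict = field(default_factory=lambda: {b: 0.25 for b in _BASES})
    pseudocount: float = 1e-6

    def __post_init__(self) -> None:
        expected = DONOR_KMER_LEN if self.site_kind == DONOR else ACCEPTOR_KMER_LEN
        if self.site_kind not in (DONOR, ACCEPTOR):
            raise ValueError(f"site_kind must be donor or acceptor, got {self.site_kind}")
        if self.kmer_length != expected:
            raise ValueError(
                f"{self.site_kind} model must use {expected}-mers, got {self.kmer_length}"
            )

    def validate(self) -> "SpliceModel":
        for t in self.tables:
            t.validate()
        coverage = {i: 0 for i in range(self.kmer_length)}
        for i in self.consensus_positions:
            coverage[i] += 1
        for t in self.tables:
            for i in t.positions:
                coverage[i] += t.sign
        bad = [i for i, c in coverage.items() if c != 1]
        if bad:
            raise ValueError(f"positions {bad} not covered exactly once (net)")
        if abs(math.fsum(self.background.values()) - 1.0) > 1e-9:
            raise ValueError("background base probabilities must sum to 1")
        return self

    def background_product(self, sub: str) -> float:
        p = 1.0
        for b in sub:
            p *= self.background[b]
        return p


def score_site(kmer: str, model: SpliceModel) -> float:
    """Score a k-mer in bits: log2(P_model / P_background).

    Consensus positions contribute the log-ratio of consensus frequencies;
    every sub-table contributes sign * log2 of its probability ratio against
    the 0th-order background over the same positions.  A pseudocount keeps
    every lookup finite; it is added to both sides of each ratio so a model
    identical to its background scores exactly 0.
    """
    kmer = kmer.upper()
    if len(kmer) != model.kmer_length:
        raise ValueError(
            f"k-mer length {len(kmer)} does not match model ({model.kmer_length})"
        )
    if any(b not in _BASES for b in kmer):
        raise UnscoreableKmer(f"non-ACGT base in {kmer!r}")
    pc = model.pseudocount
    cons = "".join(kmer[i] for i in model.consensus_positions)
    model_p, bg_p = model.consensus_probs.get(
        cons, (0.0, model.background_product(cons))
    )
    score = math.log2((model_p + pc) / (bg_p + pc))
    for t in model.tables:
        sub = "".join(kmer[i] for i in t.positions)
        p = t.probs.get(sub, 0.0)
        q = model.background_product(sub)
        score += t.sign * math.log2((p + pc) / (q + pc))
    return score


# ---------------------------------------------------------------------------
# Model constructors
# ---------------------------------------------------------------------------


def _consensus_positions(site_kind: str) -> tuple:
    return DONOR_CONSENSUS if site_kind == DONOR else ACCEPTOR_CONSENSUS


def _kmer_length(site_kind: str) -> int:
    return DONOR_KMER_LEN if site_kind == DONOR else ACCEPTOR_KMER_LEN


def uniform_model(site_kind: str) -> SpliceModel:
    """A model identical to its background; scores 0 bits for every k-mer."""
    k = _kmer_length(site_kind)
    cons = _consensus_positions(site_kind)
    rest = tuple(i for i in range(k) if i not in cons)
    bg = {b: 0.25 for b in _BASES}
    consensus = {
        "".join(p): (0.0625, 0.0625) for p in product(_BASES, repeat=2)
    }
    tables = [
        SubTable(positions=(i,), probs={b: 0.25 for b in _BASES}, sign=1)
        for i in rest
    ]
    return SpliceModel(
        site_kind=site_kind,
        kmer_length=k,
        consensus_positions=cons,
        consensus_probs=consensus,
        tables=tables,
        background=bg,
    ).validate()


def positional_model_from_sites(
    site_kind: str,
    sequences: Sequence[str],
    background: Optional[dict] = None,
) -> SpliceModel:
    """Independence model from observed splice-site k-mers.

    Each non-consensus position gets its own single-position frequency table;
    the consensus dinucleotide is scored by its observed frequency against
    the background product.  This is the simplest member of the factorized
    family and is what the synthetic fixtures use.
    """
    k = _kmer_length(site_kind)
    cons = _consensus_positions(site_kind)
    if not sequences:
        raise ValueError("need at least one site sequence")
    if any(len(s) != k for s in sequences):
        raise ValueError(f"all site sequences must be {k}-mers")
    sequences = [s.upper() for s in sequences]
    bg = dict(background) if background else {b: 0.25 for b in _BASES}
    n = len(sequences)
    tables = []
    for i in range(k):
        if i in cons:
            continue
        counts = {b: 0 for b in _BASES}
        for s in sequences:
            counts[s[i]] += 1
        tables.append(
            SubTable(positions=(i,), probs={b: c / n for b, c in counts.items()})
        )
    cons_counts: dict = {}
    for s in sequences:
        sub = "".join(s[i] for i in cons)
        cons_counts[sub] = cons_counts.get(sub, 0) + 1
    consensus = {}
    for sub_tuple in product(_BASES, repeat=len(cons)):
        sub = "".join(sub_tuple)
        bg_p = 1.0
        for b in sub:
            bg_p *= bg[b]
        consensus[sub] = (cons_counts.get(sub, 0) / n, bg_p)
    return SpliceModel(
        site_kind=site_kind,
        kmer_length=k,
        consensus_positions=cons,
        consensus_probs=consensus,
        tables=tables,
        background=bg,
    ).validate()


# ---------------------------------------------------------------------------
# Text model format
# ---------------------------------------------------------------------------


def save_splice_model(model: SpliceModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"site_kind: {model.site_kind}\n")
        fh.write(f"kmer_length: {model.kmer_length}\n")
        fh.write(f"pseudocount: {model.pseudocount!r}\n\n")
        fh.write("[background]\n")
        for b in _BASES:
            fh.write(f"{b}\t{model.background[b]!r}\n")
        cons = ",".join(str(i) for i in model.consensus_positions)
        fh.write(f"\n[consensus positions={cons}]\n")
        for sub in sorted(model.consensus_probs):
            mp, bp = model.consensus_probs[sub]
            fh.write(f"{sub}\t{mp!r}\t{bp!r}\n")
        for t in model.tables:
            pos = ",".join(str(i) for i in t.positions)
            fh.write(f"\n[table positions={pos} sign={t.sign}]\n")
            for sub in sorted(t.probs):
                fh.write(f"{sub}\t{t.probs[sub]!r}\n")


def load_splice_model(path) -> SpliceModel:
    meta: dict = {}
    background: dict = {}
    consensus: dict = {}
    cons_positions: tuple = ()
    tables: list = []
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                head = line.strip("[]")
                parts = head.split()
                kind = parts[0]
                attrs = dict(p.split("=", 1) for p in parts[1:])
                if kind == "background":
                    section = ("background",)
                elif kind == "consensus":
                    cons_positions = tuple(
                        int(i) for i in attrs["positions"].split(",")
                    )
                    section = ("consensus",)
                elif kind == "table":
                    tables.append(
                        SubTable(
                            positions=tuple(
                                int(i) for i in attrs["positions"].split(",")
                            ),
                            probs={},
                            sign=int(attrs.get("sign", "1")),
                        )
                    )
                    section = ("table",)
                else:
                    raise ValueError(f"unknown section {kind!r} in {path}")
                continue
            if ":" in line and section is None:
                key, val = (s.strip() for s in line.split(":", 1))
                meta[key] = val
                continue
            fields = line.split()
            if section == ("background",):
                background[fields[0]] = float(fields[1])
            elif section == ("consensus",):
                consensus[fields[0]] = (float(fields[1]), float(fields[2]))
            elif section == ("table",):
                tables[-1].probs[fields[0]] = float(fields[1])
            else:
                raise ValueError(f"stray line {line!r} in {path}")
    model = SpliceModel(
        site_kind=meta["site_kind"],
        kmer_length=int(meta["kmer_length"]),
        consensus_positions=cons_positions,
        consensus_probs=consensus,
        tables=tables,
        background=background,
        pseudocount=float(meta.get("pseudocount", "1e-6")),
    )
    return model.validate()


# ---------------------------------------------------------------------------
# k-mer extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KmerPair:
    """Reference and mutant k-mers for one splice site."""

    ref_kmer: str
    mut_kmer: Optional[str]
    scoreable: bool
    mut_index: Optional[int] = None  # 0-based index of the substituted base
    footprint: Optional[GenomicInterval] = None


def _footprint(side: str, boundary: int, strand: str) -> tuple[int, int]:
    """Genomic half-open footprint of the k-mer for a splice point at
    ``boundary`` (0-based coordinate of the exon/intron transition)."""
    if side == DONOR:
        if strand == "+":
            return boundary - DONOR_EXONIC, boundary + (DONOR_KMER_LEN - DONOR_EXONIC)
        return boundary - (DONOR_KMER_LEN - DONOR_EXONIC), boundary + DONOR_EXONIC
    if side == ACCEPTOR:
        if strand == "+":
            return boundary - ACCEPTOR_INTRONIC, boundary + (
                ACCEPTOR_KMER_LEN - ACCEPTOR_INTRONIC
            )
        return boundary - (ACCEPTOR_KMER_LEN - ACCEPTOR_INTRONIC), (
            boundary + ACCEPTOR_INTRONIC
        )
    raise ValueError(f"side must be donor or acceptor, got {side!r}")


def _mutation_span(mutation: MutationRecord) -> tuple[int, int]:
    """Genomic footprint of the variant's reference-side bases."""
    if mutation.ref_allele == "-":
        # pure insertion between pos0 and pos0+1
        return mutation.pos0, mutation.pos0 + 2
    return mutation.pos0, mutation.pos0 + len(mutation.ref_allele)


def extract_site_kmers(
    junction_side: str,
    chrom: str,
    boundary_pos: int,
    strand: str,
    ref: ReferenceGenome,
    mutation: Optional[MutationRecord] = None,
) -> KmerPair:
    """Reference and mutant k-mers covering a splice point.

    ``boundary_pos`` is the 0-based genomic coordinate of the splice point
    (intron start for a plus-strand donor, intron end for a plus-strand
    acceptor, mirrored on the minus strand).  Substitutions inside the k-mer
    footprint yield a mutant k-mer; an indel overlapping the footprint marks
    the pair unscoreable (the model is defined for single-base events); a
    mutation outside the footprint leaves the mutant side empty.
    """
    fstart, fend = _footprint(junction_side, boundary_pos, strand)
    ref_seq = ref.fetch(chrom, fstart, fend, "+")
    orient = (lambda s: reverse_complement(s)) if strand == "-" else (lambda s: s)
    footprint = GenomicInterval(chrom, fstart, fend, strand)
    ref_kmer = orient(ref_seq)

    if mutation is None or mutation.chrom != chrom:
        return KmerPair(ref_kmer, None, True, footprint=footprint)

    mstart, mend = _mutation_span(mutation)
    overlaps = mstart < fend and fstart < mend
    if not mutation.is_snv:
        if overlaps:
            return KmerPair(ref_kmer, None, False, footprint=footprint)
        return KmerPair(ref_kmer, None, True, footprint=footprint)
    if not overlaps:
        return KmerPair(ref_kmer, None, True, footprint=footprint)

    offset = mutation.pos0 - fstart
    mut_seq = ref_seq[:offset] + mutation.alt_allele + ref_seq[offset + 1 :]
    mut_kmer = orient(mut_seq)
    mut_index = offset if strand == "+" else len(ref_seq) - 1 - offset
    return KmerPair(ref_kmer, mut_kmer, True, mut_index=mut_index, footprint=footprint)


# ---------------------------------------------------------------------------
# Score comparison and context classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScorePair:
    """Reference/mutant scores (bits) at one site."""

    ref_score: float
    mut_score: float
    site_role: str  # "alternative" | "canonical"

    @property
    def delta(self) -> float:
        return self.mut_score - self.ref_score


ALT_STRONGER = "alt_stronger"
GAP_NARROWED = "gap_narrowed"
NO_EVIDENCE = "no_evidence"
UNSCOREABLE = "unscoreable"


def _score_pair(pair: KmerPair, model: SpliceModel, role: str) -> ScorePair:
    ref_score = score_site(pair.ref_kmer, model)
    # A mutation outside this site's footprint leaves the site unchanged.
    mut_score = score_site(pair.mut_kmer, model) if pair.mut_kmer else ref_score
    return ScorePair(ref_score=ref_score, mut_score=mut_score, site_role=role)


def compare_scores(
    side: str,
    chrom: str,
    alt_boundary: int,
    canonical_boundary: int,
    strand: str,
    mutation: Optional[MutationRecord],
    ref: ReferenceGenome,
    models: dict,
) -> tuple[Optional[ScorePair], Optional[ScorePair], str]:
    """Score the alternative and nearest-canonical site before/after mutation.

    preference_class:
      * ``alt_stronger`` — mutant alternative score exceeds the mutant
        canonical score outright;
      * ``gap_narrowed`` — it does not, but the (alternative - canonical)
        margin increased after mutation;
      * ``no_evidence`` — neither;
      * ``unscoreable`` — either site cannot be scored (indel in footprint,
        ambiguous base).
    """
    model = models[side]
    alt_pair = extract_site_kmers(side, chrom, alt_boundary, strand, ref, mutation)
    can_pair = extract_site_kmers(side, chrom, canonical_boundary, strand, ref, mutation)
    if not (alt_pair.scoreable and can_pair.scoreable):
        return None, None, UNSCOREABLE
    try:
        alt = _score_pair(alt_pair, model, "alternative")
        can = _score_pair(can_pair, model, "canonical")
    except UnscoreableKmer:
        return None, None, UNSCOREABLE
    if alt.mut_score > can.mut_score:
        cls = ALT_STRONGER
    elif (alt.mut_score - can.mut_score) > (alt.ref_score - can.ref_score):
        cls = GAP_NARROWED
    else:
        cls = NO_EVIDENCE
    return alt, can, cls


AGAG = "aGag"
AGGAG = "agGag"
OTHER_CONTEXT = "other"
NOT_APPLICABLE = "not_applicable"

#: 0-based 23-mer index of the acceptor intronic -3 position.
ACCEPTOR_MINUS3_INDEX = 17

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def substitution_label(ref_base: str, alt_base: str) -> str:
    kind = "transition" if (ref_base, alt_base) in _TRANSITIONS else "transversion"
    return f"{ref_base}>{alt_base} {kind}"


def classify_minus3_context(
    acceptor_kmer_ref: str, acceptor_kmer_mut: str
) -> tuple[str, Optional[str]]:
    """Classify the sequence context of an acceptor -3 mutation.

    Expects reference and mutant acceptor 23-mers differing at exactly the
    intronic -3 position with an AG at -2/-1.  The context patterns are read
    on the reference sequence around the mutated base (capitalized base =
    mutated position): ``aGag`` when -4..-1 is A,G,A,G and ``agGag`` when
    -5..-1 is A,G,G,A,G.  These are the repeat contexts in which a -3 change
    creates an acceptor two nucleotides from the annotated one.
    """
    ref = acceptor_kmer_ref.upper()
    mut = acceptor_kmer_mut.upper()
    if len(ref) != ACCEPTOR_KMER_LEN or len(mut) != ACCEPTOR_KMER_LEN:
        raise ValueError("expected acceptor 23-mers")
    diffs = [i for i in range(ACCEPTOR_KMER_LEN) if ref[i] != mut[i]]
    if len(diffs) != 1:
        return NOT_APPLICABLE, None
    i = diffs[0]
    label = substitution_label(ref[i], mut[i])
    if i != ACCEPTOR_MINUS3_INDEX or ref[18:20] != "AG":
        return NOT_APPLICABLE, label
    if ref[15:20] == "AGGAG":
        return AGGAG, label
    if ref[16:20] == "AGAG":
        return AGAG, label
    return OTHER_CONTEXT, label
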
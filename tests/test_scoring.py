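import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import score_by_table_arithmetic
from conftest import snv

from scmfinder.io import VariantClass
from scmfinder.scoring import (
    ACCEPTOR,
    AGAG,
    AGGAG,
    ALT_STRONGER,
    DONOR,
    GAP_NARROWED,
    NO_EVIDENCE,
    NOT_APPLICABLE,
    OTHER_CONTEXT,
    SpliceModel,
    SubTable,
    UnscoreableKmer,
    classify_minus3_context,
    extract_site_kmers,
    load_splice_model,
    positional_model_from_sites,
    save_splice_model,
    score_site,
    uniform_model,
)

kmer_strategy = st.text(alphabet="ACGT", min_size=9, max_size=9)


def random_donor_model(seed: int) -> SpliceModel:
    """Seeded donor model with two multi-position tables and rich consensus."""
    rng = np.random.default_rng(seed)

    def dirichlet_table(positions):
        keys = ["".join(p) for p in product("ACGT", repeat=len(positions))]
        probs = rng.dirichlet(np.ones(len(keys)))
        return SubTable(positions=positions, probs=dict(zip(keys, probs.tolist())))

    consensus = {}
    weights = rng.dirichlet(np.ones(16))
    for i, sub in enumerate("".join(p) for p in product("ACGT", repeat=2)):
        consensus[sub] = (float(weights[i]), 0.0625)
    return SpliceModel(
        site_kind=DONOR,
        kmer_length=9,
        consensus_positions=(3, 4),
        consensus_probs=consensus,
        tables=[dirichlet_table((0, 1, 2)), dirichlet_table((5, 6, 7, 8))],
    ).validate()


class TestScoreSite:
    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(kmer=kmer_strategy)
    def test_background_equal_model_scores_exactly_zero(self, kmer):
        assert score_site(kmer, uniform_model(DONOR)) == 0.0

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(kmer=kmer_strategy)
    def test_matches_direct_table_arithmetic(self, kmer):
        model = random_donor_model(42)
        assert score_site(kmer, model) == pytest.approx(
            score_by_table_arithmetic(kmer, model), abs=1e-9
        )

    def test_length_mismatch_and_ambiguous_base(self):
        model = uniform_model(DONOR)
        with pytest.raises(ValueError, match="length"):
            score_site("ACGT", model)
        with pytest.raises(UnscoreableKmer):
            score_site("CAGGTNAGT", model)

    def test_score_depends_only_on_sequence(self):
        # translation invariance: identical k-mer, no positional state
        model = random_donor_model(7)
        assert score_site("CAGGTAAGT", model) == score_site("CAGGTAAGT", model)

    def test_neutral_position_does_not_discriminate(self):
        model = uniform_model(DONOR)
        assert score_site("AAGGTAAGT", model) == score_site("CAGGTAAGT", model)

    def test_round_trip_through_text_format(self, tmp_path):
        model = random_donor_model(3)
        path = tmp_path / "donor.model"
        save_splice_model(model, path)
        loaded = load_splice_model(path)
        for kmer in ("CAGGTAAGT", "TTTTTTTTT", "ACGTACGTA"):
            assert score_site(kmer, loaded) == score_site(kmer, model)


class TestKmerExtraction:
    CONTIG = "".join(
        "ACGT"[(i * 7 + 3) % 4] for i in range(400)
    )  # deterministic scrambled sequence

    @pytest.fixture
    def ref(self, make_fasta):
        return make_fasta({"c": self.CONTIG})

    def test_plus_strand_donor_geometry(self, ref):
        boundary = 100
        pair = extract_site_kmers(DONOR, "c", boundary, "+", ref)
        assert pair.ref_kmer == self.CONTIG[97:106]
        assert pair.mut_kmer is None and pair.scoreable

    def test_minus_strand_acceptor_geometry(self, ref):
        from scmfinder.intervals import reverse_complement

        boundary = 200  # intron start on the minus strand
        pair = extract_site_kmers(ACCEPTOR, "c", boundary, "-", ref)
        assert pair.ref_kmer == reverse_complement(self.CONTIG[197:220])

    def test_minus3_substitution_lands_at_index_17(self, ref):
        # acceptor on + strand: intronic -3 is 3 bases 5' of the boundary
        boundary = 150
        pos0 = boundary - 3
        mut = snv(chrom="c", pos=pos0 + 1, ref=self.CONTIG[pos0], alt="G"
                  if self.CONTIG[pos0] != "G" else "A")
        pair = extract_site_kmers(ACCEPTOR, "c", boundary, "+", ref, mut)
        diffs = [
            i for i in range(23) if pair.ref_kmer[i] != pair.mut_kmer[i]
        ]
        assert diffs == [17]
        assert pair.mut_index == 17

    def test_indel_in_footprint_is_unscoreable(self, ref):
        boundary = 100
        mut = snv(chrom="c", pos=boundary, ref=self.CONTIG[99:101], alt="-",
                  vclass=VariantClass.INDEL)
        pair = extract_site_kmers(DONOR, "c", boundary, "+", ref, mut)
        assert not pair.scoreable and pair.mut_kmer is None

    def test_mutation_outside_footprint_gives_ref_only(self, ref):
        pair = extract_site_kmers(
            DONOR, "c", 100, "+", ref, snv(chrom="c", pos=300, ref="A", alt="G")
        )
        assert pair.scoreable and pair.mut_kmer is None


class TestCompareScores:
    def _model_pair(self):
        return {DONOR: uniform_model(DONOR), ACCEPTOR: uniform_model(ACCEPTOR)}

    def test_trichotomy_rules(self):
        # exercised directly on the classification arithmetic
        from scmfinder.scoring import ScorePair

        def classify(alt_ref, alt_mut, can_ref, can_mut):
            if alt_mut > can_mut:
                return ALT_STRONGER
            if (alt_mut - can_mut) > (alt_ref - can_ref):
                return GAP_NARROWED
            return NO_EVIDENCE

        assert classify(1.0, 8.1, 3.0, 3.0) == ALT_STRONGER
        assert classify(2.0, 4.0, 9.0, 9.0) == GAP_NARROWED
        assert classify(5.0, 5.0, 5.0, 5.0) == NO_EVIDENCE

    def test_end_to_end_alt_stronger(self, make_fasta):
        # mutant GT at the alternative donor, scrambled canonical site
        contig = "A" * 97 + "CAGATAAGT" + "A" * 94 + "CAGCCAAGT" + "A" * 100
        ref = make_fasta({"c": contig})
        sites = ["CAGGTAAGT"] * 8 + ["CAGATAAGT"] * 1 + ["AAGGTAAGA"] * 1
        models = {DONOR: positional_model_from_sites(DONOR, sites)}
        mut = snv(chrom="c", pos=101, ref="A", alt="G")  # creates GT at alt donor
        alt, can, cls = __import__("scmfinder.scoring", fromlist=["compare_scores"]).compare_scores(
            DONOR, "c", 100, 200, "+", mut, ref, models
        )
        assert alt.mut_score > alt.ref_score
        assert can.mut_score == can.ref_score  # mutation outside canonical 9-mer
        assert cls == ALT_STRONGER

    def test_unscoreable_when_indel_hits_footprint(self, make_fasta):
        ref = make_fasta({"c": "ACGT" * 100})
        mut = snv(chrom="c", pos=100, ref="GT", alt="-", vclass=VariantClass.INDEL)
        from scmfinder.scoring import compare_scores

        alt, can, cls = compare_scores(
            DONOR, "c", 100, 200, "+", mut, ref, self._model_pair()
        )
        assert (alt, can, cls) == (None, None, "unscoreable")


class TestMinus3Context:
    def _kmers(self, around: str, mut_base: str):
        """Place `around` so that it ends at k-mer index 19 (intron -1)."""
        prefix = "T" * (20 - len(around))
        ref = prefix + around + "CCC"
        i = 17
        mut = ref[:i] + mut_base + ref[i + 1 :]
        return ref, mut

    def test_agag_g_to_c_transversion(self):
        ref, mut = self._kmers("AGAG", "C")
        assert classify_minus3_context(ref, mut) == (AGAG, "G>C transversion")

    def test_aggag_context(self):
        ref, mut = self._kmers("AGGAG", "A")
        assert classify_minus3_context(ref, mut) == (AGGAG, "G>A transition")

    def test_other_context(self):
        ref = "T" * 16 + "CG" + "AG" + "CCC"
        assert ref[18:20] == "AG" and len(ref) == 23
        mut = ref[:17] + "A" + ref[18:]
        context, label = classify_minus3_context(ref, mut)
        assert context == OTHER_CONTEXT

    def test_not_applicable_off_minus3_or_no_ag(self):
        ref = "T" * 20 + "CCC"
        mut = ref[:10] + "A" + ref[11:]
        assert classify_minus3_context(ref, mut)[0] == NOT_APPLICABLE
        ref2, mut2 = self._kmers("AGAT", "C")  # no AG at -2/-1
        assert classify_minus3_context(ref2, mut2)[0] == NOT_APPLICABLE

    def test_minus3_gain_raises_score_under_consensus_model(self):
        # acceptor sites with G common at -3: an A>G change at -3 must gain bits
        sites = []
        for i in range(10):
            core = "TTTTTTTTTTTTTTTTT" + ("G" if i < 8 else "A") + "AG" + "CTC"
            sites.append(core)
        model = positional_model_from_sites(ACCEPTOR, sites)
        weak = "TTTTTTTTTTTTTTTTT" + "A" + "AG" + "CTC"
        strong = weak[:17] + "G" + weak[18:]
        assert score_site(strong, model) > score_site(weak, model)
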
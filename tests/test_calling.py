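import pytest

from conftest import snv

from scmfinder.calling import (
    COMPLEX,
    NO_SUPPORT,
    PASS,
    PipelineConfig,
    call_scms,
    calls_to_dataframe,
    review_and_aggregate,
    write_junctions_bed12,
)
from scmfinder.intervals import GenomicInterval
from scmfinder.io import (
    MutationRecord,
    ReferenceGenome,
    VariantClass,
    build_junction_index,
    read_mutations,
)
from scmfinder.simulate import SamBuilder


@pytest.fixture
def world_run(standard_world, uniform_models, tmp_path_factory):
    world = standard_world["world"]
    paths = standard_world["paths"]
    index = build_junction_index(world.gtf_path)
    ref = ReferenceGenome(world.genome_path)
    callset = call_scms(
        read_mutations(world.maf_path),
        {s: paths[s] for s in world.case_samples},
        {s: paths[s] for s in world.control_samples},
        index,
        uniform_models,
        ref,
        PipelineConfig(),
    )
    return world, callset


class TestEndToEnd:
    def test_every_truth_event_is_a_pass_call(self, world_run):
        world, callset = world_run
        passes = {
            (c.mutation.sample_id, c.mutation.gene): c for c in callset.passes()
        }
        assert len(passes) == len(world.events)
        for ev in world.events:
            call = passes[(ev.sample, ev.gene)]
            detail = call.details[0]
            assert detail.junction.key() == (
                ev.chrom, *ev.alternative_intron
            )
            assert detail.quant.in_out == ev.in_out
            assert detail.quant.jaf == pytest.approx(ev.true_jaf, abs=0.15)

    def test_no_decoy_produces_a_call(self, world_run):
        world, callset = world_run
        decoy_keys = {(d.sample, d.gene) for d in world.decoys}
        called = {(c.mutation.sample_id, c.mutation.gene) for c in callset.calls}
        assert not decoy_keys & called

    def test_audit_completeness(self, world_run):
        world, callset = world_run
        keys = [c.mutation.key() for c in callset.calls] + [
            a.mutation.key() for a in callset.audit
        ]
        expected = [m.key() for m in read_mutations(world.maf_path)]
        assert sorted(keys) == sorted(expected)

    def test_splice_in_events_have_full_spliced_in_jaf(self, world_run):
        world, callset = world_run
        for call in callset.passes():
            detail = call.details[0]
            if detail.quant.in_out == "splice_in" and call.mutation.is_snv:
                # error-free reads from the mutant haplotype all carry the allele
                assert detail.quant.spliced_in_jaf == 1.0

    def test_near_canonical_decoys_audited_as_canonical(self, world_run):
        world, callset = world_run
        near = {
            (d.sample, d.chrom, d.pos)
            for d in world.decoys
            if d.near_canonical
        }
        audited = {
            (a.mutation.sample_id, a.mutation.chrom, a.mutation.pos): a
            for a in callset.audit
        }
        for key in near:
            assert audited[key].first_reason == "canonical junction"

    def test_tabular_outputs(self, world_run, tmp_path):
        _, callset = world_run
        df = calls_to_dataframe(callset)
        assert len(df) == len(callset.calls)
        assert set(df["review"]) == {PASS}
        write_junctions_bed12(callset, tmp_path / "j.bed")
        lines = (tmp_path / "j.bed").read_text().splitlines()
        assert len(lines) == len(callset.calls)
        assert all(len(line.split("\t")) == 12 for line in lines)


class ToyCohort:
    """Hand-built single-gene cohort for review-rule checks."""

    CONTIG = 5000

    def __init__(self, tmp_path, make_gtf, make_fasta):
        self.index = build_junction_index(
            make_gtf([("G1", "chr1", "+", [(500, 1500), (1600, 2500)])])
        )
        self.ref = make_fasta({"chr1": "A" * self.CONTIG})
        self.tmp = tmp_path

    def control(self, name="ctrl"):
        b = SamBuilder({"chr1": self.CONTIG})
        for i in range(30):
            b.add_read(f"{name}{i}", "chr1", [(950, 100)])
        return b.write(self.tmp / f"{name}.sam")

    def case(self, introns, n_ref=10, name="case"):
        b = SamBuilder({"chr1": self.CONTIG})
        for j, intron in enumerate(introns):
            for i in range(8):
                b.add_spliced_fragment(f"j{j}.{i}", "chr1", intron)
        for i in range(n_ref):
            b.add_read(f"bg{i}", "chr1", [(950, 100)])
        return b.write(self.tmp / f"{name}.sam")


@pytest.fixture
def toy(tmp_path, make_gtf, make_fasta):
    return ToyCohort(tmp_path, make_gtf, make_fasta)


class TestReviewRules:
    def run(self, toy, introns, uniform_models):
        mutation = snv(sample="case", gene="G1", pos=995)
        return call_scms(
            [mutation],
            {"case": toy.case(introns)},
            {"ctrl": toy.control()},
            toy.index,
            uniform_models,
            toy.ref,
        )

    def test_single_junction_is_pass(self, toy, uniform_models):
        callset = self.run(toy, [(1000, 1600)], uniform_models)
        (call,) = callset.calls
        assert call.review == PASS and len(call.details) == 1

    def test_two_junctions_are_complex(self, toy, uniform_models):
        callset = self.run(toy, [(1000, 1600), (1010, 1600)], uniform_models)
        (call,) = callset.calls
        assert call.review == COMPLEX and len(call.details) == 2

    def test_no_junction_is_no_support(self, toy, uniform_models):
        callset = self.run(toy, [], uniform_models)
        assert callset.calls == []
        (audit,) = callset.audit
        assert audit.review == NO_SUPPORT
        assert audit.first_reason == "no candidate junction"

    def test_filter_order_invariance_of_pass_set(self, toy, uniform_models):
        """JAF and control filters are per-event predicates; the surviving
        set must not depend on evaluation order (checked by construction:
        one junction failing JAF, one failing controls, one passing both)."""
        mutation = snv(sample="case", gene="G1", pos=995)
        # junction A: strong in case, absent in controls -> survives
        # junction B: below 5% JAF -> fails JAF regardless of controls
        case = SamBuilder({"chr1": toy.CONTIG})
        for i in range(20):
            case.add_spliced_fragment(f"a{i}", "chr1", (1000, 1600))
        for i in range(5):
            case.add_spliced_fragment(f"b{i}", "chr1", (990, 1600))
        for i in range(200):
            case.add_read(f"bg{i}", "chr1", [(930, 100)])
        case_path = case.write(toy.tmp / "case_mix.sam")
        callset = call_scms(
            [mutation],
            {"case": case_path},
            {"ctrl": toy.control()},
            toy.index,
            uniform_models,
            toy.ref,
        )
        (call,) = callset.calls
        assert call.review == PASS
        assert call.junction.key() == ("chr1", 1000, 1600)


class TestAggregation:
    def _call(self, gene, pos, intron, sample="s1",
              vclass=VariantClass.MISSENSE, review=PASS):
        from scmfinder.calling import JunctionCallDetail, SCMCall
        from scmfinder.cohort import ControlStats, Verdict
        from scmfinder.discovery import CandidateJunction
        from scmfinder.quant import JunctionQuant

        mutation = snv(sample=sample, gene=gene, pos=pos, vclass=vclass)
        cand = CandidateJunction(
            intron=GenomicInterval("chr1", *intron),
            supporting_fragment_ids=frozenset({"x"}),
            distance_to_mutation=1,
        )
        detail = JunctionCallDetail(
            junction=cand,
            quant=JunctionQuant(10, 20, 0.5, anchor0=intron[0] - 1),
            control=ControlStats.from_counts([0] * 5),
            verdict=Verdict.HIGH,
        )
        return SCMCall(mutation=mutation, details=[detail], review=review)

    def test_cluster_of_two_within_five_bp(self):
        calls = [
            self._call("G1", 100, (110, 200), sample="s1"),
            self._call("G1", 104, (110, 200), sample="s2"),
            self._call("G1", 150, (160, 200), sample="s3"),
        ]
        table = review_and_aggregate(calls)
        assert table.gene_counts == {"G1": 3}
        assert len(table.clusters) == 1
        (gene, jkey, members) = table.clusters[0]
        assert gene == "G1" and len(members) == 2

    def test_two_genes_no_clusters(self):
        calls = [
            self._call("G1", 100, (110, 200), sample="s1"),
            self._call("G2", 100, (110, 200), sample="s2"),
        ]
        table = review_and_aggregate(calls)
        assert sum(table.gene_counts.values()) == 2
        assert table.clusters == []

    def test_adjacent_mutations_different_junctions_do_not_cluster(self):
        calls = [
            self._call("G1", 100, (110, 200), sample="s1"),
            self._call("G1", 102, (112, 200), sample="s2"),
        ]
        assert review_and_aggregate(calls).clusters == []

    def test_cancer_type_matrix(self):
        calls = [
            self._call("G1", 100, (110, 200), sample="s1"),
            self._call("G1", 300, (310, 400), sample="s2"),
            self._call("G2", 100, (110, 200), sample="s1"),
        ]
        table = review_and_aggregate(
            calls, sample_metadata={"s1": "BRCA", "s2": "LUSC"}
        )
        m = table.per_cancer_type
        assert m.loc["G1", "BRCA"] == 1 and m.loc["G1", "LUSC"] == 1
        assert m.loc["G2", "BRCA"] == 1

    def test_summary_counts(self):
        calls = [
            self._call("G1", 100, (110, 200), sample="s1"),
            self._call("G1", 500, (510, 600), sample="s2"),
            self._call("G2", 100, (110, 200), sample="s3"),
            self._call("G3", 100, (110, 200), review=COMPLEX),
        ]
        table = review_and_aggregate(calls)
        assert table.summary["n_pass"] == 3
        assert table.summary["n_genes"] == 2
        assert table.summary["n_genes_multi"] == 1


class TestConfig:
    def test_config_file_round_trip(self, tmp_path):
        path = tmp_path / "cfg"
        path.write_text("window=30\njaf_min=0.1\nexclude_duplicates=false\n")
        config = PipelineConfig.from_file(path)
        assert config.window == 30
        assert config.jaf_min == 0.1
        assert config.exclude_duplicates is False

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg"
        path.write_text("wibble=1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            PipelineConfig.from_file(path)
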
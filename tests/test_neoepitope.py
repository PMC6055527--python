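import pytest
from hypothesis import given, settings, strategies as st

from conftest import snv

from scmfinder.intervals import GenomicInterval
from scmfinder.io import VariantClass
from scmfinder.neoepitope import (
    EPITOPE_LENGTHS,
    TranscriptModel,
    enumerate_novel_epitopes,
    read_affinity_table,
    translate_mutant,
)
from scmfinder.simulate import WorldParams, generate_truth_set

AA = "ACDEFGHIKLMNPQRSTVWY"


def toy_transcript(make_fasta, exon_cds: str, intron: str, exon2_cds: str,
                   chrom="c", lead=9):
    """Two-exon plus-strand gene; CDS spans both exons entirely."""
    seq = "G" * lead + exon_cds + intron + exon2_cds + "G" * 9
    ref = make_fasta({chrom: seq})
    e1 = (lead, lead + len(exon_cds))
    e2 = (e1[1] + len(intron), e1[1] + len(intron) + len(exon2_cds))
    tx = TranscriptModel(
        transcript_id="t1", chrom=chrom, strand="+",
        exons=[e1, e2], cds_start=e1[0], cds_end=e2[1],
    )
    return ref, tx, (e1[1], e2[0])


class TestTranslateMutant:
    def test_identity_junction_reproduces_wild_type(self, make_fasta):
        ref, tx, intron = toy_transcript(
            make_fasta,
            "ATGGCTGCAGCTTGT" * 2,  # 30 nt
            "GTAAGTTTTTTTTTTTTTTTTTTCAG",
            "GCTGCA" * 3 + "TAA",
        )
        res = translate_mutant(tx, GenomicInterval("c", *intron), None, ref)
        assert res.protein == res.wt_protein
        assert not res.frameshift

    def test_in_frame_donor_shift_deletes_amino_acids(self, make_fasta):
        ref, tx, intron = toy_transcript(
            make_fasta,
            "ATG" + "GCT" * 20,  # Met + 20 Ala
            "GTAAGTTTTTTTTTTTTTTTTTTCAG",
            "TGT" * 5 + "TAA",
        )
        # alternative donor 30 nt upstream of the canonical one: -10 aa
        alt = GenomicInterval("c", intron[0] - 30, intron[1])
        res = translate_mutant(tx, alt, None, ref)
        assert len(res.wt_protein) - len(res.protein) == 10
        assert not res.frameshift
        assert res.wt_protein.startswith(res.protein[: len(res.protein) - 5])

    def test_acceptor_shift_by_seven_causes_frameshift(self, make_fasta):
        ref, tx, intron = toy_transcript(
            make_fasta,
            "ATG" + "GCT" * 10,
            "GTAAGTTTTTTTTTTTTTTTTTTCAG",
            "TGTTGCTGCTGGTGATGGTAA" * 2,
        )
        alt = GenomicInterval("c", intron[0], intron[1] + 7)
        res = translate_mutant(tx, alt, None, ref)
        assert res.frameshift
        prefix_len = 11  # Met + 10 Ala from exon 1
        assert res.protein[:prefix_len] == res.wt_protein[:prefix_len]
        assert res.protein[prefix_len:] != res.wt_protein[prefix_len: len(res.protein)]

    def test_junction_outside_transcript_is_error(self, make_fasta):
        ref, tx, intron = toy_transcript(
            make_fasta, "ATGGCTGCT", "GTAAGTTTTTTTTTTCAG", "GCTTAA"
        )
        with pytest.raises(ValueError, match="outside"):
            translate_mutant(tx, GenomicInterval("c", 2000, 2100), None, ref)

    def test_cds_start_removed_yields_empty_protein(self, make_fasta):
        ref, tx, intron = toy_transcript(
            make_fasta, "GGGGGGATGGCTGCTGCAGCA", "GTAAGTTTTTTTTTTCAG", "GCTTAA"
        )
        tx.cds_start += 6  # 6 nt 5' UTR; ATG starts there
        alt = GenomicInterval("c", tx.cds_start - 1, intron[1])
        res = translate_mutant(tx, alt, None, ref)
        assert res.protein == "" and "CDS start" in res.note

    def test_splice_in_substitution_lands_in_protein(self, make_fasta):
        ref, tx, intron = toy_transcript(
            make_fasta,
            "ATG" + "GCT" * 10,
            "GTAAGTTTTTTTTTTTTTTTTTTCAG",
            "TGT" * 5 + "TAA",
        )
        # A>C at the second base of codon 2: GCT -> GGT (Ala -> Gly)
        mut = snv(chrom="c", pos=tx.cds_start + 5, ref="C", alt="G",
                  vclass=VariantClass.MISSENSE)
        res = translate_mutant(tx, GenomicInterval("c", *intron), mut, ref)
        assert res.wt_protein[1] == "A" and res.protein[1] == "G"
        assert res.protein[2:] == res.wt_protein[2:]

    def test_simulated_coding_gene_round_trip(self, tmp_path):
        """Translating the unmodified simulated transcript must reproduce the
        simulator's declared wild-type protein."""
        from scmfinder.io import ReferenceGenome

        world = generate_truth_set(
            WorldParams(n_events=1, event_kinds=["inframe_del"]), 21, tmp_path
        )
        gene = world.gene(world.events[0].gene)
        ref = ReferenceGenome(world.genome_path)
        tx = TranscriptModel(
            transcript_id=gene.name, chrom=gene.chrom, strand="+",
            exons=gene.exons, cds_start=gene.cds_start,
        )
        res = translate_mutant(
            tx, GenomicInterval(gene.chrom, *gene.introns[0]), None, ref
        )
        assert res.protein == gene.wt_protein


class TestEpitopeEnumeration:
    def _mutant_pair(self, n=30, pos=14):
        wt = (AA * 3)[:n]
        mut = wt[:pos] + ("W" if wt[pos] != "W" else "Y") + wt[pos + 1 :]
        return mut, wt

    def test_single_interior_substitution_yields_38_novel_windows(self):
        mut, wt = self._mutant_pair()
        epitopes = enumerate_novel_epitopes(mut, wt)
        assert len(epitopes) == 8 + 9 + 10 + 11
        by_len = {L: sum(1 for e in epitopes.peptides if e.length == L)
                  for L in EPITOPE_LENGTHS}
        assert by_len == {8: 8, 9: 9, 10: 10, 11: 11}

    def test_identical_proteins_yield_nothing(self):
        wt = (AA * 2)[:25]
        assert len(enumerate_novel_epitopes(wt, wt)) == 0

    def test_affinity_threshold_at_500nm(self):
        mut, wt = self._mutant_pair()
        all_eps = enumerate_novel_epitopes(mut, wt)
        peptides = sorted(all_eps.sequences())
        table = {(p, "HLA-A*02:01"): 600.0 for p in peptides}
        table[(peptides[0], "HLA-A*02:01")] = 450.0
        table[(peptides[1], "HLA-B*07:02")] = 120.0
        kept = enumerate_novel_epitopes(mut, wt, affinity_table=table)
        assert kept.sequences() == {peptides[0], peptides[1]}
        # exactly at threshold is kept
        table[(peptides[2], "HLA-A*02:01")] = 500.0
        kept = enumerate_novel_epitopes(mut, wt, affinity_table=table)
        assert peptides[2] in kept.sequences()

    def test_missing_peptides_kept_with_unknown_affinity(self):
        mut, wt = self._mutant_pair()
        table = {("NOTINPROTEIN", "HLA-A*02:01"): 10.0}
        kept = enumerate_novel_epitopes(mut, wt, affinity_table=table)
        assert len(kept) == 38
        assert all(e.affinity_nm is None for e in kept.peptides)

    def test_affinity_table_reader_validates_columns(self, tmp_path):
        good = tmp_path / "aff.tsv"
        good.write_text("peptide\tallele\taffinity_nm\nKPKRRLPG\tHLA-A\t42\n")
        assert read_affinity_table(good) == {("KPKRRLPG", "HLA-A"): 42.0}
        bad = tmp_path / "bad.tsv"
        bad.write_text("pep\tnM\nKPKRRLPG\t42\n")
        with pytest.raises(ValueError, match="columns"):
            read_affinity_table(bad)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        wt=st.text(alphabet=AA, min_size=12, max_size=40),
        data=st.data(),
    )
    def test_every_epitope_is_mutant_substring_absent_from_wild_type(
        self, wt, data
    ):
        pos = data.draw(st.integers(0, len(wt) - 1))
        sub = data.draw(st.sampled_from(AA))
        mut = wt[:pos] + sub + wt[pos + 1 :]
        epitopes = enumerate_novel_epitopes(mut, wt)
        for e in epitopes.peptides:
            assert mut[e.position : e.position + e.length] == e.sequence
            assert e.sequence not in wt
        # brute-force window census agrees
        expected = sum(
            1
            for L in EPITOPE_LENGTHS
            for i in range(len(mut) - L + 1)
            if mut[i : i + L] not in wt
        )
        assert len(epitopes) == expected
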
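from pathlib import Path

import pytest

from scmfinder.io import MutationRecord, ReferenceGenome, VariantClass, ensure_faidx
from scmfinder.scoring import uniform_model
from scmfinder.simulate import WorldParams, generate_truth_set, simulate_alignments


@pytest.fixture
def make_fasta(tmp_path):
    """Write {contig: sequence} to an indexed FASTA, return ReferenceGenome."""

    def _make(contigs: dict, name: str = "ref.fa") -> ReferenceGenome:
        path = tmp_path / name
        with open(path, "w") as fh:
            for contig, seq in contigs.items():
                fh.write(f">{contig}\n{seq}\n")
        ensure_faidx(path)
        return ReferenceGenome(path)

    return _make


@pytest.fixture
def make_gtf(tmp_path):
    """Write [(gene, chrom, strand, [(exon_start, exon_end), ...])] to a GTF."""

    def _make(genes: list, name: str = "anno.gtf") -> str:
        path = tmp_path / name
        with open(path, "w") as fh:
            for gi, (gene, chrom, strand, exons) in enumerate(genes):
                tx = f"{gene}.t{gi}"
                for s, e in exons:
                    attrs = (
                        f'gene_id "{gene}"; gene_name "{gene}"; '
                        f'transcript_id "{tx}";'
                    )
                    fh.write(
                        f"{chrom}\tt\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"
                    )
        return str(path)

    return _make


def snv(sample="s1", gene="G1", chrom="chr1", pos=100, ref="A", alt="G",
        vclass=VariantClass.MISSENSE, **kw) -> MutationRecord:
    return MutationRecord(
        sample_id=sample, gene=gene, chrom=chrom, pos=pos,
        ref_allele=ref, alt_allele=alt, variant_class=vclass, **kw
    )


@pytest.fixture
def mutation_factory():
    return snv


@pytest.fixture(scope="session")
def uniform_models():
    return {"donor": uniform_model("donor"), "acceptor": uniform_model("acceptor")}


@pytest.fixture(scope="session")
def standard_world(tmp_path_factory):
    """One shared noise-free world with all four event kinds and decoys."""
    outdir = tmp_path_factory.mktemp("world")
    params = WorldParams(
        n_events=4, n_cases=2, n_controls=10,
        n_decoy_genes=2, decoys_per_gene=3,
    )
    world = generate_truth_set(params, seed=11, outdir=outdir)
    paths = simulate_alignments(world, Path(outdir) / "aln", seed=12)
    return {"world": world, "paths": paths, "params": params}
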
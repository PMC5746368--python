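import pytest

from tffg.models import FusionRecord, GenomicPosition, ProteinFeature, TranscriptModel
from tffg.synth import SyntheticConfig, generate_bundle


def make_transcript(
    gene="GENE1",
    transcript_id="GENE1.T1",
    chrom="chr1",
    strand="+",
    exons=((999, 1299), (1399, 1699)),
    cds_start=999,
    cds_end=1699,
):
    """Convenience builder; defaults give a 2-exon plus-strand transcript
    with a 600 nt fully-coding CDS (protein length 199, codons 1-100 on
    exon 1) interrupted by an intron after genomic base 1299 (0-based
    half-open coords)."""
    return TranscriptModel(
        gene=gene,
        transcript_id=transcript_id,
        protein_accession=f"{transcript_id}_P",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
    )


def make_fusion(
    g5="TFA", g3="PARTB", bp5=1298, bp3=5000, sample="S1", cancer="AML",
    frame="in-frame", chrom5="chr1", chrom3="chr2",
):
    return FusionRecord(
        sample_id=sample,
        cancer_type=cancer,
        gene_5p=g5,
        gene_3p=g3,
        breakpoint_5p=GenomicPosition(chrom5, bp5),
        breakpoint_3p=GenomicPosition(chrom3, bp3),
        frame_status=frame,
    )


@pytest.fixture
def transcript_plus():
    return make_transcript()


@pytest.fixture
def feature():
    return ProteinFeature("GENE1.T1_P", "DNA binding", "DBD", 10, 50)


@pytest.fixture(scope="session")
def bundle():
    """One shared synthetic cohort (seed 1) for cross-module tests."""
    return generate_bundle(SyntheticConfig(seed=1))
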
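"""Breakpoint-to-protein mapping and domain-retention calling, validated
against the exhaustive codon-enumeration oracle."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_fusion, make_transcript
from tffg.models import GenomicPosition, ProteinFeature, TFTargetMap
from tffg.retention import (
    ROLE_3P,
    ROLE_5P,
    MappingError,
    brute_force_retention,
    call_feature_retention,
    call_fusion_retention,
    classify_fusion,
    compute_frame_status,
    filter_in_frame,
    map_breakpoint_to_protein,
)


class TestBreakpointMapping:
    def test_plus_strand_codon_arithmetic(self, transcript_plus):
        """CDS base 300 at an exon end -> 100 complete codons retained."""
        pos = map_breakpoint_to_protein(
            GenomicPosition("chr1", 1298), transcript_plus, ROLE_5P
        )
        assert pos.aa_position == 100
        assert pos.offset_nt == 0
        assert pos.in_cds

    def test_breakpoint_before_cds(self):
        t = make_transcript(exons=((900, 1299), (1399, 1699)), cds_start=999)
        pos = map_breakpoint_to_protein(GenomicPosition("chr1", 950), t, ROLE_5P)
        assert pos.aa_position == 0
        assert not pos.in_cds

    def test_breakpoint_after_cds(self):
        t = make_transcript(exons=((999, 1299), (1399, 1799)), cds_start=999)
        pos = map_breakpoint_to_protein(GenomicPosition("chr1", 1750), t, ROLE_5P)
        assert pos.aa_position == t.protein_length
        assert not pos.in_cds

    def test_minus_strand_counts_from_genomic_end(self):
        """On the minus strand the 5' prefix is the genomically-last part."""
        t = make_transcript(strand="-")
        # retained: genomic >= 1400, i.e. CDS bases 1400..1698 = 299 nt
        pos = map_breakpoint_to_protein(GenomicPosition("chr1", 1400), t, ROLE_5P)
        assert pos.aa_position == 299 // 3
        assert pos.offset_nt == 299 % 3

    def test_3p_role_first_retained_codon(self, transcript_plus):
        # junction at genomic 1400 keeps a 299 nt CDS suffix: 2 residual
        # junction bases, first fully retained codon is 102
        pos = map_breakpoint_to_protein(GenomicPosition("chr1", 1400), transcript_plus, ROLE_3P)
        assert pos.offset_nt == 2
        assert pos.aa_position == 102
        # clean junction at 1399 starts exactly at codon 101
        clean = map_breakpoint_to_protein(GenomicPosition("chr1", 1399), transcript_plus, ROLE_3P)
        assert clean.offset_nt == 0
        assert clean.aa_position == 101

    def test_3p_nothing_retained(self, transcript_plus):
        pos = map_breakpoint_to_protein(GenomicPosition("chr1", 1699), transcript_plus, ROLE_3P)
        assert pos.aa_position == transcript_plus.protein_length + 1

    def test_strict_mode_rejects_intronic(self, transcript_plus):
        with pytest.raises(MappingError):
            map_breakpoint_to_protein(
                GenomicPosition("chr1", 1350), transcript_plus, ROLE_5P, strict=True
            )

    def test_wrong_chromosome_rejected(self, transcript_plus):
        with pytest.raises(MappingError):
            map_breakpoint_to_protein(GenomicPosition("chr9", 1298), transcript_plus, ROLE_5P)


class TestFeatureRetention:
    @pytest.mark.parametrize(
        "role,aa_pos,aa_start,aa_end,expected",
        [
            (ROLE_5P, 60, 10, 50, True),
            (ROLE_5P, 30, 10, 50, False),   # breakpoint inside the feature
            (ROLE_5P, 50, 10, 50, True),    # boundary included by default
            (ROLE_3P, 80, 100, 150, True),
            (ROLE_3P, 120, 100, 150, False),
            (ROLE_3P, 100, 100, 150, True),
        ],
    )
    def test_retention_rule(self, role, aa_pos, aa_start, aa_end, expected):
        from tffg.models import BreakpointProteinPosition

        pos = BreakpointProteinPosition("T1", aa_pos, True, 0)
        feat = ProteinFeature("P1", "DNA binding", "DBD", aa_start, aa_end)
        assert call_feature_retention(pos, feat, role) is expected

    def test_boundary_strictness_switch(self):
        from tffg.models import BreakpointProteinPosition

        pos = BreakpointProteinPosition("T1", 50, True, 0)
        feat = ProteinFeature("P1", "DNA binding", "DBD", 10, 50)
        assert call_feature_retention(pos, feat, ROLE_5P, include_boundary=True)
        assert not call_feature_retention(pos, feat, ROLE_5P, include_boundary=False)


@st.composite
def transcripts(draw):
    strand = draw(st.sampled_from("+-"))
    n_exons = draw(st.integers(2, 5))
    coding = [draw(st.integers(9, 60)) for _ in range(n_exons)]
    coding[-1] += (3 - sum(coding) % 3) % 3
    utr_l = draw(st.integers(0, 30))
    utr_r = draw(st.integers(0, 30))
    lengths = list(coding)
    lengths[0] += utr_l
    lengths[-1] += utr_r
    start = 1000
    exons = []
    for i, ln in enumerate(lengths):
        exons.append((start, start + ln))
        start += ln + draw(st.integers(30, 200))
    return make_transcript(
        strand=strand,
        exons=tuple(exons),
        cds_start=exons[0][0] + utr_l,
        cds_end=exons[-1][1] - utr_r,
    )


@settings(max_examples=300, deadline=None, derandomize=True)
@given(data=st.data(), t=transcripts(), role=st.sampled_from([ROLE_5P, ROLE_3P]))
def test_fast_path_agrees_with_codon_oracle(data, t, role):
    """The arithmetic retention call equals exhaustive codon enumeration
    for any breakpoint (exonic or intronic) and any feature interval."""
    span = (t.exons[0][0] - 10, t.exons[-1][1] + 10)
    bp = GenomicPosition(t.chrom, data.draw(st.integers(*span)))
    plen = t.protein_length
    a = data.draw(st.integers(1, plen))
    b = data.draw(st.integers(a, plen))
    feat = ProteinFeature(t.protein_accession, "domain", "F", a, b)
    pos = map_breakpoint_to_protein(bp, t, role)
    assert call_feature_retention(pos, feat, role) == brute_force_retention(t, bp, feat, role)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(data=st.data(), t=transcripts())
def test_5p_monotone_in_breakpoint(data, t):
    """Moving a 5' breakpoint downstream never flips retained -> lost."""
    plen = t.protein_length
    a = data.draw(st.integers(1, plen))
    b = data.draw(st.integers(a, plen))
    feat = ProteinFeature(t.protein_accession, "motif", "F", a, b)
    lo, hi = t.exons[0][0], t.exons[-1][1] - 1
    p1 = data.draw(st.integers(lo, hi))
    p2 = data.draw(st.integers(p1, hi))
    if t.strand == "-":
        p1, p2 = p2, p1  # downstream in transcript orientation
    r1 = call_feature_retention(
        map_breakpoint_to_protein(GenomicPosition(t.chrom, p1), t, ROLE_5P), feat, ROLE_5P
    )
    r2 = call_feature_retention(
        map_breakpoint_to_protein(GenomicPosition(t.chrom, p2), t, ROLE_5P), feat, ROLE_5P
    )
    assert r2 or not r1


def _tf_map(*tfs):
    m = TFTargetMap()
    for tf in tfs:
        m.add(tf, "TARGET1")
    return m


class TestClassification:
    def _models_and_features(self):
        t5 = make_transcript(gene="TFA", transcript_id="TFA.T1")
        t3 = make_transcript(gene="PARTB", transcript_id="PARTB.T1", chrom="chr2")
        models = {"TFA": [t5], "PARTB": [t3]}
        features = {
            "TFA.T1_P": [ProteinFeature("TFA.T1_P", "DNA binding", "DBD", 10, 50)],
            "PARTB.T1_P": [ProteinFeature("PARTB.T1_P", "helix", "H1", 90, 110)],
        }
        return models, features

    def test_5p_tffg_with_binding_retention(self):
        models, features = self._models_and_features()
        f = make_fusion(bp5=1298, bp3=1399)  # TF keeps 100 codons incl. DBD
        calls = call_fusion_retention(f, models, features)
        cl = classify_fusion(f, _tf_map("TFA"), calls)
        assert cl.orientation == "5'-TFFG"
        assert cl.binding_domain_retained

    def test_both_partners_tf(self):
        models, features = self._models_and_features()
        f = make_fusion(bp5=1298, bp3=1399)
        calls = call_fusion_retention(f, models, features)
        cl = classify_fusion(f, _tf_map("TFA", "PARTB"), calls)
        assert cl.orientation == "5'-3'-TFFG"

    def test_non_binding_category_not_enough(self):
        """A TF retaining only a 'helix' feature is not binding-retained."""
        models, features = self._models_and_features()
        f = make_fusion(bp5=1298, bp3=1399)
        calls = call_fusion_retention(f, models, features)
        cl = classify_fusion(f, _tf_map("PARTB"), calls)
        assert cl.orientation == "3'-TFFG"
        # 3' role keeps codons from 101 on; helix 90..110 straddles -> lost
        assert not cl.binding_domain_retained
        assert not cl.any_feature_retained

    def test_non_tf_fusion(self):
        models, features = self._models_and_features()
        f = make_fusion()
        cl = classify_fusion(f, _tf_map("SOMEONE"), [])
        assert cl.orientation == "non-TFFG"

    def test_multi_isoform_or_aggregation(self):
        """An extra isoform can only turn a feature retained, never lost."""
        t1 = make_transcript(gene="TFA", transcript_id="TFA.T1")
        # second isoform: same locus, shorter CDS -> breakpoint keeps more codons
        t2 = make_transcript(
            gene="TFA", transcript_id="TFA.T2",
            exons=((999, 1299), (1399, 1699)), cds_start=999, cds_end=1465,
        )
        features = {
            "TFA.T1_P": [ProteinFeature("TFA.T1_P", "DNA binding", "DBD", 90, 110)],
            "TFA.T2_P": [ProteinFeature("TFA.T2_P", "DNA binding", "DBD", 90, 100)],
        }
        f = make_fusion(bp5=1298, bp3=5000)
        one = call_fusion_retention(f, {"TFA": [t1]}, features, roles=(ROLE_5P,))
        both = call_fusion_retention(f, {"TFA": [t1, t2]}, features, roles=(ROLE_5P,))
        retained_one = any(c.retained_any_isoform for c in one)
        retained_both = any(c.retained_any_isoform for c in both)
        assert retained_both or not retained_one


class TestFrameFilter:
    def test_explicit_labels(self):
        records = [make_fusion(frame="in-frame"), make_fusion(frame="out-of-frame", sample="S2")]
        kept, excluded = filter_in_frame(records)
        assert [f.sample_id for f in kept] == ["S1"]
        assert [f.sample_id for f in excluded] == ["S2"]

    def test_unknown_frame_resolved_by_arithmetic(self):
        t5 = make_transcript(gene="TFA", transcript_id="TFA.T1")
        t3 = make_transcript(gene="PARTB", transcript_id="PARTB.T1", chrom="chr2")
        models = {"TFA": [t5], "PARTB": [t3]}
        # 5' junction keeps 300 CDS nt (offset 0); a 3' breakpoint keeping
        # a 299 nt suffix (offset 2) breaks the frame
        f_bad = make_fusion(bp5=1298, bp3=1400, frame="unknown")
        # 297 nt suffix (offset 0) preserves it
        f_good = make_fusion(bp5=1298, bp3=1402, frame="unknown", sample="S2")
        kept, excluded = filter_in_frame([f_bad, f_good], models)
        assert [f.sample_id for f in kept] == ["S2"]
        assert [f.sample_id for f in excluded] == ["S1"]

    def test_unknown_uncomputable_excluded(self):
        f = make_fusion(frame="unknown")
        kept, excluded = filter_in_frame([f], {})
        assert not kept and excluded == [f]

    def test_mixed_cohort_counts(self, bundle):
        _, _, _, fusions, _, _ = bundle
        labels = [f.frame_status for f in fusions]
        kept, excluded = filter_in_frame(fusions)
        assert len(kept) == labels.count("in-frame")
        assert len(kept) + len(excluded) == len(fusions)


def test_compute_frame_status_planted_cohort(bundle):
    """Planted junction fusions are in-frame by construction and the CDS
    arithmetic agrees with the generator's label."""
    gene_models, _, _, fusions, _, _ = bundle
    planted = [f for f in fusions if f.gene_5p in ("TF001", "TF002")]
    assert planted
    for f in planted:
        assert (
            compute_frame_status(f, gene_models[f.gene_5p], gene_models[f.gene_3p])
            == "in-frame"
        )
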
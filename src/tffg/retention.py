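"""Breakpoint-to-protein mapping and functional-domain retention calling.

The junction of an in-frame fusion splits each partner's coding sequence
into a retained and a lost part. Working in transcript orientation, a 5'
partner keeps every complete codon up to the junction and a 3' partner
keeps every complete codon from the junction onward. A feature interval
is called retained when it lies entirely on the retained side:

* 5' partner: retained iff ``aa_position >= aa_end`` of the feature;
* 3' partner: retained iff ``aa_position <= aa_start``.

A breakpoint strictly inside the feature interval is never retained —
partial domains are functionally suspect, so the conservative call is made
for both roles. Across isoforms the verdicts are OR-aggregated: a feature
counts as retained if any annotated isoform retains it.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

from .models import (
    BreakpointProteinPosition,
    FusionRecord,
    GenomicPosition,
    ProteinFeature,
    RetentionCall,
    TFFGClassification,
    TFTargetMap,
    TffgError,
    TranscriptModel,
)
from .vocab import BINDING_CATEGORIES, IN_FRAME, OUT_OF_FRAME, UNKNOWN_FRAME

ROLE_5P = "5p"
ROLE_3P = "3p"


class MappingError(TffgError):
    """A breakpoint cannot be placed on the transcript under strict mode."""


def _retained_cds_count(transcript: TranscriptModel, pos: int, role: str) -> tuple[int, bool]:
    """Number of CDS bases on the retained side of the junction, and whether
    the junction base itself is coding.

    The retained side is the transcript-order prefix ending at ``pos`` for a
    5' partner and the suffix starting at ``pos`` for a 3' partner.
    """
    plus = transcript.strand == "+"
    # genomic predicate for "base is retained"
    if (role == ROLE_5P) == plus:
        keep = lambda p: p <= pos  # noqa: E731
    else:
        keep = lambda p: p >= pos  # noqa: E731
    r = 0
    in_cds = False
    for s, e in transcript.exons:
        cs, ce = max(s, transcript.cds_start), min(e, transcript.cds_end)
        if cs >= ce:
            continue
        if cs <= pos < ce:
            in_cds = True
        if keep(cs) and keep(ce - 1):
            r += ce - cs
        elif keep(cs) or keep(ce - 1):
            # junction falls inside this CDS chunk
            if keep(cs):
                r += pos - cs + 1 if pos < ce else ce - cs
            else:
                r += ce - pos if pos >= cs else ce - cs
    return r, in_cds


def map_breakpoint_to_protein(
    breakpoint: GenomicPosition,
    transcript: TranscriptModel,
    role: str,
    strict: bool = False,
) -> BreakpointProteinPosition:
    """Convert a genomic breakpoint into protein coordinates on one isoform.

    ``role`` is ``"5p"`` or ``"3p"``. Breakpoints need not hit an exon
    boundary; any genomic base within the transcript span is mapped. When
    the breakpoint lies outside every exon, intronic bases contribute no
    coding sequence, so the mapping degrades gracefully to the nearest
    exon-junction behaviour unless ``strict`` is set, in which case a
    :class:`MappingError` is raised.
    """
    if role not in (ROLE_5P, ROLE_3P):
        raise ValueError(f"role must be '5p' or '3p', got {role!r}")
    if breakpoint.chrom != transcript.chrom:
        raise MappingError(
            f"breakpoint on {breakpoint.chrom} but transcript "
            f"{transcript.transcript_id} on {transcript.chrom}"
        )
    pos = breakpoint.pos
    exonic = any(s <= pos < e for s, e in transcript.exons)
    if strict and not exonic:
        raise MappingError(
            f"breakpoint {pos + 1} outside all exons of {transcript.transcript_id}"
        )

    r, in_cds = _retained_cds_count(transcript, pos, role)
    plen = transcript.protein_length
    if role == ROLE_5P:
        # complete codons retained from the start; the stop codon never counts
        aa = min(r // 3, plen)
        offset = r % 3
    else:
        # first fully retained codon; plen + 1 encodes "no residue retained"
        if r == 0:
            aa = plen + 1
        else:
            j = transcript.cds_len - r + 1  # 1-based CDS position of first kept nt
            aa = min((j + 1) // 3 + 1, plen + 1)  # ceil((j-1)/3) + 1, stop clamped
        offset = r % 3
    return BreakpointProteinPosition(
        transcript_id=transcript.transcript_id, aa_position=aa, in_cds=in_cds, offset_nt=offset
    )


def call_feature_retention(
    position: BreakpointProteinPosition,
    feature: ProteinFeature,
    role: str,
    include_boundary: bool = True,
) -> bool:
    """Decide whether ``feature`` survives the fusion on this isoform.

    ``include_boundary`` controls whether a breakpoint exactly at the
    feature edge (``aa_position == aa_end`` for 5', ``== aa_start`` for 3')
    still counts as retained (the default).
    """
    if role == ROLE_5P:
        return (
            position.aa_position >= feature.aa_end
            if include_boundary
            else position.aa_position > feature.aa_end
        )
    if role == ROLE_3P:
        return (
            position.aa_position <= feature.aa_start
            if include_boundary
            else position.aa_position < feature.aa_start
        )
    raise ValueError(f"role must be '5p' or '3p', got {role!r}")


def brute_force_retention(
    transcript: TranscriptModel,
    breakpoint: GenomicPosition,
    feature: ProteinFeature,
    role: str,
) -> bool:
    """Exhaustive oracle: enumerate each codon's genomic bases and test
    feature containment directly.

    A codon is retained when all three of its genomic bases lie on the
    retained side of the junction; the feature is retained when every codon
    of ``aa_start..aa_end`` is. Independent of the arithmetic fast path and
    used to validate it.
    """
    cds = transcript.cds_positions()
    plus = transcript.strand == "+"
    pos = breakpoint.pos
    if (role == ROLE_5P) == plus:
        kept = [p <= pos for p in cds]
    else:
        kept = [p >= pos for p in cds]
    codons = [kept[i : i + 3] for i in range(0, len(kept) - 3, 3)]  # stop codon dropped
    for aa in range(feature.aa_start, feature.aa_end + 1):
        if aa > len(codons) or not all(codons[aa - 1]):
            return False
    return True


def compute_frame_status(
    fusion: FusionRecord,
    transcripts_5p: Sequence[TranscriptModel],
    transcripts_3p: Sequence[TranscriptModel],
) -> str:
    """Infer frame status from CDS arithmetic when the caller left it unknown.

    The fusion is in frame when, for some isoform pair, the residual
    nucleotides on both sides of the junction complete a codon:
    ``(retained 5' CDS nt + 3' junction offset) % 3 == 0``. Breakpoints
    outside both CDS regions are uninformative and yield "unknown".
    """
    informative = False
    for t5 in transcripts_5p:
        p5 = map_breakpoint_to_protein(fusion.breakpoint_5p, t5, ROLE_5P)
        for t3 in transcripts_3p:
            p3 = map_breakpoint_to_protein(fusion.breakpoint_3p, t3, ROLE_3P)
            if not (p5.in_cds or p3.in_cds):
                continue
            informative = True
            if (p5.offset_nt + p3.offset_nt) % 3 == 0:
                return IN_FRAME
    return OUT_OF_FRAME if informative else UNKNOWN_FRAME


def filter_in_frame(
    fusions: Iterable[FusionRecord],
    gene_models: dict[str, list[TranscriptModel]] | None = None,
) -> tuple[list[FusionRecord], list[FusionRecord]]:
    """Keep in-frame fusions; resolve unknown frames from gene models when
    possible. Returns ``(kept, excluded)``.
    """
    kept: list[FusionRecord] = []
    excluded: list[FusionRecord] = []
    for f in fusions:
        status = f.frame_status
        if status == UNKNOWN_FRAME and gene_models is not None:
            t5 = gene_models.get(f.gene_5p, [])
            t3 = gene_models.get(f.gene_3p, [])
            if t5 and t3:
                status = compute_frame_status(f, t5, t3)
        (kept if status == IN_FRAME else excluded).append(f)
    return kept, excluded


def call_fusion_retention(
    fusion: FusionRecord,
    gene_models: dict[str, list[TranscriptModel]],
    features_by_accession: dict[str, list[ProteinFeature]],
    roles: Iterable[str] = (ROLE_5P, ROLE_3P),
    include_boundary: bool = True,
) -> list[RetentionCall]:
    """Retention calls for every feature of the fusion's partners.

    One :class:`RetentionCall` per (role, feature), with per-isoform
    verdicts OR-aggregated via ``retained_any_isoform``.
    """
    calls: list[RetentionCall] = []
    for role in roles:
        gene = fusion.gene_5p if role == ROLE_5P else fusion.gene_3p
        bp = fusion.breakpoint_5p if role == ROLE_5P else fusion.breakpoint_3p
        transcripts = gene_models.get(gene, [])
        feats: dict[int, RetentionCall] = {}
        for t in transcripts:
            try:
                pos = map_breakpoint_to_protein(bp, t, role)
            except MappingError:
                continue
            for feat in features_by_accession.get(t.protein_accession, []):
                if feat.aa_end > t.protein_length:
                    continue  # annotation does not fit this isoform
                verdict = call_feature_retention(pos, feat, role, include_boundary)
                key = id(feat)
                if key not in feats:
                    feats[key] = RetentionCall(fusion=fusion, role=role, feature=feat)
                feats[key].per_isoform[t.transcript_id] = verdict
        calls.extend(feats.values())
    return calls


def classify_fusion(
    fusion: FusionRecord,
    tf_map: TFTargetMap,
    retention_calls: Sequence[RetentionCall],
) -> TFFGClassification:
    """Orientation from TF membership of the partners; binding verdict from
    the retained features of the TF partner(s)."""
    tf5 = fusion.gene_5p in tf_map
    tf3 = fusion.gene_3p in tf_map
    if tf5 and tf3:
        orientation = "5'-3'-TFFG"
    elif tf5:
        orientation = "5'-TFFG"
    elif tf3:
        orientation = "3'-TFFG"
    else:
        orientation = "non-TFFG"

    tf_roles = {r for r, is_tf in ((ROLE_5P, tf5), (ROLE_3P, tf3)) if is_tf}
    tf_calls = [c for c in retention_calls if c.role in tf_roles]
    any_retained = any(c.retained_any_isoform for c in tf_calls)
    binding = any(
        c.retained_any_isoform and c.feature.category in BINDING_CATEGORIES for c in tf_calls
    )
    return TFFGClassification(
        fusion=fusion,
        orientation=orientation,
        binding_domain_retained=binding,
        any_feature_retained=any_retained,
        tf_has_features=bool(tf_calls) or not tf_roles,
    )
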
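"""Controlled vocabularies shared across the pipeline.

Feature categories follow the UniProt feature-key nomenclature (34 keys of
the sequence-annotation section). The binding-related subset is the seven
categories that carry transcription-factor activity and drive the
binding-retention filter.
"""

from __future__ import annotations

#: The 34 protein-feature categories surveyed for retention.
FEATURE_CATEGORIES: frozenset[str] = frozenset({
    "active site",
    "beta strand",
    "binding site",
    "calcium binding",
    "chain",
    "coiled coil",
    "compositional bias",
    "cross-link",
    "DNA binding",
    "domain",
    "glycosylation site",
    "helix",
    "initiator methionine",
    "intramembrane",
    "lipidation",
    "metal binding",
    "modified residue",
    "motif",
    "mutagenesis",
    "natural variant",
    "non-standard residue",
    "nucleotide binding",
    "peptide",
    "propeptide",
    "region",
    "repeat",
    "signal peptide",
    "site",
    "topological domain",
    "transit peptide",
    "transmembrane",
    "turn",
    "zinc finger",
    "disulfide bond",
})

#: Categories with direct TF activity; retention of any of these makes a
#: fusion "binding-domain-retained".
BINDING_CATEGORIES: frozenset[str] = frozenset({
    "calcium binding",
    "DNA binding",
    "domain",
    "metal binding",
    "motif",
    "nucleotide binding",
    "zinc finger",
})

#: TCGA study codes of the 13 cancer types of the pan-cancer cohort.
CANCER_TYPES: tuple[str, ...] = (
    "BLCA", "BRCA", "GBM", "HNSC", "KIRC", "AML", "LGG",
    "LUAD", "LUSC", "OV", "PRAD", "SKCM", "THCA",
)

IN_FRAME = "in-frame"
OUT_OF_FRAME = "out-of-frame"
UNKNOWN_FRAME = "unknown"

#: Fixed synonym map for the frame column of fusion-call tables. Unknown
#: strings map to "unknown", never silently to in-frame.
FRAME_SYNONYMS: dict[str, str] = {
    "in-frame": IN_FRAME,
    "in_frame": IN_FRAME,
    "inframe": IN_FRAME,
    "in frame": IN_FRAME,
    "frame-shift": OUT_OF_FRAME,
    "frame_shift": OUT_OF_FRAME,
    "frameshift": OUT_OF_FRAME,
    "out-of-frame": OUT_OF_FRAME,
    "out_of_frame": OUT_OF_FRAME,
    "out of frame": OUT_OF_FRAME,
    "unknown": UNKNOWN_FRAME,
    "na": UNKNOWN_FRAME,
    "": UNKNOWN_FRAME,
}


def normalize_frame(value: str) -> str:
    """Map a free-text frame label onto {in-frame, out-of-frame, unknown}."""
    return FRAME_SYNONYMS.get(str(value).strip().lower(), UNKNOWN_FRAME)
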
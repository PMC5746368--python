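"""Core domain types.

Genomic coordinates are 1-based inclusive in all external files and
converted to 0-based half-open intervals on ingestion; a *breakpoint* is
stored as the 0-based index of the junction base — the last retained base
of the 5' partner's transcript, or the first retained base of the 3'
partner's transcript, both in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .vocab import FEATURE_CATEGORIES, IN_FRAME, OUT_OF_FRAME, UNKNOWN_FRAME


class TffgError(Exception):
    """Base class for all package errors."""


class FormatError(TffgError):
    """A file violates its documented dialect (missing column, bad value)."""


class ValidationError(TffgError):
    """A record violates a type invariant."""


class ConfigError(TffgError):
    """An invalid configuration value; the message names the field."""


class GenerationError(TffgError):
    """The synthetic generator cannot satisfy the requested configuration."""


@dataclass(frozen=True)
class GenomicPosition:
    chrom: str
    pos: int  # 0-based index of the base

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"genomic position must be >= 1 (1-based), got {self.pos + 1}")


@dataclass(frozen=True)
class FusionRecord:
    """One fusion call in one tumor sample."""

    sample_id: str
    cancer_type: str
    gene_5p: str
    gene_3p: str
    breakpoint_5p: GenomicPosition
    breakpoint_3p: GenomicPosition
    frame_status: str = UNKNOWN_FRAME

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be nonempty")
        if self.frame_status not in (IN_FRAME, OUT_OF_FRAME, UNKNOWN_FRAME):
            raise ValidationError(f"invalid frame_status {self.frame_status!r}")

    @property
    def is_self_fusion(self) -> bool:
        return self.gene_5p == self.gene_3p

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_5p, self.gene_3p)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript isoform.

    ``exons`` are non-overlapping 0-based half-open intervals sorted by
    genomic coordinate regardless of strand; ``cds_start``/``cds_end`` bound
    the coding region (half-open) and must lie within the exon union.
    """

    gene: str
    transcript_id: str
    protein_accession: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: strand must be '+' or '-'")
        if len(self.exons) < 1:
            raise ValidationError(f"{self.transcript_id}: needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"{self.transcript_id}: empty exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = e
        if not (self.exons[0][0] <= self.cds_start < self.cds_end <= self.exons[-1][1]):
            raise ValidationError(f"{self.transcript_id}: CDS outside exon span")
        n = self.cds_len
        if n == 0:
            raise ValidationError(f"{self.transcript_id}: CDS does not overlap any exon")
        if n % 3 != 0:
            raise ValidationError(f"{self.transcript_id}: CDS length {n} not a multiple of 3")

    @property
    def cds_len(self) -> int:
        return sum(
            max(0, min(e, self.cds_end) - max(s, self.cds_start)) for s, e in self.exons
        )

    @property
    def protein_length(self) -> int:
        """Residue count, stop codon excluded."""
        return self.cds_len // 3 - 1

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcript (5'->3') order."""
        pos = [
            p
            for s, e in self.exons
            for p in range(max(s, self.cds_start), min(e, self.cds_end))
        ]
        return pos[::-1] if self.strand == "-" else pos

    def exon_junctions(self) -> list[int]:
        """0-based positions of the last base of each non-terminal exon,
        in transcript orientation (candidate 5'-side breakpoints)."""
        if self.strand == "+":
            return [e - 1 for _, e in self.exons[:-1]]
        return [s for s, _ in self.exons[1:]][::-1]


@dataclass(frozen=True)
class ProteinFeature:
    """A UniProt-style feature interval on one protein accession.

    ``aa_start``/``aa_end`` are 1-based inclusive residue positions.
    """

    protein_accession: str
    category: str
    name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if self.category not in FEATURE_CATEGORIES:
            raise ValidationError(f"unknown feature category {self.category!r}")
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValidationError(
                f"feature {self.name!r}: invalid span {self.aa_start}..{self.aa_end}"
            )


class TFTargetMap:
    """TF symbol -> set of target gene symbols, with per-pair provenance."""

    def __init__(self) -> None:
        self._targets: dict[str, set[str]] = {}
        self._provenance: dict[tuple[str, str], str] = {}

    def add(self, tf: str, target: str, provenance: str = "user") -> None:
        tf, target = tf.upper(), target.upper()
        self._targets.setdefault(tf, set()).add(target)
        self._provenance[(tf, target)] = provenance

    def __contains__(self, tf: str) -> bool:
        return tf.upper() in self._targets

    def __len__(self) -> int:
        return len(self._targets)

    @property
    def tfs(self) -> set[str]:
        return set(self._targets)

    def targets(self, tf: str) -> set[str]:
        return set(self._targets.get(tf.upper(), set()))

    def provenance(self, tf: str, target: str) -> str | None:
        return self._provenance.get((tf.upper(), target.upper()))

    def iter_pairs(self):
        for (tf, target), prov in sorted(self._provenance.items()):
            yield tf, target, prov


class ExpressionMatrix:
    """Genes x samples matrix of log2(normalized count + 1) values."""

    def __init__(self, values: pd.DataFrame, sample_cancer: dict[str, str]):
        if values.index.duplicated().any():
            raise ValidationError("duplicate gene identifiers in expression matrix")
        if values.columns.duplicated().any():
            raise ValidationError("duplicate sample identifiers in expression matrix")
        if (values.to_numpy() < 0).any():
            raise ValidationError("expression values must be >= 0 on the log2(count+1) scale")
        missing = set(values.columns) - set(sample_cancer)
        if missing:
            raise ValidationError(f"samples without cancer-type label: {sorted(missing)[:5]}")
        self.values = values
        self.sample_cancer = dict(sample_cancer)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, cancer_type: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_cancer[s] == cancer_type]


@dataclass(frozen=True)
class BreakpointProteinPosition:
    """Protein-coordinate image of a genomic breakpoint on one isoform.

    For a 5' partner, ``aa_position`` is the number of complete codons
    retained; for a 3' partner, the 1-based index of the first fully
    retained codon (``protein_length + 1`` when no coding residue
    survives). ``offset_nt`` counts the residual junction nucleotides that
    do not form a complete codon.
    """

    transcript_id: str
    aa_position: int
    in_cds: bool
    offset_nt: int

    def __post_init__(self) -> None:
        if self.offset_nt not in (0, 1, 2):
            raise ValidationError(f"offset_nt must be in 0..2, got {self.offset_nt}")


@dataclass
class RetentionCall:
    """Verdict on whether one feature is retained in one fusion event."""

    fusion: FusionRecord
    role: str  # "5p" or "3p"
    feature: ProteinFeature
    per_isoform: dict[str, bool] = field(default_factory=dict)

    @property
    def retained_any_isoform(self) -> bool:
        return any(self.per_isoform.values())


@dataclass(frozen=True)
class TFFGClassification:
    """Orientation and binding-retention verdict for one fusion event."""

    fusion: FusionRecord
    orientation: str  # 5'-TFFG | 3'-TFFG | 5'-3'-TFFG | non-TFFG
    binding_domain_retained: bool
    any_feature_retained: bool = False
    tf_has_features: bool = True


@dataclass(frozen=True)
class TFScore:
    """Per-TF recurrence summary (one row of the score table)."""

    tf: str
    n_cancer_types: int
    n_partners: int
    n_breakpoints: int
    dof: int
    obs: int
    maii: float
    tmaii: float
    tf_class: str  # eTFinFG | peTFinFG | neither
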
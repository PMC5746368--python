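"""Synthetic cohort generator with known ground truth.

Emulates the five inputs of the pipeline — fusion calls, gene models,
protein features, TF-target map, expression matrix — at desk scale, with
every quantity the downstream stages estimate planted and recorded:

* per-feature retention status of every planted fusion (recomputed at
  generation time with the exhaustive codon oracle, never the fast path);
* per-TF recurrence structure (distinct cancer types, partners,
  breakpoints and positive samples), so expected DoF/MAII values are
  known exactly;
* per-gene planted expression shifts for the DETG stage.

Breakpoints are placed only at exon junctions, matching the exon-junction
resolution of fusion callers; frame status is assigned from CDS
arithmetic. Expression noise is Gaussian on the log2(count+1) scale,
truncated at zero. Everything is driven by one integer seed; two runs
with the same config produce byte-identical files.

Ground truth is emitted as separate machine-readable tables that the
pipeline itself never reads.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .models import (
    ConfigError,
    ExpressionMatrix,
    FusionRecord,
    GenerationError,
    GenomicPosition,
    ProteinFeature,
    TFTargetMap,
    TranscriptModel,
)
from .retention import ROLE_3P, ROLE_5P, brute_force_retention, compute_frame_status
from .vocab import BINDING_CATEGORIES, FEATURE_CATEGORIES

#: (cancer types, partners, breakpoints, positive samples) planted by
#: default: one highly recurrent single-isofusion TF and one TF with a
#: combinatorially diverse but weakly recurrent fusion profile.
DEFAULT_PLANTED = ((1, 1, 1, 15), (3, 3, 5, 10))

_NON_BINDING = sorted(FEATURE_CATEGORIES - BINDING_CATEGORIES)
_BINDING = sorted(BINDING_CATEGORIES)


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 60
    n_tfs: int = 15
    n_samples_per_cancer: int = 40
    cancer_types: tuple[str, ...] = ("AML", "PRAD", "KIRC")
    n_fusion_events: int = 60
    fraction_tf_fusions: float = 0.6
    planted_detg_log2fc: float = 2.0
    planted_detg_fraction: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0
    planted_tfs: tuple[tuple[int, int, int, int], ...] = DEFAULT_PLANTED

    def __post_init__(self) -> None:
        if self.n_tfs > self.n_genes:
            raise ConfigError("n_tfs: must not exceed n_genes")
        for name in ("n_genes", "n_tfs", "n_samples_per_cancer", "n_fusion_events"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be >= 1")
        for name in ("fraction_tf_fusions", "planted_detg_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name}: must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd: must be >= 0")
        if not self.cancer_types:
            raise ConfigError("cancer_types: must be nonempty")
        if len(self.planted_tfs) > self.n_tfs:
            raise ConfigError("planted_tfs: more planted structures than TFs")
        for planted in self.planted_tfs:
            n_ct, n_p, n_b, obs = planted
            if obs < max(n_ct, n_p, n_b):
                raise ConfigError(f"planted_tfs: obs {obs} below diversity counts {planted}")
            if n_ct > len(self.cancer_types):
                raise ConfigError("planted_tfs: more cancer types than configured")


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator planted."""

    #: rows: fusion identity x role x feature -> retention flag from the codon oracle
    retention: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: rows: tf -> expected (n_cancer_types, n_partners, n_breakpoints, obs)
    tf_counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: rows: gene x cancer_type -> planted log2 shift (signed)
    detg: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.retention.to_csv(outdir / "truth_retention.tsv", sep="\t", index=False)
        self.tf_counts.to_csv(outdir / "truth_tf_counts.tsv", sep="\t", index=False)
        self.detg.to_csv(outdir / "truth_detg.tsv", sep="\t", index=False)


def _gene_names(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    tfs = [f"TF{i:03d}" for i in range(1, config.n_tfs + 1)]
    others = [f"GEN{i:03d}" for i in range(1, config.n_genes - config.n_tfs + 1)]
    return tfs, others


def _make_transcript(
    rng: np.random.Generator,
    gene: str,
    tx_index: int,
    chrom: str,
    start: int,
    strand: str,
    regular: bool,
) -> TranscriptModel:
    """One isoform. ``regular`` forces 7 exons with codon-aligned coding
    chunks (every junction sits on a codon boundary), used for the first
    isoform of each gene so planted junction-to-junction fusions are
    in-frame by construction; other isoforms get 2-6 exons with arbitrary
    coding chunk lengths."""
    if regular:
        n_exons = 7
        coding = [90] * n_exons
    else:
        n_exons = int(rng.integers(2, 7))
        coding = [int(rng.integers(20, 120)) for _ in range(n_exons)]
        excess = sum(coding) % 3
        coding[-1] += (3 - excess) % 3  # total CDS a multiple of 3
    utr5 = int(rng.integers(20, 80))
    utr3 = int(rng.integers(20, 80))
    lengths = list(coding)
    lengths[0] += utr5 if strand == "+" else utr3
    lengths[-1] += utr3 if strand == "+" else utr5
    introns = [int(rng.integers(60, 400)) for _ in range(n_exons - 1)]
    exons = []
    pos = start
    for i, ln in enumerate(lengths):
        exons.append((pos, pos + ln))
        pos += ln + (introns[i] if i < n_exons - 1 else 0)
    left_utr = utr5 if strand == "+" else utr3
    right_utr = utr3 if strand == "+" else utr5
    tx_id = f"{gene}.T{tx_index}"
    return TranscriptModel(
        gene=gene,
        transcript_id=tx_id,
        protein_accession=f"{tx_id}_P",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=exons[0][0] + left_utr,
        cds_end=exons[-1][1] - right_utr,
    )


def generate_gene_models(config: SyntheticConfig) -> dict[str, list[TranscriptModel]]:
    """1-3 isoforms per gene; both strands represented; CDS always a
    multiple of 3. Each gene lives on its own chromosome arm so loci never
    collide."""
    rng = np.random.default_rng(config.seed)
    tfs, others = _gene_names(config)
    models: dict[str, list[TranscriptModel]] = {}
    for idx, gene in enumerate(tfs + others):
        chrom = f"chr{idx % 22 + 1}"
        start = 1_000_000 + (idx // 22) * 200_000
        strand = "+" if idx % 2 == 0 else "-"
        n_iso = int(rng.integers(1, 4))
        models[gene] = [
            _make_transcript(rng, gene, k + 1, chrom, start, strand, regular=(k == 0))
            for k in range(n_iso)
        ]
    return models


def generate_features(
    config: SyntheticConfig, gene_models: dict[str, list[TranscriptModel]]
) -> dict[str, list[ProteinFeature]]:
    """2-5 features per protein. The first isoform of every TF carries a
    DNA-binding feature in residues 5-25, i.e. upstream of every exon
    junction of the regular 7x30-codon layout, so a junction fusion with
    the TF in 5' position always retains it."""
    rng = np.random.default_rng(config.seed + 1)
    tfs, _ = _gene_names(config)
    tf_set = set(tfs)
    features: dict[str, list[ProteinFeature]] = {}
    for gene in sorted(gene_models):
        for k, t in enumerate(gene_models[gene]):
            plen = t.protein_length
            feats = []
            if gene in tf_set and k == 0:
                feats.append(
                    ProteinFeature(t.protein_accession, "DNA binding", "DBD_syn", 5, 25)
                )
            for _ in range(int(rng.integers(2, 6))):
                lo = int(rng.integers(1, max(2, plen - 10)))
                hi = int(rng.integers(lo, min(plen, lo + 60)) + 1)
                cat_pool = _BINDING if rng.random() < 0.3 else _NON_BINDING
                cat = cat_pool[int(rng.integers(len(cat_pool)))]
                feats.append(
                    ProteinFeature(t.protein_accession, cat, f"{cat[:3].upper()}_syn", lo, min(hi, plen))
                )
            features[t.protein_accession] = feats
    return features


def generate_tf_targets(config: SyntheticConfig) -> TFTargetMap:
    rng = np.random.default_rng(config.seed + 2)
    tfs, others = _gene_names(config)
    tf_map = TFTargetMap()
    for tf in tfs:
        k = int(rng.integers(8, min(25, len(others)) + 1))
        targets = rng.choice(len(others), size=k, replace=False)
        for t in sorted(targets):
            tf_map.add(tf, others[t], "synthetic")
    return tf_map


def _sample_ids(config: SyntheticConfig) -> dict[str, list[str]]:
    return {
        ct: [f"{ct}_S{i:03d}" for i in range(1, config.n_samples_per_cancer + 1)]
        for ct in config.cancer_types
    }


def generate_fusions(
    config: SyntheticConfig, gene_models: dict[str, list[TranscriptModel]]
) -> tuple[list[FusionRecord], GroundTruth]:
    """Planted recurrent TF fusions plus random background events.

    Planted TFs occupy the 5' position with breakpoints cycling through
    distinct junctions of their first (codon-aligned) isoform, so the
    intended (cancer types, partners, breakpoints, samples) structure —
    hence DoF and MAII — is reproduced exactly by the scoring stage.
    Background events draw random gene pairs and junctions; their frame
    status comes from CDS arithmetic.
    """
    rng = np.random.default_rng(config.seed + 3)
    tfs, others = _gene_names(config)
    samples = _sample_ids(config)
    used_samples: dict[str, int] = {ct: 0 for ct in config.cancer_types}
    fusions: list[FusionRecord] = []
    truth_counts = []
    seen_pairs: set[tuple[str, str, str]] = set()

    # --- planted recurrent structures ------------------------------------
    partner_pool = list(others)
    for p_idx, (n_ct, n_p, n_b, obs) in enumerate(config.planted_tfs):
        tf = tfs[p_idx]
        t5 = gene_models[tf][0]
        junctions = t5.exon_junctions()
        if n_b > len(junctions):
            raise GenerationError(
                f"planted TF {tf}: {n_b} breakpoints requested, "
                f"only {len(junctions)} junctions available"
            )
        bps = junctions[:n_b]
        if n_p > len(partner_pool):
            raise GenerationError(
                f"planted TF {tf}: {n_p} partners requested, only "
                f"{len(partner_pool)} non-TF genes left"
            )
        partners = [partner_pool.pop(0) for _ in range(n_p)]
        cancers = list(config.cancer_types[:n_ct])
        if obs > n_ct * config.n_samples_per_cancer:
            raise GenerationError(f"planted TF {tf}: obs {obs} exceeds available samples")
        for i in range(obs):
            ct = cancers[i % n_ct]
            partner = partners[i % n_p]
            bp5 = bps[i % n_b]
            t3 = gene_models[partner][0]
            j3 = t3.exon_junctions()
            # first retained base of the 3' transcript: base after a junction
            bp3 = _junction_to_3p_pos(t3, j3[0])
            sid = samples[ct][used_samples[ct] % config.n_samples_per_cancer]
            used_samples[ct] += 1
            if (sid, tf, partner) in seen_pairs:
                raise GenerationError(
                    f"planted TF {tf}: cannot place {obs} distinct (sample, fusion) "
                    f"events with {config.n_samples_per_cancer} samples per cancer type"
                )
            fusions.append(
                FusionRecord(
                    sample_id=sid,
                    cancer_type=ct,
                    gene_5p=tf,
                    gene_3p=partner,
                    breakpoint_5p=GenomicPosition(t5.chrom, bp5),
                    breakpoint_3p=GenomicPosition(t3.chrom, bp3),
                    frame_status="in-frame",
                )
            )
            seen_pairs.add((sid, tf, partner))
        truth_counts.append(
            {"tf": tf, "n_cancer_types": n_ct, "n_partners": n_p,
             "n_breakpoints": n_b, "obs": obs}
        )

    # --- background events ------------------------------------------------
    # planted TFs are reserved: background events never touch them, so the
    # planted recurrence structure survives to the scoring stage unchanged
    planted_names = set(tfs[: len(config.planted_tfs)])
    free_tfs = [t for t in tfs if t not in planted_names]
    all_genes = [g for g in tfs + others if g not in planted_names]
    attempts = 0
    placed = 0
    while placed < config.n_fusion_events:
        attempts += 1
        if attempts > config.n_fusion_events * 50:
            raise GenerationError(
                f"could not place {config.n_fusion_events} background events "
                f"(placed {placed}); cohort too small"
            )
        if free_tfs and rng.random() < config.fraction_tf_fusions:
            g5 = free_tfs[int(rng.integers(len(free_tfs)))]
        else:
            g5 = others[int(rng.integers(len(others)))]
        g3 = all_genes[int(rng.integers(len(all_genes)))]
        if g3 == g5:
            continue
        ct = config.cancer_types[int(rng.integers(len(config.cancer_types)))]
        sid = samples[ct][int(rng.integers(config.n_samples_per_cancer))]
        if (sid, g5, g3) in seen_pairs:
            continue
        t5 = gene_models[g5][int(rng.integers(len(gene_models[g5])))]
        t3 = gene_models[g3][int(rng.integers(len(gene_models[g3])))]
        j5, j3 = t5.exon_junctions(), t3.exon_junctions()
        if not j5 or not j3:
            continue
        bp5 = j5[int(rng.integers(len(j5)))]
        bp3 = _junction_to_3p_pos(t3, j3[int(rng.integers(len(j3)))])
        record = FusionRecord(
            sample_id=sid,
            cancer_type=ct,
            gene_5p=g5,
            gene_3p=g3,
            breakpoint_5p=GenomicPosition(t5.chrom, bp5),
            breakpoint_3p=GenomicPosition(t3.chrom, bp3),
            frame_status="unknown",
        )
        status = compute_frame_status(record, gene_models[g5], gene_models[g3])
        record = FusionRecord(
            sample_id=sid, cancer_type=ct, gene_5p=g5, gene_3p=g3,
            breakpoint_5p=record.breakpoint_5p, breakpoint_3p=record.breakpoint_3p,
            frame_status=status,
        )
        fusions.append(record)
        seen_pairs.add((sid, g5, g3))
        placed += 1

    truth = GroundTruth(tf_counts=pd.DataFrame(truth_counts))
    return fusions, truth


def _junction_to_3p_pos(t: TranscriptModel, junction_pos: int) -> int:
    """Convert a 5'-side junction (last base of an exon in transcript
    orientation) into the matching 3'-side breakpoint (first base of the
    next exon in transcript orientation)."""
    if t.strand == "+":
        ends = [e for _, e in t.exons[:-1]]
        i = ends.index(junction_pos + 1)
        return t.exons[i + 1][0]
    starts = [s for s, _ in t.exons[1:]][::-1]
    i = starts.index(junction_pos)
    # next exon in transcript orientation is the genomically preceding one
    ordered = list(t.exons)[::-1]
    return ordered[i + 1][1] - 1


def annotate_truth_retention(
    fusions: Sequence[FusionRecord],
    gene_models: dict[str, list[TranscriptModel]],
    features: dict[str, list[ProteinFeature]],
    truth: GroundTruth,
) -> GroundTruth:
    """Record the oracle retention verdict for every
    (fusion, role, feature) of the cohort, OR-aggregated over isoforms,
    using only the exhaustive codon-enumeration oracle."""
    rows = []
    for idx, f in enumerate(fusions):
        for role, gene, bp in (
            (ROLE_5P, f.gene_5p, f.breakpoint_5p),
            (ROLE_3P, f.gene_3p, f.breakpoint_3p),
        ):
            verdicts: dict[str, bool] = {}
            for t in gene_models.get(gene, []):
                for feat in features.get(t.protein_accession, []):
                    if feat.aa_end > t.protein_length:
                        continue
                    key = f"{feat.category}|{feat.name}|{feat.aa_start}|{feat.aa_end}"
                    v = brute_force_retention(t, bp, feat, role)
                    verdicts[key] = verdicts.get(key, False) or v
            for key, v in sorted(verdicts.items()):
                cat, name, a, b = key.split("|")
                rows.append(
                    {"fusion_index": idx, "sample_id": f.sample_id, "gene_5p": f.gene_5p,
                     "gene_3p": f.gene_3p, "role": role, "category": cat, "name": name,
                     "aa_start": int(a), "aa_end": int(b), "retained": v}
                )
    truth.retention = pd.DataFrame(rows)
    return truth


def generate_expression(
    config: SyntheticConfig,
    fusions: Sequence[FusionRecord],
    tf_targets: TFTargetMap,
    truth: GroundTruth | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Baseline log2(count+1) expression with planted target-gene shifts.

    For every planted TF fusion pair, a fixed fraction of the TF's targets
    is shifted by ``planted_detg_log2fc`` (alternating sign) in the
    fusion-positive samples of the fusion's cancer type only.
    """
    rng = np.random.default_rng(config.seed + 4)
    samples = _sample_ids(config)
    all_samples = [s for ct in config.cancer_types for s in samples[ct]]
    if not all_samples:
        raise GenerationError("empty sample set")
    tfs, others = _gene_names(config)
    genes = tfs + others
    baseline = rng.uniform(4.0, 10.0, size=len(genes))
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, (len(genes), len(all_samples)))

    df = pd.DataFrame(values, index=genes, columns=all_samples)
    truth = truth or GroundTruth()
    planted_tf_names = {f"TF{i + 1:03d}" for i in range(len(config.planted_tfs))}
    positive: dict[tuple[str, str], set[str]] = {}
    for f in fusions:
        if f.gene_5p in planted_tf_names:
            positive.setdefault((f.gene_5p, f.cancer_type), set()).add(f.sample_id)
    detg_rows = []
    # each gene is shifted on behalf of at most one planted TF, so one TF's
    # planted effect never leaks into another TF's fusion-negative group
    claimed: dict[str, str] = {}
    for (tf, ct), pos_samples in sorted(positive.items()):
        targets = sorted(tf_targets.targets(tf))
        n_shift = int(round(config.planted_detg_fraction * len(targets)))
        shiftable = [g for g in targets if claimed.get(g, tf) == tf][:n_shift]
        for gene in shiftable:
            claimed[gene] = tf
        for j, gene in enumerate(shiftable):
            shift = config.planted_detg_log2fc * (1 if j % 2 == 0 else -1)
            df.loc[gene, sorted(pos_samples)] += shift
            detg_rows.append(
                {"tf": tf, "cancer_type": ct, "gene": gene,
                 "log2fc": shift, "direction": "up" if shift >= 0 else "down"}
            )
    df = df.clip(lower=0.0)
    sample_cancer = {s: ct for ct in config.cancer_types for s in samples[ct]}
    truth.detg = pd.DataFrame(detg_rows)
    return ExpressionMatrix(df, sample_cancer), truth


def generate_bundle(config: SyntheticConfig, outdir: str | Path | None = None):
    """Generate the full consistent dataset; optionally write all files.

    Returns ``(gene_models, features, tf_map, fusions, expression, truth)``.
    """
    gene_models = generate_gene_models(config)
    features = generate_features(config, gene_models)
    tf_map = generate_tf_targets(config)
    fusions, truth = generate_fusions(config, gene_models)
    truth = annotate_truth_retention(fusions, gene_models, features, truth)
    expression, truth = generate_expression(config, fusions, tf_map, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tio.write_gene_models(gene_models, outdir / "gene_models.tsv")
        tio.write_features(features, outdir / "features.tsv")
        tio.write_tf_targets(tf_map, outdir / "tf_targets.tsv")
        tio.write_fusions(fusions, outdir / "fusions.tsv")
        tio.write_expression(expression, outdir / "expression.tsv", outdir / "samples.tsv")
        truth.write(outdir)
    return gene_models, features, tf_map, fusions, expression, truth
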
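"""End-to-end orchestration: in-frame filter -> TF intersection ->
retention -> enrichment -> binding filter -> scoring -> recurrence filter
-> DETG -> network, with a machine-readable funnel summary per stage."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .detg import FC_THRESHOLD, Q_THRESHOLD, results_to_frame, run_detg
from .enrichment import test_feature_enrichment
from .models import ConfigError, TffgError
from .network import build_network, degree_report
from .retention import call_fusion_retention, classify_fusion, filter_in_frame
from .scoring import recurrent_tffgs, score_all_tfs, scores_to_frame, score_count_table
from .vocab import BINDING_CATEGORIES

log = logging.getLogger("tffg")


@dataclass
class RunConfig:
    fusions: str
    gene_models: str
    features: str
    tf_targets: str
    expression: str | None = None
    samples: str | None = None
    binding_categories: tuple[str, ...] = tuple(sorted(BINDING_CATEGORIES))
    enrichment_alpha: float = 0.001
    min_recurrence: int = 2
    fc_threshold: float = FC_THRESHOLD
    q_threshold: float = Q_THRESHOLD
    q_threshold_frame: float = 0.2
    include_boundary: bool = True
    counting_unit: str = "event"
    strict_mapping: bool = False
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("enrichment_alpha", "fc_threshold", "q_threshold", "q_threshold_frame"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be positive")
        if self.min_recurrence < 1:
            raise ConfigError("min_recurrence: must be >= 1")
        for name in ("fusions", "gene_models", "features", "tf_targets"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name}: file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        if "binding_categories" in kwargs:
            kwargs["binding_categories"] = tuple(kwargs["binding_categories"])
        return cls(**kwargs, extra=extra)


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage, writing each stage's table under ``outdir``.

    Returns the run summary (also written to ``summary.json``) with the
    pipeline-funnel counts: events in, in-frame, TFFG, feature-retained,
    orientation split, binding-retained, recurrent, DETG-tested.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    skip_report: list[str] = []

    fusions = tio.read_fusions(config.fusions)
    gene_models = tio.read_gene_models(config.gene_models)
    plengths = {
        t.protein_accession: t.protein_length
        for models in gene_models.values()
        for t in models
    }
    features = tio.read_features(config.features, protein_lengths=plengths)
    tf_map = tio.read_tf_targets(config.tf_targets)
    summary["stages"]["input_events"] = len(fusions)
    log.info("input: %d fusion events", len(fusions))

    in_frame, excluded = filter_in_frame(fusions, gene_models)
    summary["stages"]["in_frame"] = len(in_frame)
    log.info("in-frame filter: %d kept, %d excluded", len(in_frame), len(excluded))

    tffg_events = [
        f for f in in_frame if f.gene_5p in tf_map or f.gene_3p in tf_map
    ]
    non_tffg_events = [f for f in in_frame if f not in tffg_events]
    summary["stages"]["tffg_events"] = len(tffg_events)
    log.info("TF intersection: %d TFFG events", len(tffg_events))

    def retained_calls(events):
        calls = []
        for f in events:
            if f.gene_5p not in gene_models or f.gene_3p not in gene_models:
                skip_report.append(
                    f"{f.sample_id} {f.gene_5p}-{f.gene_3p}: partner absent from gene models"
                )
                continue
            calls.extend(
                call_fusion_retention(
                    f, gene_models, features, include_boundary=config.include_boundary
                )
            )
        return calls

    tffg_calls = retained_calls(tffg_events)
    other_calls = retained_calls(non_tffg_events)

    retention_rows = [
        {
            "sample_id": c.fusion.sample_id, "cancer_type": c.fusion.cancer_type,
            "gene_5p": c.fusion.gene_5p, "gene_3p": c.fusion.gene_3p, "role": c.role,
            "category": c.feature.category, "name": c.feature.name,
            "aa_start": c.feature.aa_start, "aa_end": c.feature.aa_end,
            "retained_any_isoform": c.retained_any_isoform,
            **{f"retained_{tx}": v for tx, v in sorted(c.per_isoform.items())},
        }
        for c in tffg_calls
    ]
    pd.DataFrame(retention_rows).to_csv(outdir / "retention_calls.tsv", sep="\t", index=False)

    if tffg_calls or other_calls:
        enr = test_feature_enrichment(
            tffg_calls, other_calls, alpha=config.enrichment_alpha, unit=config.counting_unit
        )
        pd.DataFrame([vars(r) for r in enr]).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
        summary["stages"]["enriched_categories"] = sum(r.significant for r in enr)

    calls_by_fusion: dict[int, list] = {}
    for c in tffg_calls:
        calls_by_fusion.setdefault(id(c.fusion), []).append(c)
    classifications = [
        classify_fusion(f, tf_map, calls_by_fusion.get(id(f), []))
        for f in tffg_events
        if f.gene_5p in gene_models and f.gene_3p in gene_models
    ]
    orient = pd.Series([c.orientation for c in classifications]).value_counts().to_dict()
    retained_cls = [c for c in classifications if c.any_feature_retained]
    binding_cls = [c for c in classifications if c.binding_domain_retained]
    summary["stages"]["fd_retained_events"] = len(retained_cls)
    summary["stages"]["orientation"] = orient
    summary["stages"]["binding_retained_events"] = len(binding_cls)
    log.info("binding-domain retention: %d events", len(binding_cls))
    pd.DataFrame(
        [
            {
                "sample_id": c.fusion.sample_id, "cancer_type": c.fusion.cancer_type,
                "gene_5p": c.fusion.gene_5p, "gene_3p": c.fusion.gene_3p,
                "orientation": c.orientation,
                "binding_domain_retained": c.binding_domain_retained,
                "any_feature_retained": c.any_feature_retained,
            }
            for c in classifications
        ]
    ).to_csv(outdir / "classification.tsv", sep="\t", index=False)

    scores = score_all_tfs(classifications, tf_map)
    scores_to_frame(scores).to_csv(outdir / "tf_scores.tsv", sep="\t", index=False)
    summary["stages"]["scored_tfs"] = len(scores)

    recurrent = recurrent_tffgs(classifications, min_samples=config.min_recurrence)
    pd.DataFrame(
        recurrent, columns=["gene_5p", "gene_3p", "cancer_type", "n_samples"]
    ).to_csv(outdir / "recurrent_tffgs.tsv", sep="\t", index=False)
    summary["stages"]["recurrent_tffgs"] = len(recurrent)

    if config.expression and config.samples:
        expression = tio.read_expression(config.expression, config.samples)
        detg_frames = []
        tested = 0
        for g5, g3, ct, _n in recurrent:
            targets = sorted(tf_map.targets(g5) | tf_map.targets(g3))
            positive = sorted(
                {
                    f.sample_id
                    for f in tffg_events
                    if f.gene_5p == g5 and f.gene_3p == g3 and f.cancer_type == ct
                }
            )
            if len(positive) < 2:
                skip_report.append(f"{g5}-{g3} ({ct}): <2 positive samples, DETG skipped")
                continue
            try:
                results, skipped = run_detg(
                    f"{g5}-{g3}", ct, targets, expression, positive,
                    fc_threshold=config.fc_threshold, q_threshold=config.q_threshold,
                )
            except TffgError as exc:
                skip_report.append(str(exc))
                continue
            tested += 1
            detg_frames.append(results_to_frame(results))
            for gene in skipped:
                skip_report.append(f"{g5}-{g3} ({ct}): target {gene} absent from matrix")
        if detg_frames:
            detg_all = pd.concat(detg_frames, ignore_index=True)
        else:
            detg_all = results_to_frame([])
        detg_all.to_csv(outdir / "detg_results.tsv", sep="\t", index=False)
        summary["stages"]["detg_tested_tffgs"] = tested
        if len(detg_all):
            summary["stages"]["detg_significant"] = int(detg_all["significant"].sum())

    net = build_network(classifications, scores)
    tio.write_network(net, outdir / "network.graphml", "graphml")
    tio.write_network(net, outdir / "network.sif", "sif")
    degree_report(net).to_csv(outdir / "degree_report.tsv", sep="\t", index=False)
    summary["stages"]["network_nodes"] = net.number_of_nodes()
    summary["stages"]["network_edges"] = net.number_of_edges()

    summary["skipped"] = skip_report
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(outdir / "skip_report.txt", "w") as fh:
        fh.write("\n".join(skip_report) + ("\n" if skip_report else ""))
    return summary


def score_table_mode(counts_path: str | Path, out_path: str | Path) -> pd.DataFrame:
    """Score a pre-tabulated per-TF count table (gene, n_cancer_types,
    n_partners, n_breakpoints, obs) without any other inputs."""
    counts = pd.read_csv(counts_path, sep="\t")
    table = score_count_table(counts)
    table.to_csv(out_path, sep="\t", index=False)
    return table
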
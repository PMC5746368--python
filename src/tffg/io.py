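"""Readers and writers for the pipeline's tabular formats.

All external files are plain TSV with a header row. Genomic coordinates
are 1-based inclusive on disk and converted to 0-based half-open
internally. Dialects:

* ``fusions.tsv`` — columns sample_id, cancer_type, gene_5p, gene_3p,
  chrom_5p, pos_5p, chrom_3p, pos_3p, frame. ``pos_*`` is the junction
  base (last retained base of the 5' transcript / first retained base of
  the 3' transcript). Frame labels go through a fixed synonym map;
  unrecognized labels become "unknown", never in-frame.
* ``gene_models.tsv`` — one exon per row: gene, transcript_id,
  protein_accession, chrom, strand, exon_start, exon_end, cds_start,
  cds_end (CDS bounds repeated on every row of a transcript).
* ``features.tsv`` — protein_accession, category, name, aa_start, aa_end.
* ``tf_targets.tsv`` — tf, target, provenance.
* ``expression.tsv`` — gene column then one column per sample, paired
  with ``samples.tsv`` (sample_id, cancer_type).

Readers validate strictly. Structural problems (missing columns) raise
:class:`FormatError` immediately; row-level violations raise a
:class:`FormatError` naming the line, or are returned as a report when
``errors="collect"``.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from pathlib import Path

import networkx as nx
import pandas as pd

from .models import (
    ExpressionMatrix,
    FormatError,
    FusionRecord,
    GenomicPosition,
    ProteinFeature,
    TFTargetMap,
    TranscriptModel,
    ValidationError,
)
from .vocab import normalize_frame

FUSION_COLUMNS = [
    "sample_id", "cancer_type", "gene_5p", "gene_3p",
    "chrom_5p", "pos_5p", "chrom_3p", "pos_3p", "frame",
]
GENE_MODEL_COLUMNS = [
    "gene", "transcript_id", "protein_accession", "chrom", "strand",
    "exon_start", "exon_end", "cds_start", "cds_end",
]
FEATURE_COLUMNS = ["protein_accession", "category", "name", "aa_start", "aa_end"]
TF_TARGET_COLUMNS = ["tf", "target", "provenance"]


def _read_rows(path: str | Path, required: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header row")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        return list(reader)


def _handle(errors: str, report: list, line: int, msg: str) -> None:
    if errors == "collect":
        report.append((line, msg))
    else:
        raise FormatError(f"line {line}: {msg}")


def read_fusions(path: str | Path, errors: str = "raise"):
    """Read fusion calls. With ``errors="collect"`` returns
    ``(records, [(line, message), ...])`` instead of raising on bad rows."""
    rows = _read_rows(path, FUSION_COLUMNS)
    records: list[FusionRecord] = []
    report: list[tuple[int, str]] = []
    for i, row in enumerate(rows, start=2):  # line 1 is the header
        try:
            pos5, pos3 = int(row["pos_5p"]), int(row["pos_3p"])
        except ValueError:
            _handle(errors, report, i, f"unparseable position {row['pos_5p']!r}/{row['pos_3p']!r}")
            continue
        try:
            records.append(
                FusionRecord(
                    sample_id=row["sample_id"].strip(),
                    cancer_type=row["cancer_type"].strip(),
                    gene_5p=row["gene_5p"].strip().upper(),
                    gene_3p=row["gene_3p"].strip().upper(),
                    breakpoint_5p=GenomicPosition(row["chrom_5p"].strip(), pos5 - 1),
                    breakpoint_3p=GenomicPosition(row["chrom_3p"].strip(), pos3 - 1),
                    frame_status=normalize_frame(row["frame"]),
                )
            )
        except ValidationError as exc:
            _handle(errors, report, i, str(exc))
    return (records, report) if errors == "collect" else records


def write_fusions(records, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(FUSION_COLUMNS)
        for r in records:
            w.writerow([
                r.sample_id, r.cancer_type, r.gene_5p, r.gene_3p,
                r.breakpoint_5p.chrom, r.breakpoint_5p.pos + 1,
                r.breakpoint_3p.chrom, r.breakpoint_3p.pos + 1,
                r.frame_status,
            ])


def read_gene_models(path: str | Path, errors: str = "raise"):
    """Read the exon-per-row gene-model table into transcript models,
    returned as a dict gene -> list of :class:`TranscriptModel`."""
    rows = _read_rows(path, GENE_MODEL_COLUMNS)
    by_tx: dict[str, list[dict[str, str]]] = defaultdict(list)
    for row in rows:
        by_tx[row["transcript_id"]].append(row)
    models: dict[str, list[TranscriptModel]] = defaultdict(list)
    report: list[tuple[int, str]] = []
    for tx_id, tx_rows in by_tx.items():
        first = tx_rows[0]
        try:
            exons = tuple(
                sorted((int(r["exon_start"]) - 1, int(r["exon_end"])) for r in tx_rows)
            )
            model = TranscriptModel(
                gene=first["gene"].strip().upper(),
                transcript_id=tx_id,
                protein_accession=first["protein_accession"].strip(),
                chrom=first["chrom"].strip(),
                strand=first["strand"].strip(),
                exons=exons,
                cds_start=int(first["cds_start"]) - 1,
                cds_end=int(first["cds_end"]),
            )
        except (ValueError, ValidationError) as exc:
            _handle(errors, report, rows.index(first) + 2, f"transcript {tx_id}: {exc}")
            continue
        models[model.gene].append(model)
    result = dict(models)
    return (result, report) if errors == "collect" else result


def write_gene_models(models: dict[str, list[TranscriptModel]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENE_MODEL_COLUMNS)
        for gene in sorted(models):
            for t in models[gene]:
                for s, e in t.exons:
                    w.writerow([
                        t.gene, t.transcript_id, t.protein_accession, t.chrom,
                        t.strand, s + 1, e, t.cds_start + 1, t.cds_end,
                    ])


def read_features(
    path: str | Path,
    protein_lengths: dict[str, int] | None = None,
    errors: str = "raise",
):
    """Read protein features, as a dict accession -> list of features.

    When ``protein_lengths`` is given, features extending past their
    protein's length are rejected.
    """
    rows = _read_rows(path, FEATURE_COLUMNS)
    features: dict[str, list[ProteinFeature]] = defaultdict(list)
    report: list[tuple[int, str]] = []
    for i, row in enumerate(rows, start=2):
        try:
            feat = ProteinFeature(
                protein_accession=row["protein_accession"].strip(),
                category=row["category"].strip(),
                name=row["name"].strip(),
                aa_start=int(row["aa_start"]),
                aa_end=int(row["aa_end"]),
            )
        except (ValueError, ValidationError) as exc:
            _handle(errors, report, i, str(exc))
            continue
        if protein_lengths is not None:
            plen = protein_lengths.get(feat.protein_accession)
            if plen is not None and feat.aa_end > plen:
                _handle(errors, report, i,
                        f"feature {feat.name!r} ends at {feat.aa_end} "
                        f"beyond protein length {plen}")
                continue
        features[feat.protein_accession].append(feat)
    result = dict(features)
    return (result, report) if errors == "collect" else result


def write_features(features: dict[str, list[ProteinFeature]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(FEATURE_COLUMNS)
        for acc in sorted(features):
            for f in features[acc]:
                w.writerow([f.protein_accession, f.category, f.name, f.aa_start, f.aa_end])


def read_tf_targets(path: str | Path) -> TFTargetMap:
    rows = _read_rows(path, TF_TARGET_COLUMNS[:2])
    tf_map = TFTargetMap()
    for i, row in enumerate(rows, start=2):
        tf, target = row["tf"].strip(), row["target"].strip()
        if not tf or not target:
            raise FormatError(f"line {i}: empty TF or target symbol")
        tf_map.add(tf, target, row.get("provenance", "user") or "user")
    return tf_map


def write_tf_targets(tf_map: TFTargetMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TF_TARGET_COLUMNS)
        for tf, target, prov in tf_map.iter_pairs():
            w.writerow([tf, target, prov])


def read_expression(path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    raw_header = Path(path).open().readline().rstrip("\n").split("\t")[1:]
    if len(set(raw_header)) != len(raw_header):
        raise FormatError(f"{path}: duplicate sample column(s)")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()[:5]
        raise FormatError(f"{path}: duplicate gene identifier(s) {dupes}")
    sample_rows = _read_rows(samples_path, ["sample_id", "cancer_type"])
    sample_cancer = {r["sample_id"].strip(): r["cancer_type"].strip() for r in sample_rows}
    try:
        return ExpressionMatrix(df, sample_cancer)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, path: str | Path, samples_path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    with open(samples_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "cancer_type"])
        for s in matrix.samples:
            w.writerow([s, matrix.sample_cancer[s]])


# -- network export ----------------------------------------------------------

def write_network(network: nx.MultiDiGraph, path: str | Path, format: str = "graphml") -> None:
    """Export the fusion network.

    ``graphml`` keeps all attributes inline and round-trips losslessly;
    ``sif`` writes the simple interaction format plus sibling
    ``<stem>.nodes.tsv`` / ``<stem>.edges.tsv`` attribute tables.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network, path, named_key_ids=True)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, key in sorted(network.edges(keys=True)):
                fh.write(f"{u}\tfusion_{key}\t{v}\n")
        node_rows = [
            {"gene": n, **{k: v for k, v in network.nodes[n].items()}}
            for n in sorted(network.nodes)
        ]
        pd.DataFrame(node_rows).to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)
        edge_rows = [
            {"gene_5p": u, "gene_3p": v, **network.edges[u, v, key]}
            for u, v, key in sorted(network.edges(keys=True))
        ]
        pd.DataFrame(edge_rows).to_csv(path.with_suffix(".edges.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r} (use 'graphml' or 'sif')")


def read_network(path: str | Path) -> nx.MultiDiGraph:
    """Read back a GraphML export (the lossless format)."""
    g = nx.read_graphml(path, force_multigraph=True)
    return nx.MultiDiGraph(g)
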
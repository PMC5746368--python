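"""Differentially expressed target genes (DETGs) of recurrent fusions.

For a fusion involving a TF, the TF's known target genes are tested for
differential expression between fusion-positive and fusion-negative
samples of one cancer type. The fusion-negative group is every other
sample of that cancer type, including carriers of other fusions. Each
target gene gets a two-sided Wilcoxon rank-sum (Mann-Whitney) test —
exact when both groups have <= 25 samples and the data are tie-free,
normal approximation with continuity and tie correction otherwise — and
Benjamini-Hochberg adjustment is applied within the target-gene family of
that one fusion.

Fold change is the difference of group means on the log2(count+1) input
scale, so the default threshold 0.585 = log2(1.5) marks a 1.5-fold
change. A gene is significant when |log2FC| >= fc_threshold and
q < q_threshold (0.1 for the fusion-positive contrast, 0.2 for the
in-frame versus out-of-frame contrast).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .models import ExpressionMatrix, TffgError

FC_THRESHOLD = 0.585  # log2(1.5)
Q_THRESHOLD = 0.1
Q_THRESHOLD_FRAME = 0.2


@dataclass(frozen=True)
class DETGResult:
    tffg: str
    cancer_type: str
    target_gene: str
    mean_fg: float
    mean_nfg: float
    log2fc: float
    p_value: float
    q_value: float
    direction: str
    significant: bool


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value; exact for small tie-free groups."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and tie_free) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _test_gene_set(
    label: str,
    cancer_type: str,
    targets: Sequence[str],
    expression: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float,
    q_threshold: float,
) -> tuple[list[DETGResult], list[str]]:
    if len(group_a) < 2 or len(group_b) < 2:
        raise TffgError(
            f"{label}: need >= 2 samples per group "
            f"(got {len(group_a)} vs {len(group_b)})"
        )
    if not targets:
        raise TffgError(f"{label}: empty target-gene set")
    present = [g for g in targets if g in expression.values.index]
    skipped = sorted(set(targets) - set(present))
    if not present:
        return [], skipped
    a = expression.values.loc[present, list(group_a)].to_numpy()
    b = expression.values.loc[present, list(group_b)].to_numpy()
    pvals = [wilcoxon_rank_sum(a[i], b[i]) for i in range(len(present))]
    qvals = benjamini_hochberg(pvals)
    results = []
    for i, gene in enumerate(present):
        mean_a, mean_b = float(a[i].mean()), float(b[i].mean())
        fc = mean_a - mean_b
        results.append(
            DETGResult(
                tffg=label,
                cancer_type=cancer_type,
                target_gene=gene,
                mean_fg=mean_a,
                mean_nfg=mean_b,
                log2fc=fc,
                p_value=pvals[i],
                q_value=float(qvals[i]),
                direction="up" if fc >= 0 else "down",
                significant=abs(fc) >= fc_threshold and qvals[i] < q_threshold,
            )
        )
    return results, skipped


def run_detg(
    tffg: str,
    cancer_type: str,
    target_genes: Sequence[str],
    expression: ExpressionMatrix,
    positive_samples: Sequence[str],
    fc_threshold: float = FC_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> tuple[list[DETGResult], list[str]]:
    """Test a fusion's target genes, fusion-positive vs fusion-negative.

    ``positive_samples`` are the carriers of the fusion in ``cancer_type``;
    the negative group is every other sample of that cancer type. Returns
    ``(results, skipped)`` where ``skipped`` lists targets absent from the
    expression matrix. Refuses to run with < 2 positive samples — the test
    is undefined below the recurrence requirement.
    """
    cohort = expression.samples_of(cancer_type)
    positive = [s for s in positive_samples if s in cohort]
    negative = [s for s in cohort if s not in set(positive)]
    return _test_gene_set(
        tffg, cancer_type, target_genes, expression, positive, negative,
        fc_threshold, q_threshold,
    )


def run_frame_contrast(
    tffg: str,
    cancer_type: str,
    target_genes: Sequence[str],
    expression: ExpressionMatrix,
    in_frame_samples: Sequence[str],
    out_of_frame_samples: Sequence[str],
    fc_threshold: float = FC_THRESHOLD,
    q_threshold: float = Q_THRESHOLD_FRAME,
) -> tuple[list[DETGResult], list[str]]:
    """In-frame carriers vs out-of-frame carriers of the same fusion.

    Group A (the ``mean_fg`` side of the report) is the in-frame set; the
    relaxed default q threshold of 0.2 applies.
    """
    overlap = set(in_frame_samples) & set(out_of_frame_samples)
    if overlap:
        raise TffgError(f"{tffg}: samples in both frame groups: {sorted(overlap)[:5]}")
    return _test_gene_set(
        tffg, cancer_type, target_genes, expression,
        list(in_frame_samples), list(out_of_frame_samples),
        fc_threshold, q_threshold,
    )


def results_to_frame(results: Sequence[DETGResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tffg": r.tffg,
                "cancer_type": r.cancer_type,
                "target_gene": r.target_gene,
                "mean_fg": r.mean_fg,
                "mean_nfg": r.mean_nfg,
                "log2fc": r.log2fc,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in results
        ]
    )
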
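"""Recurrence scoring of TFs in fusion genes: DoF, MAII, tMAII.

For each TF, over its binding-domain-retained fusion events, three
diversity counts are taken: distinct cancer types, distinct partner
genes, and distinct breakpoints inside the TF gene. Their product is the
Degree-of-Frequency (DoF) score — the number of possible isofusions,
where an isofusion is one (partner, breakpoint, cancer type) combination.

The Major Active Isofusion Index is the observed fusion-positive sample
count divided by DoF: the average recurrence per possible isofusion.
Sub-unity MAII values are spread onto a symmetric scale by the transform
tMAII = MAII if MAII >= 1 else -DoF/obs (the negative reciprocal), so
|tMAII| >= 1 always holds.

Classification: tMAII > 1 marks an *effective* TF in fusion genes
(eTFinFG); tMAII < -1 together with DoF > 8 marks a *possibly effective*
TF (peTFinFG); everything else — including the fixed point tMAII == 1 —
is neither.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .models import FusionRecord, TFFGClassification, TFScore

E_TF = "eTFinFG"
PE_TF = "peTFinFG"
NEITHER = "neither"


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals, as used for all reported scores."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compute_dof(n_cancer_types: int, n_partners: int, n_breakpoints: int) -> int:
    if min(n_cancer_types, n_partners, n_breakpoints) < 1:
        raise ValueError("all diversity counts must be >= 1")
    return n_cancer_types * n_partners * n_breakpoints


def compute_maii(obs: int, dof: int) -> float:
    if obs < 1 or dof < 1:
        raise ValueError("obs and dof must be >= 1")
    return obs / dof


def compute_tmaii(maii: float, dof: int, obs: int) -> float:
    """MAII when >= 1, else the reversed negative value -dof/obs."""
    return maii if maii >= 1 else -dof / obs


def classify_tf(tmaii: float, dof: int) -> str:
    if tmaii > 1:
        return E_TF
    if tmaii < -1 and dof > 8:
        return PE_TF
    return NEITHER


def summarize_tf(
    tf: str, events: Sequence[tuple[FusionRecord, str]]
) -> tuple[int, int, int, int]:
    """Diversity counts and observed frequency for one TF.

    ``events`` pairs each fusion record with the TF's role ("5p"/"3p") in
    it, restricted upstream to binding-domain-retained TFFG events. Counts
    are over distinct values; obs is the number of distinct
    (sample, fusion pair) events. Breakpoint identity is the exact genomic
    coordinate of the junction within the TF gene.
    """
    if not events:
        raise ValueError(f"no events for TF {tf}")
    cancers, partners, breakpoints, samples = set(), set(), set(), set()
    for fusion, role in events:
        cancers.add(fusion.cancer_type)
        if role == "5p":
            partners.add(fusion.gene_3p)
            bp = fusion.breakpoint_5p
        else:
            partners.add(fusion.gene_5p)
            bp = fusion.breakpoint_3p
        breakpoints.add((bp.chrom, bp.pos))
        samples.add((fusion.sample_id, fusion.gene_5p, fusion.gene_3p))
    return len(cancers), len(partners), len(breakpoints), len(samples)


def score_tf(
    tf: str, n_cancer_types: int, n_partners: int, n_breakpoints: int, obs: int
) -> TFScore:
    dof = compute_dof(n_cancer_types, n_partners, n_breakpoints)
    maii = compute_maii(obs, dof)
    tmaii = compute_tmaii(maii, dof, obs)
    return TFScore(
        tf=tf,
        n_cancer_types=n_cancer_types,
        n_partners=n_partners,
        n_breakpoints=n_breakpoints,
        dof=dof,
        obs=obs,
        maii=maii,
        tmaii=tmaii,
        tf_class=classify_tf(tmaii, dof),
    )


def score_all_tfs(
    classifications: Iterable[TFFGClassification],
    tf_map,
    binding_retained_only: bool = True,
) -> list[TFScore]:
    """Score every TF appearing in the classified fusion events.

    Events are restricted to binding-domain-retained TFFGs (the score-table
    universe) unless ``binding_retained_only`` is disabled. A TF that is
    both partners of a self-informative 5'-3' fusion contributes the event
    once per role.
    """
    events: dict[str, list[tuple[FusionRecord, str]]] = {}
    for cl in classifications:
        if cl.orientation == "non-TFFG":
            continue
        if binding_retained_only and not cl.binding_domain_retained:
            continue
        f = cl.fusion
        if f.gene_5p in tf_map:
            events.setdefault(f.gene_5p, []).append((f, "5p"))
        if f.gene_3p in tf_map:
            events.setdefault(f.gene_3p, []).append((f, "3p"))
    scores = []
    for tf in sorted(events):
        c, p, b, obs = summarize_tf(tf, events[tf])
        scores.append(score_tf(tf, c, p, b, obs))
    return scores


def recurrent_tffgs(
    classifications: Iterable[TFFGClassification], min_samples: int = 2
) -> list[tuple[str, str, str, int]]:
    """Fusions (unique gene pair within a cancer type) whose
    binding-retained sample count reaches ``min_samples``.

    Returns ``(gene_5p, gene_3p, cancer_type, n_samples)`` tuples sorted by
    descending recurrence.
    """
    counts: dict[tuple[str, str, str], set[str]] = {}
    for cl in classifications:
        if cl.orientation == "non-TFFG" or not cl.binding_domain_retained:
            continue
        f = cl.fusion
        counts.setdefault((f.gene_5p, f.gene_3p, f.cancer_type), set()).add(f.sample_id)
    out = [
        (g5, g3, ct, len(samples))
        for (g5, g3, ct), samples in counts.items()
        if len(samples) >= min_samples
    ]
    out.sort(key=lambda t: (-t[3], t[0], t[1], t[2]))
    return out


def scores_to_frame(scores: Sequence[TFScore]) -> pd.DataFrame:
    """Score table with reported values rounded half-up to 2 decimals;
    exact values remain available on the :class:`TFScore` objects."""
    return pd.DataFrame(
        {
            "gene": [s.tf for s in scores],
            "n_cancer_types": [s.n_cancer_types for s in scores],
            "n_partners": [s.n_partners for s in scores],
            "n_breakpoints": [s.n_breakpoints for s in scores],
            "dof": [s.dof for s in scores],
            "obs": [s.obs for s in scores],
            "maii": [round2(s.maii) for s in scores],
            "tmaii": [round2(s.tmaii) for s in scores],
            "tf_class": [s.tf_class for s in scores],
        }
    )


def score_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Score a table of pre-tabulated per-TF counts.

    ``counts`` needs columns gene, n_cancer_types, n_partners,
    n_breakpoints, obs; this is the direct entry point for published
    recurrence-count tables.
    """
    required = {"gene", "n_cancer_types", "n_partners", "n_breakpoints", "obs"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    scores = [
        score_tf(
            str(r.gene),
            int(r.n_cancer_types),
            int(r.n_partners),
            int(r.n_breakpoints),
            int(r.obs),
        )
        for r in counts.itertuples()
    ]
    return scores_to_frame(scores)
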
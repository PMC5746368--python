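"""Feature-category enrichment in TFFGs versus all other fusion genes.

For each of the 34 feature categories we ask whether TFFG events retain it
at a higher relative frequency than the fusion cohort at large. With N
fusion events overall, K of which retain the category, and n TFFG events,
k of which retain it, the one-sided over-representation p-value is the
upper hypergeometric tail P[X >= k] for X ~ Hypergeom(N, K, n). No
multiple-testing correction is applied; significance is a raw p < alpha
cutoff (default 0.001).

The counting unit is one fusion *event* (one sample x one fusion); a
category counts once per event regardless of how many of its features are
retained. Switching ``unit="pair"`` collapses events to unique
(gene_5p, gene_3p) pairs instead.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from scipy.stats import hypergeom

from .models import RetentionCall, TffgError


@dataclass(frozen=True)
class FeatureEnrichmentResult:
    category: str
    k: int  # TFFG events retaining the category
    n: int  # TFFG events
    K: int  # all events retaining the category
    N: int  # all events
    p_value: float
    significant: bool


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def _event_key(call: RetentionCall, unit: str):
    f = call.fusion
    if unit == "event":
        return (f.sample_id, f.gene_5p, f.gene_3p, f.cancer_type)
    if unit == "pair":
        return (f.gene_5p, f.gene_3p)
    raise ValueError(f"unknown counting unit {unit!r}")


def test_feature_enrichment(
    tffg_calls: Iterable[RetentionCall],
    other_calls: Iterable[RetentionCall],
    alpha: float = 0.001,
    unit: str = "event",
    categories: Sequence[str] | None = None,
) -> list[FeatureEnrichmentResult]:
    """Per-category over-representation of retained features in TFFGs.

    ``tffg_calls`` and ``other_calls`` are retention calls for the TFFG and
    non-TFFG fusions respectively; only calls with
    ``retained_any_isoform`` contribute to the retention counts, while the
    event universe is every event appearing in either stream.
    """
    tffg_calls = list(tffg_calls)
    other_calls = list(other_calls)
    tffg_events = {_event_key(c, unit) for c in tffg_calls}
    other_events = {_event_key(c, unit) for c in other_calls} - tffg_events
    n = len(tffg_events)
    N = n + len(other_events)
    if N == 0:
        raise TffgError("no fusion events to test")

    def retained_by_category(calls):
        out: dict[str, set] = {}
        for c in calls:
            if c.retained_any_isoform:
                out.setdefault(c.feature.category, set()).add(_event_key(c, unit))
        return out

    ret_tffg = retained_by_category(tffg_calls)
    ret_other = retained_by_category(other_calls)
    cats = (
        sorted(set(ret_tffg) | set(ret_other)) if categories is None else list(categories)
    )
    results = []
    for cat in cats:
        k = len(ret_tffg.get(cat, set()))
        K = k + len(ret_other.get(cat, set()) - tffg_events)
        p = hypergeom_upper_tail(k, N, K, n)
        results.append(
            FeatureEnrichmentResult(
                category=cat, k=k, n=n, K=K, N=N, p_value=p, significant=p < alpha
            )
        )
    return results
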
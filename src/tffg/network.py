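"""The prioritized TFFG network.

Genes are nodes; each fusion in each cancer type is one directed
multi-edge from the 5' to the 3' partner, carrying the cancer type and
the fusion-positive sample count. TF nodes carry their tMAII score and
class as attributes; pure partner nodes carry none. By default TFs whose
tMAII is exactly 1 (a single observation per possible isofusion —
uninformative) are dropped along with their edges, mirroring the
prioritization view of the score table.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import networkx as nx
import pandas as pd

from .models import TFFGClassification, TFScore


def build_network(
    classifications: Iterable[TFFGClassification],
    tf_scores: Sequence[TFScore],
    drop_tmaii_one: bool = True,
) -> nx.MultiDiGraph:
    """Network over the binding-domain-retained TFFG events.

    Edges are keyed by (gene_5p, gene_3p, cancer_type); the same fusion in
    two cancer types contributes two edges. ``drop_tmaii_one`` removes TFs
    with tMAII exactly 1 and the fusions whose only TF partners are such.
    """
    scores = {s.tf: s for s in tf_scores}
    dropped = {tf for tf, s in scores.items() if drop_tmaii_one and s.tmaii == 1}

    g = nx.MultiDiGraph()
    counts: dict[tuple[str, str, str], set[str]] = {}
    for cl in classifications:
        if cl.orientation == "non-TFFG" or not cl.binding_domain_retained:
            continue
        f = cl.fusion
        tf_partners = {p for p in (f.gene_5p, f.gene_3p) if p in scores}
        if tf_partners and tf_partners <= dropped:
            continue
        counts.setdefault((f.gene_5p, f.gene_3p, f.cancer_type), set()).add(f.sample_id)

    for (g5, g3, ct), samples in sorted(counts.items()):
        for gene in (g5, g3):
            if gene not in g:
                attrs = {"is_tf": gene in scores}
                s = scores.get(gene)
                if s is not None:
                    attrs["tmaii"] = s.tmaii
                    attrs["tf_class"] = s.tf_class
                g.add_node(gene, **attrs)
        g.add_edge(g5, g3, key=ct, cancer_type=ct, n_samples=len(samples))
    return g


def degree_report(network: nx.MultiDiGraph) -> pd.DataFrame:
    """Per-node degree, multi-edge aware, deterministically ordered."""
    rows = [
        {
            "gene": node,
            "degree": network.degree(node),
            "out_degree": network.out_degree(node),
            "in_degree": network.in_degree(node),
            "is_tf": bool(network.nodes[node].get("is_tf", False)),
        }
        for node in network.nodes
    ]
    df = pd.DataFrame(rows, columns=["gene", "degree", "out_degree", "in_degree", "is_tf"])
    return df.sort_values(["degree", "gene"], ascending=[False, True]).reset_index(drop=True)
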
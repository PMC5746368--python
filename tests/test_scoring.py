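"""Recurrence scoring: DoF/MAII/tMAII arithmetic, classification, and the
published pan-cancer score table reproduced from its count columns."""

import importlib.resources

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tffg.models import TFFGClassification
from tffg.scoring import (
    classify_tf,
    compute_dof,
    compute_maii,
    compute_tmaii,
    recurrent_tffgs,
    round2,
    score_count_table,
    score_tf,
    summarize_tf,
)
from conftest import make_fusion

# Published per-TF recurrence rows: (gene, n_cancer_types, n_partners,
# n_breakpoints, obs) -> expected (dof, maii, tmaii) at 2-decimal rounding.
TABLE_ROWS = [
    ("RARA", 1, 1, 1, 15, 1, 15.0, 15.0),
    ("RUNX1T1", 1, 1, 1, 7, 1, 7.0, 7.0),
    ("PML", 1, 1, 3, 16, 3, 5.33, 5.33),
    ("ERG", 2, 3, 2, 24, 12, 2.0, 2.0),
    ("RUNX1", 1, 2, 2, 8, 4, 2.0, 2.0),
    ("SFPQ", 1, 1, 2, 3, 2, 1.5, 1.5),
    ("TFE3", 1, 1, 2, 3, 2, 1.5, 1.5),
    ("TRPS1", 1, 4, 1, 4, 4, 1.0, 1.0),
    ("YY1", 1, 2, 1, 2, 2, 1.0, 1.0),
    ("BPTF", 1, 2, 3, 3, 6, 0.5, -2.0),
    ("GLIS3", 2, 2, 1, 2, 4, 0.5, -2.0),
    ("IKBKB", 1, 2, 2, 2, 4, 0.5, -2.0),
    ("KAT6A", 2, 2, 1, 2, 4, 0.5, -2.0),
    ("NCOR1", 1, 2, 2, 2, 4, 0.5, -2.0),
    ("RFWD2", 1, 2, 2, 2, 4, 0.5, -2.0),
    ("WWP1", 1, 2, 2, 2, 4, 0.5, -2.0),
    ("BRIP1", 1, 2, 2, 2, 4, 0.5, -2.0),
    ("ARID1B", 2, 2, 1, 2, 4, 0.5, -2.0),
    ("RBMS1", 2, 1, 2, 2, 4, 0.5, -2.0),
    ("PAX8", 1, 2, 2, 2, 4, 0.5, -2.0),
    ("UHRF1", 2, 2, 1, 2, 4, 0.5, -2.0),
    ("ZNF143", 2, 2, 1, 2, 4, 0.5, -2.0),
    ("FOXK2", 1, 3, 3, 3, 9, 0.33, -3.0),
    ("NFIX", 2, 3, 2, 3, 12, 0.25, -4.0),
    ("RFX4", 2, 3, 2, 3, 12, 0.25, -4.0),
    ("CLOCK", 2, 2, 2, 2, 8, 0.25, -4.0),
    ("KHSRP", 2, 2, 2, 2, 8, 0.25, -4.0),
    ("NFIB", 2, 2, 2, 2, 8, 0.25, -4.0),
    ("TRIM24", 2, 2, 2, 2, 8, 0.25, -4.0),
    ("YAP1", 2, 2, 2, 2, 8, 0.25, -4.0),
    ("ZBTB48", 2, 2, 2, 2, 8, 0.25, -4.0),
    ("FGFR1", 2, 2, 2, 2, 8, 0.25, -4.0),
    ("LIN28A", 2, 2, 2, 2, 8, 0.25, -4.0),
    ("ETV6", 3, 3, 5, 10, 45, 0.22, -4.5),
    ("MLLT10", 2, 3, 6, 7, 36, 0.19, -5.14),
    ("EP300", 2, 3, 3, 3, 18, 0.17, -6.0),
    ("TBL1XR1", 2, 3, 3, 3, 18, 0.17, -6.0),
    ("VAV1", 2, 3, 3, 3, 18, 0.17, -6.0),
    ("KDM5A", 2, 4, 4, 4, 32, 0.13, -8.0),
    ("NCOR2", 3, 3, 3, 3, 27, 0.11, -9.0),
    ("SMARCA4", 3, 3, 3, 3, 27, 0.11, -9.0),
    ("SND1", 4, 4, 5, 6, 80, 0.08, -13.33),
    ("KDM4B", 5, 5, 3, 5, 75, 0.07, -15.0),
    ("NSD1", 4, 5, 5, 6, 100, 0.06, -16.67),
]
E_TF_GENES = {"RARA", "RUNX1T1", "PML", "ERG", "RUNX1", "SFPQ", "TFE3"}


@pytest.mark.parametrize(
    "gene,n_ct,n_p,n_b,obs,dof,maii,tmaii",
    TABLE_ROWS,
    ids=[r[0] for r in TABLE_ROWS],
)
def test_published_row_reproduced(gene, n_ct, n_p, n_b, obs, dof, maii, tmaii):
    s = score_tf(gene, n_ct, n_p, n_b, obs)
    assert s.dof == dof
    assert round2(s.maii) == maii
    assert round2(s.tmaii) == tmaii


def test_published_table_classifications():
    """7 effective TFs and 15 TFs above the DoF > 8 recurrence bar."""
    scores = [score_tf(*row[:5]) for row in TABLE_ROWS]
    e_tfs = {s.tf for s in scores if s.tf_class == "eTFinFG"}
    assert e_tfs == E_TF_GENES
    assert sum(s.dof > 8 for s in scores) == 15


def test_score_count_table_matches_packaged_counts():
    res = importlib.resources.files("tffg.data").joinpath("pancancer_tf_counts.tsv")
    counts = pd.read_csv(res, sep="\t")
    table = score_count_table(counts)
    assert len(table) == 44
    expected = pd.DataFrame(
        TABLE_ROWS,
        columns=["gene", "n_cancer_types", "n_partners", "n_breakpoints",
                 "obs", "dof", "maii", "tmaii"],
    )
    merged = table.merge(expected, on="gene", suffixes=("", "_exp"))
    assert len(merged) == 44
    assert (merged["dof"] == merged["dof_exp"]).all()
    assert (merged["maii"] == merged["maii_exp"]).all()
    assert (merged["tmaii"] == merged["tmaii_exp"]).all()


def test_dof_requires_positive_counts():
    with pytest.raises(ValueError):
        compute_dof(0, 1, 1)


@pytest.mark.parametrize(
    "tmaii,dof,expected",
    [(15.0, 1, "eTFinFG"), (1.0, 1, "neither"), (-16.67, 100, "peTFinFG"),
     (-4.0, 8, "neither"), (1.01, 1, "eTFinFG"), (-1.0, 100, "neither")],
)
def test_classification_rule(tmaii, dof, expected):
    assert classify_tf(tmaii, dof) == expected


@given(
    obs=st.integers(1, 500),
    n_ct=st.integers(1, 13),
    n_p=st.integers(1, 20),
    n_b=st.integers(1, 20),
)
def test_score_invariants(obs, n_ct, n_p, n_b):
    """dof is the product of the counts; doubling obs doubles maii;
    |tmaii| >= 1 with tmaii monotone in maii."""
    dof = compute_dof(n_ct, n_p, n_b)
    assert dof == n_ct * n_p * n_b
    maii = compute_maii(obs, dof)
    assert compute_maii(2 * obs, dof) == pytest.approx(2 * maii)
    tmaii = compute_tmaii(maii, dof, obs)
    assert abs(tmaii) >= 1 or maii == pytest.approx(abs(tmaii))
    assert abs(tmaii) >= 1 - 1e-12
    bigger = compute_tmaii(compute_maii(obs + 1, dof), dof, obs + 1)
    assert bigger >= tmaii


def test_summarize_tf_distinct_counting():
    """Duplicated breakpoint coordinates collapse; obs counts distinct
    (sample, fusion) events."""
    events = [
        (make_fusion(g5="TFA", g3="P1", bp5=100, sample="S1"), "5p"),
        (make_fusion(g5="TFA", g3="P1", bp5=100, sample="S2"), "5p"),
        (make_fusion(g5="TFA", g3="P2", bp5=200, sample="S3", cancer="PRAD"), "5p"),
    ]
    assert summarize_tf("TFA", events) == (2, 2, 2, 3)


def test_summarize_tf_single_event():
    assert summarize_tf("TFA", [(make_fusion(), "5p")]) == (1, 1, 1, 1)


def _cls(f, binding=True):
    return TFFGClassification(
        fusion=f, orientation="5'-TFFG", binding_domain_retained=binding,
        any_feature_retained=binding,
    )


def test_recurrent_tffgs_threshold():
    events = [
        _cls(make_fusion(sample="S1")),
        _cls(make_fusion(sample="S2")),
        _cls(make_fusion(g3="OTHER", sample="S3")),
        _cls(make_fusion(g3="NORET", sample="S4"), binding=False),
    ]
    assert recurrent_tffgs(events) == [("TFA", "PARTB", "AML", 2)]
    at_one = recurrent_tffgs(events, min_samples=1)
    assert len(at_one) == 2  # binding-retained fusions only
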
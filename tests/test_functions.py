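"""Term enrichment, functional similarity and crosstalk-function ranking."""

import math
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from regmotif.functions import (
    AnnotationMap,
    build_similarity_table,
    compare_zero_vs_nonzero,
    crosstalk_functions,
    enrich_terms,
    functional_similarity,
    rank_processes,
    read_gmt,
    write_gmt,
)
from regmotif.motifs import CROSSTALK, TF_TF, MotifInstance


def exact_tail(k, m, n_term, n_query) -> float:
    """Brute-force hypergeometric upper tail P(X >= k)."""
    return sum(
        comb(n_term, i) * comb(m - n_term, n_query - i)
        for i in range(k, min(n_term, n_query) + 1)
    ) / comb(m, n_query)


def _annotation(universe_size=20, term_size=5):
    genes = [f"g{i:02d}" for i in range(universe_size)]
    terms = {
        "T1": frozenset(genes[:term_size]),
        "T2": frozenset(genes[term_size:]),
    }
    return AnnotationMap(terms, {t: t for t in terms}), genes


# ----------------------------------------------------------- enrichment --

def test_enrichment_matches_exact_tail_sum():
    """Universe 20, term 5, query 5, overlap 4: p = 76/15504."""
    ann, genes = _annotation()
    query = genes[:4] + [genes[10]]
    res = enrich_terms(query, ann, alpha=0.05)
    row = res.table.set_index("term_id").loc["T1"]
    assert row.overlap == 4
    expected = exact_tail(4, 20, 5, 5)
    assert expected == pytest.approx(76 / 15504)
    assert row.p_value == pytest.approx(expected, rel=1e-9)


def test_enrichment_randomized_brute_force_battery():
    rng = np.random.default_rng(6)
    for _ in range(25):
        m = int(rng.integers(8, 31))
        genes = [f"g{i}" for i in range(m)]
        n_term = int(rng.integers(2, m))
        n_query = int(rng.integers(2, m))
        term = frozenset(rng.choice(genes, n_term, replace=False))
        # make sure the universe is all m genes
        ann = AnnotationMap(
            {"T": term, "ALL": frozenset(genes)}, {"T": "t", "ALL": "all"}
        )
        query = list(rng.choice(genes, n_query, replace=False))
        res = enrich_terms(query, ann)
        row = res.table.set_index("term_id").loc["T"]
        k = len(set(query) & term)
        assert row.p_value == pytest.approx(exact_tail(k, m, n_term, n_query),
                                            rel=1e-9)


def test_term_equal_to_universe_is_never_enriched():
    genes = [f"g{i}" for i in range(10)]
    ann = AnnotationMap({"ALL": frozenset(genes)}, {"ALL": "all"})
    res = enrich_terms(genes[:4], ann)
    assert res.table.p_value.iloc[0] == pytest.approx(1.0)


def test_bh_reported_terms_form_p_sorted_prefix():
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(25)]
    terms = {
        f"T{j}": frozenset(rng.choice(genes, 6, replace=False)) for j in range(12)
    }
    terms["ALL"] = frozenset(genes)
    ann = AnnotationMap(terms, {t: t for t in terms})
    res = enrich_terms(genes[:6], ann, alpha=0.3)
    reported_positions = [
        i for i, t in enumerate(res.table.term_id) if t in res.reported
    ]
    assert reported_positions == list(range(len(reported_positions)))


def test_enrichment_disjoint_query_errors():
    ann, _ = _annotation()
    with pytest.raises(ValueError):
        enrich_terms(["nope"], ann)


def test_gmt_roundtrip(tmp_path):
    ann, _ = _annotation()
    path = tmp_path / "ann.gmt"
    write_gmt(ann, path)
    again = read_gmt(path)
    assert again.term_genes == dict(ann.term_genes)
    assert again.universe == ann.universe


# ----------------------------------------------------------- similarity --

def _term_set(ids, ann):
    table = pd.DataFrame(
        [(t, t, 1, 0.01, 0.01) for t in sorted(ids)],
        columns=["term_id", "label", "overlap", "p_value", "adjusted_p"],
    )
    from regmotif.functions import EnrichedTermSet
    return EnrichedTermSet(table, frozenset(ids), 0.05, ann.key)


def test_functional_similarity_cases():
    ann, _ = _annotation()
    a = _term_set({"t1", "t2"}, ann)
    b = _term_set({"t2", "t3", "t4"}, ann)
    assert functional_similarity(a, a) == 1.0
    assert functional_similarity(a, b) == pytest.approx(0.25)
    assert functional_similarity(a, b) == functional_similarity(b, a)
    disjoint = _term_set({"x"}, ann)
    assert functional_similarity(a, disjoint) == 0.0
    assert functional_similarity(a, b, method="overlap") == pytest.approx(0.5)


def test_functional_similarity_annotation_mismatch_errors():
    ann1, _ = _annotation()
    ann2, _ = _annotation(universe_size=22)
    with pytest.raises(ValueError):
        functional_similarity(_term_set({"t"}, ann1), _term_set({"t"}, ann2))


# ----------------------------------------------- zero vs nonzero groups --

def test_compare_zero_vs_nonzero_identical_groups():
    df = pd.DataFrame({
        "motif_id": [f"m{i}" for i in range(8)],
        "class_combo": ["TF-TF"] * 8,
        "similarity": [0, 0, 0, 0, 0.5, 0.5, 0.5, 0.5],
        "ppi_z": [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0],
    })
    out = compare_zero_vs_nonzero(df)
    assert len(out) == 1
    row = out.iloc[0]
    assert row.mean_zero == row.mean_nonzero
    assert row.p_value == pytest.approx(1.0, abs=0.05)


def test_compare_zero_vs_nonzero_detects_planted_direction():
    rng = np.random.default_rng(3)
    n = 30
    df = pd.DataFrame({
        "motif_id": [f"m{i}" for i in range(2 * n)],
        "class_combo": ["TF-TF"] * (2 * n),
        "similarity": [0.0] * n + [0.6] * n,
        "ppi_z": np.concatenate([rng.normal(0, 1, n), rng.normal(3, 1, n)]),
    })
    row = compare_zero_vs_nonzero(df).iloc[0]
    assert row.mean_nonzero > row.mean_zero
    assert row.p_value < 0.01


def test_compare_zero_vs_nonzero_small_group_flagged():
    df = pd.DataFrame({
        "motif_id": ["m1", "m2"],
        "class_combo": ["TF-TF"] * 2,
        "similarity": [0.0, 0.4],
        "ppi_z": [1.0, 2.0],
    })
    assert math.isnan(compare_zero_vs_nonzero(df).iloc[0].p_value)


def test_build_similarity_table_shape():
    motifs = [
        MotifInstance(CROSSTALK, TF_TF, ("A", "B"), frozenset({"s"}),
                      frozenset({"a"}), frozenset({"b"})),
        MotifInstance(CROSSTALK, TF_TF, ("A", "C"), frozenset({"s"}),
                      frozenset({"a"}), frozenset({"c"})),
    ]
    keys = [m.key for m in motifs]
    table = build_similarity_table(
        motifs, {keys[0]: 0.5}, {keys[0]: 1.0}, {}
    )
    assert len(table) == 1 and math.isnan(table.property_z.iloc[0])


# ------------------------------------------------- crosstalk functions --

def test_crosstalk_functions_query_is_inter_edge_endpoints():
    ann = AnnotationMap(
        {"T": frozenset({"a1", "b1"}), "ALL": frozenset({"a1", "a2", "b1", "b2"})},
        {"T": "t", "ALL": "all"},
    )
    motif = MotifInstance(
        CROSSTALK, TF_TF, ("A", "B"), frozenset(),
        frozenset({"a1", "a2"}), frozenset({"b1", "b2"}),
    )
    pin = nx.Graph([("a1", "b1"), ("a1", "a2")])  # intra edge must not count
    res = crosstalk_functions(motif, pin, ann, alpha=0.5)
    assert not res.flagged
    # the query was exactly {a1, b1}: term T overlaps fully
    assert res.table.set_index("term_id").loc["T", "overlap"] == 2


def test_crosstalk_functions_no_inter_edges_flagged():
    ann = AnnotationMap({"T": frozenset({"a1"})}, {"T": "t"})
    motif = MotifInstance(
        CROSSTALK, TF_TF, ("A", "B"), frozenset(),
        frozenset({"a1"}), frozenset({"b1"}),
    )
    res = crosstalk_functions(motif, nx.Graph([("a1", "x")]), ann)
    assert res.flagged and res.reported == frozenset()


def test_crosstalk_functions_recovers_planted_term():
    rng = np.random.default_rng(9)
    pool = [f"g{i:02d}" for i in range(40)]
    priv_a, priv_b = frozenset(pool[:8]), frozenset(pool[8:16])
    motif = MotifInstance(CROSSTALK, TF_TF, ("A", "B"), frozenset(),
                          priv_a, priv_b)
    # wire the planted term's genes across the private sets
    planted = sorted(priv_a)[:4] + sorted(priv_b)[:4]
    pin = nx.Graph()
    pin.add_edges_from(zip(planted[:4], planted[4:]))
    terms = {"T_planted": frozenset(planted), "ALL": frozenset(pool)}
    for j in range(8):
        terms[f"T{j}"] = frozenset(rng.choice(pool, 8, replace=False))
    ann = AnnotationMap(terms, {t: t for t in terms})
    res = crosstalk_functions(motif, pin, ann, alpha=0.05)
    assert "T_planted" in res.reported


# ------------------------------------------------------- term ranking --

def test_rank_processes_proportions_and_coverage():
    single = {"m1": frozenset({"t1", "t2", "t3"})}
    table, coverage = rank_processes(single, top_k=20)
    assert set(table.proportion) == {1.0} and coverage == 1.0

    per_motif = {
        "m1": frozenset({"t1"}), "m2": frozenset({"t1", "t2"}),
        "m3": frozenset({"t3"}), "m4": frozenset({"t4"}),
    }
    table, coverage = rank_processes(per_motif, top_k=2)
    assert table.set_index("term_id").loc["t1", "proportion"] == 0.5
    # coverage non-decreasing in top_k
    coverages = [rank_processes(per_motif, k)[1] for k in (1, 2, 3, 4)]
    assert coverages == sorted(coverages)
    # with every term included, coverage equals fraction with any enrichment
    assert rank_processes(per_motif, 100)[1] == 1.0
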
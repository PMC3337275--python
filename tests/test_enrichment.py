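"""The Bernoulli z-score, its permutation oracle, and enrichment summaries."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regmotif.enrichment import (
    background_probability,
    bernoulli_z,
    bottomup_scores,
    crosstalk_ppi_decomposition,
    observed_and_tested,
    permutation_z_oracle,
    threshold_sweep,
    topdown_scores,
)
from regmotif.motifs import (
    CO_REGULATION,
    CROSSTALK,
    TF_TF,
    MotifInstance,
    enumerate_motifs,
)

from conftest import make_grn


# ------------------------------------------------- background probability --

def test_background_probability_cases():
    complete = nx.complete_graph(4)
    assert background_probability(complete, complete.nodes) == 1.0
    empty = nx.empty_graph(200)
    assert background_probability(empty, empty.nodes) == 0.0
    g = nx.Graph([("a", "b"), ("c", "d")])
    g.add_node("e")
    assert background_probability(g, g.nodes) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        background_probability(g, ["a"])


# ------------------------------------------------------------- z-score --

@pytest.mark.parametrize(
    "observed,n,p,expected",
    [
        (10, 100, 0.1, 0.0),                       # at expectation
        (20, 100, 0.1, 10 / 3),                    # closed form
        (0, 50, 0.1, -5 / math.sqrt(4.5)),         # depletion
    ],
)
def test_bernoulli_z_closed_form(observed, n, p, expected):
    assert bernoulli_z(observed, n, p) == pytest.approx(expected, abs=1e-12)


def test_bernoulli_z_flags_degenerate_inputs():
    assert math.isnan(bernoulli_z(0, 0, 0.5))
    assert math.isnan(bernoulli_z(0, 10, 0.0))
    assert math.isnan(bernoulli_z(10, 10, 1.0))
    with pytest.raises(ValueError):
        bernoulli_z(11, 10, 0.5)
    with pytest.raises(ValueError):
        bernoulli_z(1, 10, 1.5)


@settings(max_examples=60, derandomize=True)
@given(
    n=st.integers(1, 10_000),
    k=st.integers(0, 500),
    p=st.floats(0.01, 0.99),
)
def test_bernoulli_z_antisymmetric_around_expectation(n, k, p):
    """z(E+k) == -z(E-k) whenever both counts are feasible."""
    e = n * p
    hi, lo = e + k, e - k
    if not (0 <= lo and hi <= n):
        return
    # use the formula directly on the (possibly fractional) counts
    denom = math.sqrt(n * p * (1 - p))
    assert (hi - e) / denom == pytest.approx(-((lo - e) / denom), abs=1e-9)


# ------------------------------------------------------------ top-down --

def test_topdown_toy_crosstalk_score(toy_pin):
    """Hand-computed: O=1, N=2, p=0.2 -> z = 0.6/sqrt(0.32)."""
    motif = MotifInstance(
        CROSSTALK, TF_TF, ("A", "B"),
        shared=frozenset({"c1", "c2"}),
        private_a=frozenset({"a1", "a2"}),
        private_b=frozenset({"b1"}),
    )
    (res,) = topdown_scores([motif], toy_pin, toy_pin.nodes)
    assert (res.observed, res.n_pairs) == (1, 2)
    assert res.p_background == pytest.approx(0.2)
    assert res.z == pytest.approx(0.6 / math.sqrt(0.32))


def test_topdown_flags_motifs_absent_from_pin(toy_pin):
    motif = MotifInstance(
        CROSSTALK, TF_TF, ("A", "B"),
        shared=frozenset(),
        private_a=frozenset({"zz1"}),
        private_b=frozenset({"zz2"}),
    )
    (res,) = topdown_scores([motif], toy_pin, toy_pin.nodes)
    assert res.flagged and res.n_pairs == 0


def test_topdown_result_count_matches_motifs(toy_pin):
    motifs = [
        MotifInstance(CROSSTALK, TF_TF, (f"R{i}", "S"), frozenset(),
                      frozenset({"a1"}), frozenset({"b1"}))
        for i in range(5)
    ]
    assert len(topdown_scores(motifs, toy_pin, toy_pin.nodes)) == 5


# --------------------------------------------------- permutation oracle --

def _random_crosstalk_motif(rng, universe, ka, kb):
    picks = rng.choice(len(universe), ka + kb, replace=False)
    return MotifInstance(
        CROSSTALK, TF_TF, ("A", "B"), frozenset(),
        frozenset(universe[i] for i in picks[:ka]),
        frozenset(universe[i] for i in picks[ka:]),
    )


def test_permutation_oracle_deterministic_and_degenerate():
    g = nx.empty_graph(30)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(30)})
    universe = sorted(g.nodes)
    motif = _random_crosstalk_motif(np.random.default_rng(0), universe, 4, 4)
    assert math.isnan(permutation_z_oracle(motif, g, universe, 200, seed=1))
    g2 = nx.gnp_random_graph(30, 0.2, seed=5)
    g2 = nx.relabel_nodes(g2, {i: f"n{i}" for i in range(30)})
    z1 = permutation_z_oracle(motif, g2, universe, 500, seed=9)
    z2 = permutation_z_oracle(motif, g2, universe, 500, seed=9)
    assert z1 == z2


def test_analytic_z_matches_oracle_on_er_graphs():
    """Spot check of the oracle equivalence (full battery in acceptance)."""
    for trial in range(3):
        rng = np.random.default_rng([7, trial])
        g = nx.gnp_random_graph(120, 0.05, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(120)})
        universe = sorted(g.nodes)
        motif = _random_crosstalk_motif(rng, universe, 12, 12)
        p = background_probability(g, universe)
        o, n = observed_and_tested(motif, g)
        za = bernoulli_z(o, n, p)
        zp = permutation_z_oracle(motif, g, universe, 4000,
                                  seed=int(rng.integers(2**31)))
        assert abs(za - zp) <= 0.35


def test_oracle_handles_within_set_motifs():
    g = nx.gnp_random_graph(80, 0.1, seed=3)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(80)})
    universe = sorted(g.nodes)
    motif = MotifInstance(
        CO_REGULATION, TF_TF, ("A", "B"), frozenset(universe[:10])
    )
    p = background_probability(g, universe)
    o, n = observed_and_tested(motif, g)
    za = bernoulli_z(o, n, p)
    zp = permutation_z_oracle(motif, g, universe, 4000, seed=11)
    assert abs(za - zp) <= 0.5


# ------------------------------------------------------------ bottom-up --

def test_bottomup_full_coverage_construction(toy_pin):
    """Every PIN gene is a private target of the one synergistic pair."""
    grn = make_grn(tf={
        "A": {"s1", "s2", "a1", "a2", "c1"},
        "B": {"s1", "s2", "b1", "c2", "c3"},
    })
    motifs = enumerate_motifs(grn, CROSSTALK, TF_TF, 2)
    universe = set(toy_pin.nodes)  # a1,a2,b1,c1,c2,c3
    (res,) = bottomup_scores(motifs, toy_pin, universe)
    assert res.coverage == pytest.approx(100.0)
    assert 0.0 <= res.coverage <= 100.0


def test_bottomup_unions_overlapping_pairs(toy_pin):
    m1 = MotifInstance(CROSSTALK, TF_TF, ("A", "B"), frozenset(),
                       frozenset({"a1", "a2"}), frozenset({"b1"}))
    m2 = MotifInstance(CROSSTALK, TF_TF, ("A", "C"), frozenset(),
                       frozenset({"a1"}), frozenset({"b1"}))
    (res,) = bottomup_scores([m1, m2], toy_pin, toy_pin.nodes)
    assert res.n_pairs == 2  # (a1,b1) counted once, plus (a2,b1)
    assert res.observed == 1


# ------------------------------------------------------ threshold sweep --

def test_threshold_sweep_shape_and_monotonicity():
    grn = make_grn(tf={
        "A": {f"g{i}" for i in range(12)},
        "B": {f"g{i}" for i in range(8)} | {"h1"},
        "C": {"g0", "g1", "x1", "x2"},
        "D": {"y1", "y2"},
    })
    pin = nx.Graph()
    pin.add_nodes_from([f"g{i}" for i in range(12)] + ["h1", "x1", "x2", "y1", "y2"])
    pin.add_edges_from([(f"g{i}", f"g{j}") for i in range(8) for j in range(i + 1, 8)])
    pin.add_edges_from([("x1", "y1"), ("x2", "y2")])
    universe = set(pin.nodes)
    sweep = threshold_sweep(grn, pin, universe, CO_REGULATION, TF_TF, [2, 5, 8])
    assert len(sweep) == 3
    assert list(sweep.n_motifs) == sorted(sweep.n_motifs, reverse=True)
    # only the large-overlap pair (A,B) has PPI-dense shared targets, so the
    # median z rises once the small-overlap pair (A,C) is filtered out
    assert sweep.median_z.iloc[-1] > sweep.median_z.iloc[0]
    with pytest.raises(ValueError):
        threshold_sweep(grn, pin, universe, CO_REGULATION, TF_TF, [5, 2])


# -------------------------------------------------------- decomposition --

def _toy_crosstalk():
    return MotifInstance(
        CROSSTALK, TF_TF, ("A", "B"),
        shared=frozenset({"s1"}),
        private_a=frozenset({"a1", "a2"}),
        private_b=frozenset({"b1"}),
    )


def test_decomposition_hand_classified_toy():
    pin = nx.Graph([("a1", "a2"), ("a1", "b1"), ("s1", "b1")])
    d = crosstalk_ppi_decomposition(_toy_crosstalk(), pin)
    assert d.n_edges == 3
    assert d.fractions == pytest.approx((1 / 3, 0.0, 1 / 3, 1 / 3))


def test_decomposition_fractions_sum_to_one_and_swap_symmetric():
    rng = np.random.default_rng(12)
    g = nx.gnp_random_graph(40, 0.15, seed=4)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(40)})
    nodes = sorted(g.nodes)
    motif = MotifInstance(
        CROSSTALK, TF_TF, ("A", "B"),
        shared=frozenset(nodes[:8]),
        private_a=frozenset(nodes[8:20]),
        private_b=frozenset(nodes[20:30]),
    )
    d = crosstalk_ppi_decomposition(motif, g)
    assert sum(d.fractions) == pytest.approx(1.0)
    swapped = MotifInstance(
        CROSSTALK, TF_TF, ("B", "A"),
        shared=motif.shared, private_a=motif.private_b,
        private_b=motif.private_a,
    )
    ds = crosstalk_ppi_decomposition(swapped, g)
    assert ds.intra_a == d.intra_b and ds.intra_b == d.intra_a
    assert ds.inter == d.inter and ds.involving_shared == d.involving_shared


def test_decomposition_empty_shared_has_no_shared_fraction():
    motif = MotifInstance(
        CROSSTALK, TF_TF, ("A", "B"), frozenset(),
        frozenset({"a1", "a2"}), frozenset({"b1"}),
    )
    pin = nx.Graph([("a1", "b1")])
    d = crosstalk_ppi_decomposition(motif, pin)
    assert d.involving_shared == 0 and d.inter == 1
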
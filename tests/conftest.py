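"""Shared fixtures: hand-built toy networks and a small synthetic bundle."""

from __future__ import annotations

import networkx as nx
import pytest

from regmotif.assembly import MIRNA, TF, RegulatoryNetwork
from regmotif.synthetic import SyntheticConfig


def make_grn(tf: dict[str, set[str]] | None = None,
             mirna: dict[str, set[str]] | None = None) -> RegulatoryNetwork:
    """Build a RegulatoryNetwork from literal target-set dicts."""
    tf = tf or {}
    mirna = mirna or {}
    targets = {**tf, **mirna}
    classes = {r: TF for r in tf}
    classes.update({r: MIRNA for r in mirna})
    return RegulatoryNetwork(targets, classes)


@pytest.fixture
def hand_grn() -> RegulatoryNetwork:
    """Six regulators with exactly known pair structure at threshold 2.

    TF pairs:   (T1,T2) share {g2,g3} -> synergistic, both privates non-empty
                (T1,T3) share {g1}    -> independent, both privates non-empty
                (T2,T3) share {}      -> independent, both privates non-empty
    miR pairs:  (M1,M2) share {g5,g6} -> synergistic, M2 has no private
                (M1,M3) share {g7}    -> independent (1 shared, excluded from
                                          private sets), both privates left
                (M2,M3) share {}      -> independent
    """
    return make_grn(
        tf={
            "T1": {"g1", "g2", "g3"},
            "T2": {"g2", "g3", "g4"},
            "T3": {"g1", "g5"},
        },
        mirna={
            "M1": {"g5", "g6", "g7"},
            "M2": {"g5", "g6"},
            "M3": {"g7", "g8"},
        },
    )


@pytest.fixture
def toy_pin() -> nx.Graph:
    """Six genes, three interactions: background probability 3/15 = 0.2."""
    g = nx.Graph()
    g.add_nodes_from(["a1", "a2", "b1", "c1", "c2", "c3"])
    g.add_edges_from([("a1", "b1"), ("c1", "c2"), ("c2", "c3")])
    return g


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-scale synthetic configuration used by slower integration tests."""
    return SyntheticConfig(n_genes=200, n_tfs=10, n_mirnas=10, seed=7)
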
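"""PPI enrichment of motif tested-pair universes.

The central statistic treats each tested gene pair as an independent
Bernoulli trial whose success probability p is the background interaction
density of the PIN on the analysis universe.  With N tested pairs and O
observed interacting pairs,

    z = (O - N*p) / sqrt(N*p*(1-p))

which is computable in constant time, replacing the usual random-sampling
significance evaluation.  A seeded permutation oracle (random gene sets of
the same shape) is provided to validate the analytic score.

Enrichment is scored in two directions: top-down (one score per motif
instance) and bottom-up (one score per motif category, over the union of all
its instances' tested pairs, with the coverage of the gene universe).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections.abc import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .assembly import RegulatoryNetwork
from .motifs import (
    CO_REGULATION,
    CROSSTALK,
    SINGLE_REGULATION,
    MotifInstance,
    enumerate_motifs,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """PPI enrichment of one motif (top-down) or motif category (bottom-up).

    ``z`` is NaN when the score is undefined (no tested pairs in the PIN, or
    a degenerate background probability); it is never silently zero.
    ``coverage`` (percent of universe genes appearing in the tested-pair
    universe) is filled for bottom-up results only.
    """

    label: str
    motif_type: str
    class_combo: str
    regulators: tuple[str, ...]
    n_pairs: int
    observed: int
    p_background: float
    z: float
    coverage: float | None = None

    @property
    def flagged(self) -> bool:
        return not math.isfinite(self.z)


def background_probability(pin: nx.Graph, universe: Iterable[str]) -> float:
    """Background interaction probability: PIN density on the universe."""
    nodes = set(universe)
    if len(nodes) < 2:
        raise ValueError("universe must contain at least 2 genes")
    n_edges = sum(
        1 for a, b in pin.edges if a in nodes and b in nodes
    )
    n_possible = len(nodes) * (len(nodes) - 1) // 2
    return n_edges / n_possible


def bernoulli_z(observed: int, n_pairs: int, p: float) -> float:
    """Analytic Bernoulli z-score of an observed interacting-pair count.

    Undefined (NaN) when n_pairs == 0 or p is 0 or 1.
    """
    if n_pairs < 0 or observed < 0 or observed > n_pairs:
        raise ValueError("need 0 <= observed <= n_pairs")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    if n_pairs == 0 or p <= 0.0 or p >= 1.0:
        return float("nan")
    return (observed - n_pairs * p) / math.sqrt(n_pairs * p * (1.0 - p))


def _motif_pin_sets(motif: MotifInstance, pin: nx.Graph):
    """Motif gene sets restricted to genes present in the PIN.

    Pairs whose genes are absent from the PIN carry no interaction evidence
    and are dropped from the tested-pair count.
    """
    if motif.motif_type in (SINGLE_REGULATION, CO_REGULATION):
        return (sorted(g for g in motif.shared if pin.has_node(g)),)
    return (
        sorted(g for g in motif.private_a if pin.has_node(g)),
        sorted(g for g in motif.private_b if pin.has_node(g)),
    )


def _count_within(pin: nx.Graph, genes: Sequence[str]) -> tuple[int, int]:
    gene_set = set(genes)
    n = len(genes)
    obs = sum(len(set(pin.adj[g]) & gene_set) for g in genes) // 2
    return obs, n * (n - 1) // 2


def _count_between(
    pin: nx.Graph, genes_a: Sequence[str], genes_b: Sequence[str]
) -> tuple[int, int]:
    set_b = set(genes_b)
    obs = sum(len(set(pin.adj[g]) & set_b) for g in genes_a)
    return obs, len(genes_a) * len(genes_b)


def observed_and_tested(motif: MotifInstance, pin: nx.Graph) -> tuple[int, int]:
    """(O, N): observed interacting tested pairs and tested-pair count."""
    sets = _motif_pin_sets(motif, pin)
    if len(sets) == 1:
        return _count_within(pin, sets[0])
    return _count_between(pin, sets[0], sets[1])


def score_motif(motif: MotifInstance, pin: nx.Graph, p: float) -> EnrichmentResult:
    obs, n = observed_and_tested(motif, pin)
    return EnrichmentResult(
        label="|".join(motif.key),
        motif_type=motif.motif_type,
        class_combo=motif.class_combo,
        regulators=motif.regulators,
        n_pairs=n,
        observed=obs,
        p_background=p,
        z=bernoulli_z(obs, n, p),
    )


def topdown_scores(
    motifs: Sequence[MotifInstance], pin: nx.Graph, universe: Iterable[str]
) -> list[EnrichmentResult]:
    """One enrichment score per motif instance."""
    p = background_probability(pin, universe)
    return [score_motif(m, pin, p) for m in motifs]


def median_z(results: Sequence[EnrichmentResult]) -> float:
    """Median of the finite per-motif z-scores (box-plot annotation style)."""
    zs = [r.z for r in results if math.isfinite(r.z)]
    return float(np.median(zs)) if zs else float("nan")


def bottomup_scores(
    motifs: Sequence[MotifInstance], pin: nx.Graph, universe: Iterable[str]
) -> list[EnrichmentResult]:
    """One enrichment score per (motif_type, class_combo) category.

    A category's tested-pair universe is the deduplicated union of its motif
    instances' tested pairs; coverage is the percentage of universe genes
    touched by that pair universe.
    """
    universe = frozenset(universe)
    p = background_probability(pin, universe)
    by_cat: dict[tuple[str, str], list[MotifInstance]] = {}
    for m in motifs:
        by_cat.setdefault((m.motif_type, m.class_combo), []).append(m)
    out = []
    for (mtype, combo), members in sorted(by_cat.items()):
        pair_universe: set[frozenset[str]] = set()
        for m in members:
            sets = _motif_pin_sets(m, pin)
            if len(sets) == 1:
                genes = sets[0]
                pair_universe.update(
                    frozenset((genes[i], genes[j]))
                    for i in range(len(genes))
                    for j in range(i + 1, len(genes))
                )
            else:
                a_set, b_set = sets
                pair_universe.update(
                    frozenset((a, b)) for a in a_set for b in b_set if a != b
                )
        n = len(pair_universe)
        obs = sum(1 for pair in pair_universe if pin.has_edge(*tuple(pair)))
        genes_touched = set()
        for pair in pair_universe:
            genes_touched.update(pair)
        coverage = 100.0 * len(genes_touched & universe) / len(universe)
        out.append(
            EnrichmentResult(
                label=f"{mtype}|{combo}",
                motif_type=mtype,
                class_combo=combo,
                regulators=(),
                n_pairs=n,
                observed=obs,
                p_background=p,
                z=bernoulli_z(obs, n, p),
                coverage=coverage,
            )
        )
    return out


def _universe_adjacency(pin: nx.Graph, universe: Iterable[str]):
    nodes = sorted(universe)
    index = {g: i for i, g in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for a, b in pin.edges:
        ia, ib = index.get(a), index.get(b)
        if ia is not None and ib is not None:
            adj[ia, ib] = adj[ib, ia] = True
    return nodes, index, adj


def permutation_z_oracle(
    motif: MotifInstance,
    pin: nx.Graph,
    universe: Iterable[str],
    n_samples: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation z-score: the sampling baseline the analytic score replaces.

    Draws ``n_samples`` random gene sets of the same shape as the motif's
    tested universe (same private-set sizes for cross-set motifs, same set
    size for within-set motifs) uniformly from the universe, and standardises
    the observed interacting-pair count against that null.  NaN when the null
    is degenerate (zero standard deviation).
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = np.random.default_rng(seed)
    nodes, index, adj = _universe_adjacency(pin, universe)
    n_universe = len(nodes)
    sets = _motif_pin_sets(motif, pin)
    sets = tuple(
        [g for g in s if g in index] for s in sets
    )
    if len(sets) == 1:
        (genes,) = sets
        k = len(genes)
        idx = np.array([index[g] for g in genes], dtype=int)
        obs = int(adj[np.ix_(idx, idx)].sum()) // 2
        draw = _random_subsets(rng, n_samples, n_universe, k)
        sub = adj[draw[:, :, None], draw[:, None, :]]
        o_rand = sub.sum(axis=(1, 2)) // 2
    else:
        genes_a, genes_b = sets
        ka, kb = len(genes_a), len(genes_b)
        ia = np.array([index[g] for g in genes_a], dtype=int)
        ib = np.array([index[g] for g in genes_b], dtype=int)
        obs = int(adj[np.ix_(ia, ib)].sum())
        draw = _random_subsets(rng, n_samples, n_universe, ka + kb)
        da, db = draw[:, :ka], draw[:, ka:]
        o_rand = adj[da[:, :, None], db[:, None, :]].sum(axis=(1, 2))
    sd = float(o_rand.std())
    if sd == 0.0:
        return float("nan")
    return (obs - float(o_rand.mean())) / sd


def _random_subsets(rng, n_samples: int, n: int, k: int) -> np.ndarray:
    """n_samples random k-subsets of range(n), as an (n_samples, k) index array."""
    if k > n:
        raise ValueError("cannot sample more genes than the universe holds")
    r = rng.random((n_samples, n))
    return np.argpartition(r, k - 1, axis=1)[:, :k]


def threshold_sweep(
    grn: RegulatoryNetwork,
    pin: nx.Graph,
    universe: Iterable[str],
    motif_type: str,
    class_combo: str,
    thresholds: Sequence[int],
) -> pd.DataFrame:
    """Re-screen and re-score one motif family over a synergy-threshold sweep.

    Returns one row per threshold with the motif count and the median
    per-motif z; the motif count is non-increasing in the threshold.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    universe = frozenset(universe)
    rows = []
    for theta in thresholds:
        motifs = enumerate_motifs(grn, motif_type, class_combo, theta)
        results = topdown_scores(motifs, pin, universe)
        rows.append((theta, len(motifs), median_z(results)))
    return pd.DataFrame(rows, columns=["threshold", "n_motifs", "median_z"])


@dataclass(frozen=True)
class CrosstalkDecomposition:
    """Classification of the PPIs among one crosstalk motif's target genes.

    Over all PIN edges with both endpoints in shared ∪ private_a ∪ private_b:
    intra_a / intra_b have both endpoints in one private set, inter has one in
    each, involving_shared has at least one endpoint among shared targets.
    Fractions sum to 1.
    """

    n_edges: int
    intra_a: int
    intra_b: int
    inter: int
    involving_shared: int

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        if self.n_edges == 0:
            return (float("nan"),) * 4
        return (
            self.intra_a / self.n_edges,
            self.intra_b / self.n_edges,
            self.inter / self.n_edges,
            self.involving_shared / self.n_edges,
        )


def crosstalk_ppi_decomposition(
    motif: MotifInstance, pin: nx.Graph
) -> CrosstalkDecomposition:
    """Decompose the PPIs among a crosstalk motif's targets into intra/inter
    private-set connections and interactions involving shared targets."""
    if motif.motif_type != CROSSTALK:
        raise ValueError("decomposition is defined for crosstalk motifs")
    shared, priv_a, priv_b = motif.shared, motif.private_a, motif.private_b
    all_genes = shared | priv_a | priv_b
    intra_a = intra_b = inter = with_shared = 0
    for u, v in pin.edges:
        if u not in all_genes or v not in all_genes:
            continue
        if u in shared or v in shared:
            with_shared += 1
        elif u in priv_a and v in priv_a:
            intra_a += 1
        elif u in priv_b and v in priv_b:
            intra_b += 1
        else:
            inter += 1
    n = intra_a + intra_b + inter + with_shared
    if n == 0:
        logger.info("crosstalk motif %s has no qualifying PPIs", motif.key)
    return CrosstalkDecomposition(n, intra_a, intra_b, inter, with_shared)


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        (
            r.motif_type, r.class_combo, "|".join(r.regulators),
            r.n_pairs, r.observed, r.p_background, r.z,
            "" if r.coverage is None else r.coverage,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "motif_type", "class_combo", "regulators",
            "n_pairs", "observed", "p_background", "z", "coverage",
        ],
    )
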
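"""Functional (term) enrichment and regulator functional similarity.

Gene sets are tested for term enrichment with a one-sided hypergeometric
test over the annotation universe, Benjamini–Hochberg corrected across the
tested terms.  Functional similarity between two regulators is the Jaccard
index of their enriched term-id sets (an overlap-coefficient variant is
available); zero similarity means the two regulators share no enriched
function.  Crosstalk-function analysis enriches the genes participating in a
crosstalk motif's inter-private PPIs, and term ranking summarises which
processes recur across motifs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .motifs import CROSSTALK, MotifInstance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationMap:
    """Gene→function annotation: term id → gene set, with term labels."""

    term_genes: Mapping[str, frozenset[str]]
    term_labels: Mapping[str, str]

    def __post_init__(self) -> None:
        for term, genes in self.term_genes.items():
            if not genes:
                raise ValueError(f"term {term} annotates no genes")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.term_genes.values():
            out |= genes
        return frozenset(out)

    @property
    def key(self) -> str:
        """Content fingerprint used to detect annotation mismatches."""
        import hashlib

        h = hashlib.sha256()
        for term in sorted(self.term_genes):
            h.update(term.encode())
            h.update(b"\x00")
            for g in sorted(self.term_genes[term]):
                h.update(g.encode())
                h.update(b"\x01")
        return h.hexdigest()


def read_gmt(path: str | Path, term_filter: str | None = None) -> AnnotationMap:
    """Read a GMT annotation file (term_id <tab> label <tab> genes...).

    ``term_filter`` keeps only terms whose id or label contains the given
    substring (e.g. a namespace tag).
    """
    term_genes: dict[str, frozenset[str]] = {}
    term_labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            term, label, genes = fields[0], fields[1], fields[2:]
            if term_filter and term_filter not in term and term_filter not in label:
                continue
            term_genes[term] = frozenset(g for g in genes if g)
            term_labels[term] = label
    if not term_genes:
        raise ValueError(f"{path}: no annotation terms read")
    return AnnotationMap(term_genes, term_labels)


def write_gmt(annotation: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation.term_genes):
            genes = "\t".join(sorted(annotation.term_genes[term]))
            fh.write(f"{term}\t{annotation.term_labels.get(term, term)}\t{genes}\n")


@dataclass(frozen=True)
class EnrichedTermSet:
    """Result of one enrichment run: full term table plus the reported terms.

    ``table`` has one row per tested term sorted by p-value (term_id, label,
    overlap, p_value, adjusted_p); ``reported`` are the term ids with
    BH-adjusted p <= alpha and overlap >= 1.
    """

    table: pd.DataFrame
    reported: frozenset[str]
    alpha: float
    annotation_key: str
    flagged: bool = False

    @property
    def term_ids(self) -> frozenset[str]:
        return self.reported


def enrich_terms(
    genes: Iterable[str], annotation: AnnotationMap, alpha: float = 0.05
) -> EnrichedTermSet:
    """Hypergeometric term enrichment of a gene set with BH correction.

    The population is the annotation universe; query genes outside it are
    ignored (an empty intersection is an error).
    """
    universe = annotation.universe
    query = frozenset(genes) & universe
    if not query:
        raise ValueError("query genes share no members with the annotation universe")
    m_total = len(universe)
    n_query = len(query)
    rows = []
    for term in sorted(annotation.term_genes):
        term_set = annotation.term_genes[term]
        k = len(query & term_set)
        p = float(hypergeom.sf(k - 1, m_total, len(term_set), n_query))
        rows.append((term, annotation.term_labels.get(term, term), k, p))
    table = pd.DataFrame(rows, columns=["term_id", "label", "overlap", "p_value"])
    table["adjusted_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table.sort_values(
        ["p_value", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    reported = frozenset(
        table.loc[(table.adjusted_p <= alpha) & (table.overlap >= 1), "term_id"]
    )
    return EnrichedTermSet(table, reported, alpha, annotation.key)


def functional_similarity(
    terms_a: EnrichedTermSet,
    terms_b: EnrichedTermSet,
    method: str = "jaccard",
) -> float:
    """Similarity of two regulators' enriched term sets.

    Jaccard |A∩B|/|A∪B| by default; ``overlap`` uses |A∩B|/min(|A|,|B|).
    Zero when the sets are disjoint ("no common enriched functions"); also 0
    when both are empty.  Both runs must use the same annotation and alpha.
    """
    if terms_a.annotation_key != terms_b.annotation_key or terms_a.alpha != terms_b.alpha:
        raise ValueError("enrichment runs used different annotations or alpha")
    a, b = terms_a.reported, terms_b.reported
    if not a and not b:
        logger.info("both enriched term sets empty; similarity 0 (flagged)")
        return 0.0
    inter = len(a & b)
    if method == "jaccard":
        return inter / len(a | b)
    if method == "overlap":
        denom = min(len(a), len(b))
        return inter / denom if denom else 0.0
    raise ValueError(f"unknown similarity method {method!r}")


def compare_zero_vs_nonzero(
    motif_table: pd.DataFrame,
) -> pd.DataFrame:
    """Compare PPI/property z of crosstalk motifs with zero vs non-zero
    functional similarity.

    ``motif_table`` needs columns motif_id, class_combo, similarity, and one
    column per measure (e.g. ppi_z, property_z).  Returns one row per
    (measure, class_combo) with the two group means and a two-sided
    Mann-Whitney p-value; groups with fewer than 2 members are flagged with
    NaN p.
    """
    required = {"motif_id", "class_combo", "similarity"}
    missing = required - set(motif_table.columns)
    if missing:
        raise ValueError(f"motif_table missing columns {sorted(missing)}")
    measures = [
        c for c in motif_table.columns if c not in required
    ]
    rows = []
    for combo, sub in motif_table.groupby("class_combo"):
        zero = sub[sub.similarity == 0]
        nonzero = sub[sub.similarity > 0]
        for measure in measures:
            x = zero[measure].dropna().to_numpy()
            y = nonzero[measure].dropna().to_numpy()
            if len(x) < 2 or len(y) < 2:
                p = float("nan")
            elif np.array_equal(np.sort(x), np.sort(y)):
                p = 1.0
            else:
                p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
            rows.append(
                (
                    measure, combo, len(x), len(y),
                    float(x.mean()) if len(x) else float("nan"),
                    float(y.mean()) if len(y) else float("nan"),
                    p,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "measure", "class_combo", "n_zero", "n_nonzero",
            "mean_zero", "mean_nonzero", "p_value",
        ],
    )


def build_similarity_table(
    motifs: Sequence[MotifInstance],
    similarities: Mapping[tuple[str, ...], float],
    ppi_z: Mapping[tuple[str, ...], float],
    property_z: Mapping[tuple[str, ...], float],
) -> pd.DataFrame:
    """Assemble the per-motif table consumed by compare_zero_vs_nonzero.

    All mappings are keyed by motif.key; motifs missing a similarity or a
    z-score are skipped.
    """
    rows = []
    for m in motifs:
        k = m.key
        if k not in similarities:
            continue
        rows.append(
            (
                "|".join(k), m.class_combo, similarities[k],
                ppi_z.get(k, float("nan")), property_z.get(k, float("nan")),
            )
        )
    return pd.DataFrame(
        rows, columns=["motif_id", "class_combo", "similarity", "ppi_z", "property_z"]
    )


def crosstalk_functions(
    motif: MotifInstance,
    pin: nx.Graph,
    annotation: AnnotationMap,
    alpha: float = 0.05,
) -> EnrichedTermSet:
    """Enrich the genes participating in a crosstalk motif's inter-private PPIs.

    The query set is the endpoints of tested pairs (one gene in each private
    set) that are PIN edges.  When the motif has no inter-private PPI the
    result is an empty, flagged term set.
    """
    if motif.motif_type != CROSSTALK:
        raise ValueError("crosstalk_functions is defined for crosstalk motifs")
    query: set[str] = set()
    priv_b = motif.private_b
    for a in motif.private_a:
        if not pin.has_node(a):
            continue
        for nb in pin.adj[a]:
            if nb in priv_b:
                query.add(a)
                query.add(nb)
    if not query:
        empty = pd.DataFrame(
            columns=["term_id", "label", "overlap", "p_value", "adjusted_p"]
        )
        return EnrichedTermSet(empty, frozenset(), alpha, annotation.key, flagged=True)
    return enrich_terms(query, annotation, alpha)


def rank_processes(
    per_motif_terms: Mapping[str, frozenset[str]],
    top_k: int = 20,
) -> tuple[pd.DataFrame, float]:
    """Rank terms by the proportion of motifs whose enriched set contains them.

    Returns the top-``top_k`` table (ties broken lexicographically by term
    id) and the coverage: the fraction of motifs containing at least one
    top-k term.
    """
    if not per_motif_terms:
        raise ValueError("need at least one motif with enrichment results")
    n_motifs = len(per_motif_terms)
    counts: dict[str, int] = {}
    for terms in per_motif_terms.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    table = pd.DataFrame(
        [(t, c, c / n_motifs) for t, c in ranked],
        columns=["term_id", "n_motifs", "proportion"],
    )
    top_terms = set(table.term_id)
    covered = sum(1 for terms in per_motif_terms.values() if terms & top_terms)
    return table, covered / n_motifs
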
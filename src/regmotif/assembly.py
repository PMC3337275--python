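"""Construction and merging of gene regulatory and protein interaction networks.

A gene regulatory network (GRN) is a directed bipartite map from regulators
(transcription factors or miRNA families) to target genes.  A protein
interaction network (PIN) is an undirected simple graph of physically
interacting proteins.  This module reads both from plain TSV/BED dialects,
assigns TF targets by promoter/binding-site overlap, merges networks from
several sources, and restricts both networks to their common gene universe so
that downstream enrichment statistics are computed over genes that appear in
both.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

TF = "TF"
MIRNA = "miRNA"
REGULATOR_CLASSES = (TF, MIRNA)


@dataclass(frozen=True)
class GeneAnnotation:
    """Minimal gene model: where transcription starts and on which strand."""

    gene_id: str
    chrom: str
    tss: int  # 0-based bp
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")


@dataclass(frozen=True)
class BindingSite:
    """A regulator binding site as a 0-based half-open genomic interval."""

    regulator_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"binding site for {self.regulator_id} has start {self.start} >= end {self.end}"
            )


@dataclass(frozen=True)
class RegulationEdge:
    regulator_id: str
    regulator_class: str
    target_id: str
    source: str = ""


class RegulatoryNetwork:
    """Directed bipartite regulator→target map with regulator classes.

    Edges are deduplicated on (regulator, target); per-edge source labels are
    kept as sets so a relationship supported by several databases carries all
    its provenance.  Self-regulation (regulator id == target id) is allowed.
    """

    def __init__(
        self,
        targets_of: Mapping[str, Iterable[str]],
        classes: Mapping[str, str],
        sources: Mapping[tuple[str, str], Iterable[str]] | None = None,
    ) -> None:
        self.targets_of: dict[str, frozenset[str]] = {
            r: frozenset(ts) for r, ts in targets_of.items()
        }
        for reg, ts in self.targets_of.items():
            if not ts:
                raise ValueError(f"regulator {reg} has no targets")
            if reg not in classes:
                raise ValueError(f"regulator {reg} has no class")
        self.classes: dict[str, str] = dict(classes)
        for reg, cls in self.classes.items():
            if cls not in REGULATOR_CLASSES:
                raise ValueError(f"unknown regulator class {cls!r} for {reg}")
        self.sources: dict[tuple[str, str], frozenset[str]] = {
            k: frozenset(v) for k, v in (sources or {}).items()
        }

    # -- basic views -------------------------------------------------------
    @property
    def regulators(self) -> list[str]:
        return sorted(self.targets_of)

    @property
    def targets(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self.targets_of.values():
            out |= ts
        return frozenset(out)

    @property
    def n_edges(self) -> int:
        return sum(len(ts) for ts in self.targets_of.values())

    def regulators_of_class(self, cls: str) -> list[str]:
        return sorted(r for r, c in self.classes.items() if c == cls)

    def edges(self) -> list[RegulationEdge]:
        out = []
        for reg in self.regulators:
            cls = self.classes[reg]
            for tgt in sorted(self.targets_of[reg]):
                src = ",".join(sorted(self.sources.get((reg, tgt), ())))
                out.append(RegulationEdge(reg, cls, tgt, src))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.regulator_id, e.regulator_class, e.target_id, e.source)
            for e in self.edges()
        ]
        return pd.DataFrame(
            rows, columns=["regulator_id", "regulator_class", "target_id", "source"]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self.targets_of == other.targets_of and self.classes == other.classes

    def __repr__(self) -> str:
        return (
            f"RegulatoryNetwork({len(self.targets_of)} regulators, "
            f"{len(self.targets)} targets, {self.n_edges} edges)"
        )


def _iter_tsv_rows(path: str | Path):
    """Yield (line_number, fields) for non-comment, non-blank TSV lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


_HEADER_TOKENS = {
    "regulator_id", "regulator", "target_id", "target", "gene_id", "gene",
    "id_a", "id_b", "protein_a", "protein_b", "chrom", "tss", "strand",
    "start", "end", "source",
}


def _looks_like_header(fields: Sequence[str]) -> bool:
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields)


def read_regulations(
    path: str | Path, regulator_class: str, source_label: str | None = None
) -> RegulatoryNetwork:
    """Read a regulator→target TSV into a RegulatoryNetwork.

    The file needs at least two tab-separated columns (regulator id, target
    id); further columns (e.g. scores) are ignored.  ``#`` comment lines and
    an optional header row are tolerated.  Rows are deduplicated.
    """
    if regulator_class not in REGULATOR_CLASSES:
        raise ValueError(f"regulator_class must be one of {REGULATOR_CLASSES}")
    source = source_label or Path(path).stem
    targets_of: dict[str, set[str]] = {}
    n_rows = 0
    first = True
    for lineno, fields in _iter_tsv_rows(path):
        if first:
            first = False
            if _looks_like_header(fields):
                continue
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(f"{path}: malformed row at line {lineno}: {fields!r}")
        reg, tgt = fields[0].strip(), fields[1].strip()
        targets_of.setdefault(reg, set()).add(tgt)
        n_rows += 1
    if not targets_of:
        raise ValueError(f"{path}: no regulation rows found")
    n_edges = sum(len(ts) for ts in targets_of.values())
    logger.info(
        "read %d rows (%d after dedup) from %s", n_rows, n_edges, path
    )
    classes = {r: regulator_class for r in targets_of}
    sources = {
        (r, t): {source} for r, ts in targets_of.items() for t in ts
    }
    return RegulatoryNetwork(targets_of, classes, sources)


def promoter_interval(
    annotation: GeneAnnotation, upstream_bp: int = 1000, downstream_bp: int = 500
) -> tuple[int, int]:
    """Promoter window around the TSS as a 0-based half-open interval.

    On the '+' strand upstream means smaller coordinates; on the '-' strand
    upstream means larger coordinates, so the window flips.
    """
    if annotation.strand == "+":
        start, end = annotation.tss - upstream_bp, annotation.tss + downstream_bp
    else:
        start, end = annotation.tss - downstream_bp, annotation.tss + upstream_bp
    if start < 0:
        logger.warning(
            "promoter of %s clipped at chromosome start", annotation.gene_id
        )
        start = 0
    return start, end


def map_binding_sites_to_targets(
    sites: Sequence[BindingSite],
    annotations: Sequence[GeneAnnotation],
    upstream_bp: int = 1000,
    downstream_bp: int = 500,
    min_overlap_bp: int = 1,
    source_label: str = "binding_sites",
) -> list[RegulationEdge]:
    """Assign TF targets by promoter/binding-site overlap.

    A gene becomes a target of a TF when its promoter window (default 1000 bp
    upstream and 500 bp downstream of the TSS) overlaps at least one binding
    site of that TF by at least ``min_overlap_bp`` base pairs.
    """
    if upstream_bp < 0 or downstream_bp < 0 or min_overlap_bp < 1:
        raise ValueError("window sizes must be >= 0 and min_overlap_bp >= 1")
    seen: set[str] = set()
    for ann in annotations:
        if ann.gene_id in seen:
            raise ValueError(f"duplicate gene annotation {ann.gene_id}")
        seen.add(ann.gene_id)

    trees: dict[str, IntervalTree] = {}
    for site in sites:
        trees.setdefault(site.chrom, IntervalTree()).addi(
            site.start, site.end, site.regulator_id
        )

    edges: set[tuple[str, str]] = set()
    for ann in annotations:
        tree = trees.get(ann.chrom)
        if tree is None:
            continue
        pstart, pend = promoter_interval(ann, upstream_bp, downstream_bp)
        if pstart >= pend:
            continue
        for iv in tree.overlap(pstart, pend):
            overlap = min(iv.end, pend) - max(iv.begin, pstart)
            if overlap >= min_overlap_bp:
                edges.add((iv.data, ann.gene_id))
    return [
        RegulationEdge(reg, TF, gene, source_label)
        for reg, gene in sorted(edges)
    ]


def read_binding_sites(path: str | Path) -> list[BindingSite]:
    """Read a BED-like binding-site file (chrom, start, end, regulator_id)."""
    sites = []
    first = True
    for lineno, fields in _iter_tsv_rows(path):
        if first:
            first = False
            if _looks_like_header(fields):
                continue
        if len(fields) < 4:
            raise ValueError(f"{path}: malformed BED row at line {lineno}")
        chrom, start, end, reg = fields[:4]
        try:
            sites.append(BindingSite(reg.strip(), chrom.strip(), int(start), int(end)))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not sites:
        raise ValueError(f"{path}: no binding sites read")
    return sites


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV (gene_id, chrom, tss, strand)."""
    annotations = []
    first = True
    for lineno, fields in _iter_tsv_rows(path):
        if first:
            first = False
            if _looks_like_header(fields):
                continue
        if len(fields) < 4:
            raise ValueError(f"{path}: malformed annotation row at line {lineno}")
        gene, chrom, tss, strand = fields[:4]
        try:
            annotations.append(
                GeneAnnotation(gene.strip(), chrom.strip(), int(tss), strand.strip())
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not annotations:
        raise ValueError(f"{path}: no gene annotations read")
    return annotations


def network_from_edges(edges: Iterable[RegulationEdge]) -> RegulatoryNetwork:
    """Build a RegulatoryNetwork from explicit edges (deduplicating)."""
    targets_of: dict[str, set[str]] = {}
    classes: dict[str, str] = {}
    sources: dict[tuple[str, str], set[str]] = {}
    for e in edges:
        if classes.setdefault(e.regulator_id, e.regulator_class) != e.regulator_class:
            raise ValueError(
                f"regulator {e.regulator_id} declared with conflicting classes"
            )
        targets_of.setdefault(e.regulator_id, set()).add(e.target_id)
        if e.source:
            sources.setdefault((e.regulator_id, e.target_id), set()).add(e.source)
    if not targets_of:
        raise ValueError("no edges provided")
    return RegulatoryNetwork(targets_of, classes, sources)


def merge_regulatory_networks(
    networks: Sequence[RegulatoryNetwork],
) -> RegulatoryNetwork:
    """Union of several regulatory networks.

    Edge sets are unioned and deduplicated; per-edge provenance labels are
    merged.  A regulator appearing in several networks must carry the same
    class everywhere.
    """
    if not networks:
        raise ValueError("need at least one network to merge")
    targets_of: dict[str, set[str]] = {}
    classes: dict[str, str] = {}
    sources: dict[tuple[str, str], set[str]] = {}
    for net in networks:
        for reg, ts in net.targets_of.items():
            cls = net.classes[reg]
            if classes.setdefault(reg, cls) != cls:
                raise ValueError(
                    f"regulator {reg} declared as {classes[reg]} and {cls}"
                )
            targets_of.setdefault(reg, set()).update(ts)
        for key, labels in net.sources.items():
            sources.setdefault(key, set()).update(labels)
    return RegulatoryNetwork(targets_of, classes, sources)


def read_ppis(path: str | Path) -> nx.Graph:
    """Read an undirected PPI edge list (two tab-separated id columns).

    (a, b) and (b, a) collapse to one edge; self-loops are dropped (their
    count is logged).
    """
    pin = nx.Graph()
    n_self = 0
    first = True
    for lineno, fields in _iter_tsv_rows(path):
        if first:
            first = False
            if _looks_like_header(fields):
                continue
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(f"{path}: malformed row at line {lineno}: {fields!r}")
        a, b = fields[0].strip(), fields[1].strip()
        if a == b:
            n_self += 1
            continue
        pin.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-loops from %s", n_self, path)
    if pin.number_of_edges() == 0:
        raise ValueError(f"{path}: no interactions left after cleaning")
    return pin


def union_pins(pins: Sequence[nx.Graph]) -> nx.Graph:
    """Union several PINs into one simple undirected graph."""
    if not pins:
        raise ValueError("need at least one PIN")
    out = nx.Graph()
    for pin in pins:
        out.add_nodes_from(pin.nodes)
        out.add_edges_from(pin.edges)
    return out


def restrict_to_universe(
    grn: RegulatoryNetwork, pin: nx.Graph
) -> tuple[RegulatoryNetwork, nx.Graph, frozenset[str]]:
    """Restrict both networks to their common gene universe.

    The universe is the intersection of GRN target genes with PIN nodes; the
    PIN is induced on it and each regulator's target set intersected with it.
    Regulators left without targets are dropped.  Idempotent.
    """
    universe = frozenset(grn.targets & set(pin.nodes))
    if not universe:
        raise ValueError("GRN targets and PIN nodes share no genes")
    targets_of = {}
    sources = {}
    dropped = []
    for reg, ts in grn.targets_of.items():
        kept = ts & universe
        if kept:
            targets_of[reg] = kept
            for t in kept:
                if (reg, t) in grn.sources:
                    sources[(reg, t)] = grn.sources[(reg, t)]
        else:
            dropped.append(reg)
    if dropped:
        logger.info("dropped %d regulators with no targets in universe", len(dropped))
    classes = {r: grn.classes[r] for r in targets_of}
    grn2 = RegulatoryNetwork(targets_of, classes, sources)
    pin2 = nx.Graph(pin.subgraph(universe))
    logger.info(
        "universe: %d genes, %d PIN edges, %d regulators",
        len(universe), pin2.number_of_edges(), len(targets_of),
    )
    return grn2, pin2, universe


def write_grn(grn: RegulatoryNetwork, path: str | Path) -> None:
    """Write a GRN as a 4-column TSV (read back by load_grn)."""
    grn.to_frame().to_csv(path, sep="\t", index=False)


def load_grn(path: str | Path) -> RegulatoryNetwork:
    """Read a GRN written by write_grn."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    edges = [
        RegulationEdge(r.regulator_id, r.regulator_class, r.target_id, r.source)
        for r in df.itertuples()
    ]
    return network_from_edges(edges)


def write_pin(pin: nx.Graph, path: str | Path) -> None:
    """Write a PIN edge list as a 2-column TSV (read back by read_ppis)."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in pin.edges):
            fh.write(f"{a}\t{b}\n")


def regulator_statistics(
    grn: RegulatoryNetwork, synergy_threshold: int = 2
) -> pd.DataFrame:
    """Per-regulator target counts and synergistic-partner counts by class.

    Two regulators are synergistic partners when they share at least
    ``synergy_threshold`` targets.
    """
    regs = grn.regulators
    rows = []
    for reg in regs:
        ts = grn.targets_of[reg]
        n_tf = n_mirna = 0
        for other in regs:
            if other == reg:
                continue
            if len(ts & grn.targets_of[other]) >= synergy_threshold:
                if grn.classes[other] == TF:
                    n_tf += 1
                else:
                    n_mirna += 1
        rows.append((reg, grn.classes[reg], len(ts), n_tf, n_mirna))
    return pd.DataFrame(
        rows,
        columns=[
            "regulator_id", "regulator_class", "n_targets",
            "n_tf_partners", "n_mirna_partners",
        ],
    )
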
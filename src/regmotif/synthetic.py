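"""Synthetic coupled GRN/PIN/annotation fixtures with optional planted signal.

The generator emulates the statistical structure the analysis assumes:

* heavy-tailed regulator target-set sizes (most regulators have few targets,
  a small fraction many) via a shifted zipf law;
* widespread synergy — designated regulator pairs copy a fraction of one
  partner's targets into the other so that pairs share at least the synergy
  threshold of common targets;
* a sparse background PIN (Erdős–Rényi by default, preferential attachment
  optionally);
* an optional *planted* excess of PPIs between the private target sets of
  selected synergistic pairs, the ground truth against which crosstalk
  enrichment recovery is measured;
* random annotation terms, optionally one concentrated on a chosen motif's
  inter-connected genes.

Everything is deterministic under a fixed (config, seed): the same
configuration always produces byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from collections.abc import Sequence

import networkx as nx
import numpy as np

from .assembly import MIRNA, TF, RegulatoryNetwork, restrict_to_universe
from .enrichment import background_probability
from .functions import AnnotationMap, write_gmt
from .motifs import _pair_partition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study system.

    Defaults describe the package's standard desk-scale fixture: 500 genes,
    20 TFs and 20 miRNA families, an ER PIN of density 0.02, shifted-zipf
    target-set sizes (minimum 3, cap n_genes/4), and designated synergy for
    40% of regulator pairs with half of the smaller partner's targets copied.
    """

    n_genes: int = 500
    n_tfs: int = 20
    n_mirnas: int = 20
    pin_model: str = "ER"  # or "preferential_attachment"
    pin_density: float = 0.02
    pa_edges: int = 3  # edges per new node for preferential attachment
    target_law: str = "powerlaw"  # or "fixed"
    target_alpha: float = 2.0
    target_fixed_k: int = 5
    target_min: int = 5
    synergy_boost: float = 0.4
    copy_fraction: float = 0.5
    synergy_threshold: int = 2
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    planted_min_targets: int = 30
    n_terms: int = 30
    genes_per_term: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tfs + self.n_mirnas, self.n_terms) < 1:
            raise ValueError("counts must be >= 1")
        if self.pin_model == "ER" and not 0.0 < self.pin_density < 1.0:
            raise ValueError("pin_density must be in (0, 1)")
        if self.genes_per_term > self.n_genes:
            raise ValueError("genes_per_term exceeds n_genes")
        for _, _, mult in self.planted_pairs:
            if mult < 1.0:
                raise ValueError("planted multipliers must be >= 1")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i:02d}" for i in range(self.n_tfs)]

    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR{i:02d}" for i in range(self.n_mirnas)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_pairs"] = [list(p) for p in self.planted_pairs]
        return d


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng([config.seed, stream])


def generate_pin(config: SyntheticConfig) -> nx.Graph:
    """Background PIN over the gene pool (no planted signal)."""
    genes = config.gene_ids
    seed = int(_rng(config, 11).integers(2**31))
    if config.pin_model == "ER":
        raw = nx.gnp_random_graph(config.n_genes, config.pin_density, seed=seed)
    elif config.pin_model == "preferential_attachment":
        raw = nx.barabasi_albert_graph(config.n_genes, config.pa_edges, seed=seed)
    else:
        raise ValueError(f"unknown pin_model {config.pin_model!r}")
    pin = nx.Graph()
    pin.add_nodes_from(genes)
    pin.add_edges_from((genes[a], genes[b]) for a, b in raw.edges)
    return pin


def _target_sizes(config: SyntheticConfig, regulators: Sequence[str], rng) -> dict[str, int]:
    cap = max(config.target_min + 1, config.n_genes // 4)
    sizes = {}
    planted_regs = {r for a, b, _ in config.planted_pairs for r in (a, b)}
    for reg in regulators:
        if config.target_law == "powerlaw":
            size = config.target_min - 1 + int(rng.zipf(config.target_alpha))
        elif config.target_law == "fixed":
            size = config.target_fixed_k
        else:
            raise ValueError(f"unknown target_law {config.target_law!r}")
        size = int(np.clip(size, 2, cap))
        if reg in planted_regs:
            size = max(size, config.planted_min_targets)
        sizes[reg] = size
    return sizes


def _designated_pairs(config: SyntheticConfig, regulators: Sequence[str], rng):
    """Unordered regulator pairs designated as synergistic.

    Planted regulators are kept out of the general designation web (they are
    designated only with their planted partner) so a planted pair's private
    target genes are not copied into other regulators' target sets — the
    planted PPI excess stays localised to the planted pairs.
    """
    designated = {frozenset((a, b)) for a, b, _ in config.planted_pairs}
    planted_regs = {r for a, b, _ in config.planted_pairs for r in (a, b)}
    regs = sorted(regulators)
    for i, a in enumerate(regs):
        for b in regs[i + 1:]:
            pair = frozenset((a, b))
            if pair in designated:
                continue
            if rng.random() < config.synergy_boost:
                if a in planted_regs or b in planted_regs:
                    continue
                designated.add(pair)
    return designated


def generate_grn(config: SyntheticConfig) -> RegulatoryNetwork:
    """Regulator→target map with heavy-tailed sizes and designated synergy.

    Designated pairs (including planted ones) copy targets from one partner
    to the other: the copied count is a ``copy_fraction`` share of the source
    set but always at least the synergy threshold and always leaving at
    least one private target on the source side, so designated pairs are
    synergistic with non-empty private sets whenever sizes permit.
    """
    return generate_grn_with_designations(config)[0]


def generate_grn_with_designations(
    config: SyntheticConfig,
) -> tuple[RegulatoryNetwork, set[frozenset[str]]]:
    """As generate_grn, also returning the designated synergistic pairs."""
    rng = _rng(config, 22)
    genes = np.array(config.gene_ids)
    regulators = config.tf_ids + config.mirna_ids
    classes = {r: TF for r in config.tf_ids}
    classes.update({r: MIRNA for r in config.mirna_ids})
    sizes = _target_sizes(config, regulators, rng)
    targets: dict[str, set[str]] = {}
    for reg in regulators:
        drawn = rng.choice(len(genes), sizes[reg], replace=False)
        targets[reg] = set(genes[drawn])
    designated = _designated_pairs(config, regulators, rng)
    # Copy from the regulators' ORIGINAL draws so designations do not
    # compound: each designated pair shares >= synergy_threshold targets
    # while target sets keep their heavy-tailed scale.
    original = {r: frozenset(ts) for r, ts in targets.items()}
    for pair in sorted(designated, key=sorted):
        a, b = sorted(pair)
        if rng.random() < 0.5:
            a, b = b, a
        src = sorted(original[a] - targets[b])
        if not src:
            continue
        k = int(round(config.copy_fraction * min(len(original[a]), len(original[b]))))
        k = max(config.synergy_threshold, k)
        k = min(k, len(src), len(original[a]) - 1)
        if k < 1:
            continue
        copied = rng.choice(len(src), k, replace=False)
        targets[b].update(src[i] for i in copied)
    return RegulatoryNetwork(targets, classes), designated


def plant_crosstalk_enrichment(
    grn: RegulatoryNetwork,
    pin: nx.Graph,
    planted_pairs: Sequence[tuple[str, str, float]],
    seed: int,
    synergy_threshold: int = 2,
) -> nx.Graph:
    """Add PPIs between planted pairs' private target sets.

    For each planted pair with multiplier m, edges are added between
    private_a × private_b (restricted to PIN nodes) until the inter-set
    density reaches approximately m times the background probability.  Edges
    are only ever added, never removed, so the background estimate stays
    conservative.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng([seed, 33])
    _, pin_r, universe = restrict_to_universe(grn, pin)
    p = background_probability(pin_r, universe)
    out = pin.copy()
    total_added = 0
    for reg_a, reg_b, mult in planted_pairs:
        shared, priv_a, priv_b = _pair_partition(
            grn.targets_of[reg_a], grn.targets_of[reg_b]
        )
        if len(shared) < synergy_threshold or not priv_a or not priv_b:
            raise ValueError(
                f"planted pair ({reg_a}, {reg_b}) is not synergistic with "
                "non-empty private sets"
            )
        a_nodes = sorted(g for g in priv_a if out.has_node(g))
        b_nodes = sorted(g for g in priv_b if out.has_node(g))
        n_possible = len(a_nodes) * len(b_nodes)
        target_density = mult * p
        if target_density > 1.0:
            raise ValueError(
                f"planted pair ({reg_a}, {reg_b}): requested density "
                f"{target_density:.3f} exceeds 1"
            )
        want = int(round(target_density * n_possible))
        existing = sum(
            1 for a in a_nodes for b in b_nodes if out.has_edge(a, b)
        )
        need = want - existing
        if need <= 0:
            continue
        non_edges = [
            (a, b) for a in a_nodes for b in b_nodes if not out.has_edge(a, b)
        ]
        chosen = rng.choice(len(non_edges), min(need, len(non_edges)), replace=False)
        out.add_edges_from(non_edges[i] for i in sorted(chosen))
        total_added += len(chosen)
    logger.info("planted %d inter-private PPIs", total_added)
    return out


def generate_annotations(
    config: SyntheticConfig,
    grn: RegulatoryNetwork | None = None,
    planted_term_genes: Sequence[str] | None = None,
) -> AnnotationMap:
    """Random annotation terms over the gene pool.

    When ``planted_term_genes`` is given, an extra term ("T_planted")
    concentrated on those genes is included — the recoverable ground truth
    for planted functional-enrichment tests.
    """
    rng = _rng(config, 44)
    genes = np.array(config.gene_ids)
    term_genes: dict[str, frozenset[str]] = {}
    term_labels: dict[str, str] = {}
    for t in range(config.n_terms):
        term = f"T{t:03d}"
        drawn = rng.choice(len(genes), config.genes_per_term, replace=False)
        term_genes[term] = frozenset(genes[drawn])
        term_labels[term] = f"synthetic process {t}"
    if planted_term_genes is not None:
        if not planted_term_genes:
            raise ValueError("planted term must annotate at least one gene")
        term_genes["T_planted"] = frozenset(planted_term_genes)
        term_labels["T_planted"] = "planted process"
    return AnnotationMap(term_genes, term_labels)


def generate_fixture(config: SyntheticConfig):
    """Generate the coupled (grn, pin, annotation) triple, with planting."""
    grn = generate_grn(config)
    pin = generate_pin(config)
    if config.planted_pairs:
        pin = plant_crosstalk_enrichment(
            grn, pin, config.planted_pairs, config.seed, config.synergy_threshold
        )
    annotation = generate_annotations(config, grn)
    return grn, pin, annotation


def default_planted_pairs(
    config: SyntheticConfig, n_pairs: int = 10, multiplier: float = 5.0
) -> tuple[tuple[str, str, float], ...]:
    """TF-miRNA pairs used as planted crosstalk ground truth by convention."""
    n_pairs = min(n_pairs, config.n_tfs, config.n_mirnas)
    return tuple(
        (config.tf_ids[i], config.mirna_ids[i], multiplier) for i in range(n_pairs)
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Materialise a fixture bundle in the TSV/GMT dialects the readers use.

    Writes tf_regulations.tsv, mirna_regulations.tsv, ppi.tsv,
    annotations.gmt, known_interactions.tsv (the designated synergistic
    pairs — usable as the known regulator-interaction list), and a
    manifest.json with the config and per-file digests.  Byte-identical for
    identical (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grn, designated = generate_grn_with_designations(config)
    pin = generate_pin(config)
    if config.planted_pairs:
        pin = plant_crosstalk_enrichment(
            grn, pin, config.planted_pairs, config.seed, config.synergy_threshold
        )
    annotation = generate_annotations(config, grn)

    def write_regs(path: Path, cls: str) -> None:
        with open(path, "w") as fh:
            fh.write("regulator_id\ttarget_id\n")
            for reg in grn.regulators_of_class(cls):
                for tgt in sorted(grn.targets_of[reg]):
                    fh.write(f"{reg}\t{tgt}\n")

    write_regs(outdir / "tf_regulations.tsv", TF)
    write_regs(outdir / "mirna_regulations.tsv", MIRNA)

    with open(outdir / "ppi.tsv", "w") as fh:
        fh.write("id_a\tid_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in pin.edges):
            fh.write(f"{a}\t{b}\n")

    write_gmt(annotation, outdir / "annotations.gmt")

    with open(outdir / "known_interactions.tsv", "w") as fh:
        fh.write("reg_a\treg_b\n")
        for a, b in sorted(tuple(sorted(p)) for p in designated):
            fh.write(f"{a}\t{b}\n")

    files = [
        "tf_regulations.tsv", "mirna_regulations.tsv", "ppi.tsv",
        "annotations.gmt", "known_interactions.tsv",
    ]
    manifest = {
        "config": config.to_dict(),
        "files": {f: _sha256(outdir / f) for f in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
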
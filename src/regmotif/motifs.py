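"""Screening of the four regulatory motif types.

Two regulators are *synergistic* when they share at least ``synergy_threshold``
(default 2) common targets.  Four motif types follow:

* single-regulation — one regulator and its target set; tested gene pairs are
  all pairs within the targets;
* co-regulation — a synergistic pair and its shared targets; tested pairs lie
  within the shared set;
* crosstalk — a synergistic pair and its two private (non-shared) target
  sets; tested pairs cross between the private sets;
* independent — a non-synergistic pair and its private target sets; tested
  pairs cross between them.

Single-regulation is undefined for the mixed TF-miRNA combination (it has a
single regulator, which is either a TF or a miRNA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from collections.abc import Iterable, Sequence

import numpy as np

from .assembly import MIRNA, TF, RegulatoryNetwork

logger = logging.getLogger(__name__)

SINGLE_REGULATION = "single_regulation"
CO_REGULATION = "co_regulation"
CROSSTALK = "crosstalk"
INDEPENDENT = "independent"
MOTIF_TYPES = (SINGLE_REGULATION, CO_REGULATION, CROSSTALK, INDEPENDENT)

TF_TF = "TF-TF"
MIRNA_MIRNA = "miRNA-miRNA"
TF_MIRNA = "TF-miRNA"
CLASS_COMBOS = (TF_TF, MIRNA_MIRNA, TF_MIRNA)

_COMBO_CLASSES = {
    TF_TF: (TF, TF),
    MIRNA_MIRNA: (MIRNA, MIRNA),
    TF_MIRNA: (TF, MIRNA),
}


@dataclass(frozen=True)
class RegulatorPair:
    """An unordered pair of regulators with its target-set partition.

    For the mixed combination reg_a is always the TF; otherwise the pair is
    ordered lexicographically.  shared, private_a and private_b are pairwise
    disjoint by construction.
    """

    reg_a: str
    reg_b: str
    class_combo: str
    shared: frozenset[str]
    private_a: frozenset[str]
    private_b: frozenset[str]
    synergistic: bool

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.class_combo, self.reg_a, self.reg_b)


@dataclass(frozen=True)
class MotifInstance:
    """One screened motif with its regulators and gene-set partition.

    For single-regulation the full target set is held in ``shared`` and the
    private sets are empty.
    """

    motif_type: str
    class_combo: str
    regulators: tuple[str, ...]
    shared: frozenset[str]
    private_a: frozenset[str] = frozenset()
    private_b: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, ...]:
        return (self.motif_type, self.class_combo, *self.regulators)

    @property
    def genes(self) -> frozenset[str]:
        return self.shared | self.private_a | self.private_b


def _pair_partition(ta: frozenset[str], tb: frozenset[str]):
    shared = ta & tb
    return frozenset(shared), frozenset(ta - shared), frozenset(tb - shared)


def find_regulator_pairs(
    grn: RegulatoryNetwork, class_combo: str, synergy_threshold: int = 2
) -> list[RegulatorPair]:
    """All unordered regulator pairs of a class combination, with synergy flag.

    Output is deterministic: pairs are sorted lexicographically (TF first for
    the mixed combination).
    """
    if synergy_threshold < 1:
        raise ValueError("synergy_threshold must be >= 1")
    cls_a, cls_b = _COMBO_CLASSES[class_combo]
    if cls_a == cls_b:
        regs = grn.regulators_of_class(cls_a)
        pair_ids = list(combinations(regs, 2))
    else:
        tfs = grn.regulators_of_class(cls_a)
        mirnas = grn.regulators_of_class(cls_b)
        pair_ids = [(a, b) for a in tfs for b in mirnas]
    out = []
    for a, b in pair_ids:
        shared, priv_a, priv_b = _pair_partition(
            grn.targets_of[a], grn.targets_of[b]
        )
        out.append(
            RegulatorPair(
                a, b, class_combo, shared, priv_a, priv_b,
                synergistic=len(shared) >= synergy_threshold,
            )
        )
    return out


def enumerate_motifs(
    grn: RegulatoryNetwork,
    motif_type: str,
    class_combo: str,
    synergy_threshold: int = 2,
) -> list[MotifInstance]:
    """Enumerate all motif instances of one type and class combination."""
    if motif_type not in MOTIF_TYPES:
        raise ValueError(f"unknown motif type {motif_type!r}")
    if motif_type == SINGLE_REGULATION:
        if class_combo == TF_MIRNA:
            raise ValueError(
                "single_regulation is undefined for the TF-miRNA combination"
            )
        cls = _COMBO_CLASSES[class_combo][0]
        return [
            MotifInstance(
                SINGLE_REGULATION, class_combo, (reg,),
                shared=grn.targets_of[reg],
            )
            for reg in grn.regulators_of_class(cls)
            if len(grn.targets_of[reg]) >= 2
        ]
    pairs = find_regulator_pairs(grn, class_combo, synergy_threshold)
    out = []
    for p in pairs:
        if motif_type == CO_REGULATION:
            if p.synergistic:
                out.append(
                    MotifInstance(
                        CO_REGULATION, class_combo, (p.reg_a, p.reg_b),
                        shared=p.shared,
                    )
                )
        else:
            want_synergy = motif_type == CROSSTALK
            if p.synergistic == want_synergy and p.private_a and p.private_b:
                out.append(
                    MotifInstance(
                        motif_type, class_combo, (p.reg_a, p.reg_b),
                        shared=p.shared,
                        private_a=p.private_a,
                        private_b=p.private_b,
                    )
                )
    return out


def tested_pairs(motif: MotifInstance) -> set[frozenset[str]]:
    """The set of unordered gene pairs whose interactions the motif tests.

    Within-set motifs (single-regulation over targets, co-regulation over
    shared targets) test all pairs within the set; the two cross-set motifs
    test only pairs with one gene in each private set.
    """
    if motif.motif_type in (SINGLE_REGULATION, CO_REGULATION):
        genes = sorted(motif.shared)
        return {frozenset(p) for p in combinations(genes, 2)}
    return {
        frozenset((a, b))
        for a in motif.private_a
        for b in motif.private_b
        if a != b
    }


def n_tested_pairs(motif: MotifInstance) -> int:
    if motif.motif_type in (SINGLE_REGULATION, CO_REGULATION):
        n = len(motif.shared)
        return n * (n - 1) // 2
    return len(motif.private_a) * len(motif.private_b)


def remove_outlier_regulators(
    grn: RegulatoryNetwork,
    method: str = "iqr",
    parameter: float = 1.5,
) -> tuple[RegulatoryNetwork, list[str]]:
    """Drop regulators with extreme target counts, per regulator class.

    ``iqr`` removes regulators whose target count exceeds Q3 + parameter*IQR
    of their class's target-size distribution; ``top_percentile`` removes the
    top ``parameter`` percent.  A single application only (re-applying may
    remove more).
    """
    removed: list[str] = []
    for cls in (TF, MIRNA):
        regs = grn.regulators_of_class(cls)
        if len(regs) < 4:
            continue
        sizes = np.array([len(grn.targets_of[r]) for r in regs], dtype=float)
        if method == "iqr":
            q1, q3 = np.percentile(sizes, [25, 75])
            cutoff = q3 + parameter * (q3 - q1)
        elif method == "top_percentile":
            cutoff = np.percentile(sizes, 100.0 - parameter)
        else:
            raise ValueError(f"unknown outlier method {method!r}")
        removed.extend(r for r, s in zip(regs, sizes) if s > cutoff)
    keep = {r: ts for r, ts in grn.targets_of.items() if r not in set(removed)}
    if not keep:
        raise ValueError("outlier removal would drop every regulator")
    classes = {r: grn.classes[r] for r in keep}
    sources = {k: v for k, v in grn.sources.items() if k[0] in keep}
    if removed:
        logger.info("removed %d outlier regulators: %s", len(removed), sorted(removed))
    return RegulatoryNetwork(keep, classes, sources), sorted(removed)


def split_by_known_interactions(
    pairs: Sequence[RegulatorPair],
    interactions: Iterable[tuple[str, str]],
) -> tuple[list[RegulatorPair], list[RegulatorPair]]:
    """Partition regulator pairs into (with, without) known interactions.

    Matching is order-insensitive: (A, B) in the interaction list matches the
    pair (B, A).
    """
    known = {frozenset(p) for p in interactions}
    with_known = [p for p in pairs if frozenset((p.reg_a, p.reg_b)) in known]
    without = [p for p in pairs if frozenset((p.reg_a, p.reg_b)) not in known]
    return with_known, without
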
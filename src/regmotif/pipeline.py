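"""End-to-end orchestration: assembly → screening → enrichment → properties
→ functional analysis.

Each stage reads its inputs from (and writes its outputs to) a run
directory, so the monolithic ``run`` and the per-stage subcommands compose
to byte-identical results.  A JSON manifest echoes the full configuration,
input digests and package version so any run is reproducible from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assembly import (
    MIRNA,
    TF,
    load_grn,
    merge_regulatory_networks,
    read_ppis,
    read_regulations,
    regulator_statistics,
    restrict_to_universe,
    union_pins,
    write_grn,
    write_pin,
)
from .enrichment import (
    bottomup_scores,
    crosstalk_ppi_decomposition,
    median_z,
    results_to_frame,
    threshold_sweep,
    topdown_scores,
)
from .functions import (
    build_similarity_table,
    compare_zero_vs_nonzero,
    crosstalk_functions,
    enrich_terms,
    functional_similarity,
    rank_processes,
    read_gmt,
)
from .motifs import (
    CLASS_COMBOS,
    CO_REGULATION,
    CROSSTALK,
    MOTIF_TYPES,
    SINGLE_REGULATION,
    TF_MIRNA,
    enumerate_motifs,
    n_tested_pairs,
    remove_outlier_regulators,
)
from .properties import PinPropertyCache, property_z

logger = logging.getLogger(__name__)

STAGES = ("build", "screen", "enrich", "netprops", "functions")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    tf_regulations: str
    mirna_regulations: str
    ppi: list[str]
    annotations: str
    outdir: str
    seed: int
    known_interactions: str | None = None
    synergy_threshold: int = 2
    outlier_method: str = "none"  # none | iqr | top_percentile
    outlier_param: float = 1.5
    alpha: float = 0.05
    top_k: int = 20
    similarity_method: str = "jaccard"
    n_background_samples: int = 1000
    netprops_max_motifs: int = 10
    functions_max_motifs: int = 50
    sweep_thresholds: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6, 8, 10])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in self.input_paths():
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        if self.outlier_method not in ("none", "iqr", "top_percentile"):
            raise ValueError(f"unknown outlier_method {self.outlier_method!r}")
        if self.synergy_threshold < 1:
            raise ValueError("synergy_threshold must be >= 1")

    def input_paths(self) -> list[str]:
        paths = [self.tf_regulations, self.mirna_regulations, self.annotations]
        paths.extend(self.ppi)
        if self.known_interactions:
            paths.append(self.known_interactions)
        return paths

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _all_motifs(grn, synergy_threshold):
    motifs = []
    for combo in CLASS_COMBOS:
        for mtype in MOTIF_TYPES:
            if mtype == SINGLE_REGULATION and combo == TF_MIRNA:
                continue
            motifs.extend(enumerate_motifs(grn, mtype, combo, synergy_threshold))
    return motifs


# ---------------------------------------------------------------- stages --

def stage_build(cfg: RunConfig, outdir: Path) -> None:
    """Read, merge and restrict the regulatory and interaction networks."""
    tf_net = read_regulations(cfg.tf_regulations, TF, "tf_regulations")
    mirna_net = read_regulations(cfg.mirna_regulations, MIRNA, "mirna_regulations")
    grn = merge_regulatory_networks([tf_net, mirna_net])
    pin = union_pins([read_ppis(p) for p in cfg.ppi])
    grn_r, pin_r, universe = restrict_to_universe(grn, pin)
    write_grn(grn_r, outdir / "grn.tsv")
    write_pin(pin_r, outdir / "pin.tsv")
    summary = {
        "n_regulators_input": len(grn.regulators),
        "n_targets_input": len(grn.targets),
        "n_grn_edges_input": grn.n_edges,
        "n_pin_nodes_input": pin.number_of_nodes(),
        "n_pin_edges_input": pin.number_of_edges(),
        "n_universe": len(universe),
        "n_regulators": len(grn_r.regulators),
        "n_grn_edges": grn_r.n_edges,
        "n_pin_edges": pin_r.number_of_edges(),
    }
    with open(outdir / "build_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("build: %s", summary)


def stage_screen(cfg: RunConfig, outdir: Path) -> None:
    """Outlier removal, regulator statistics and motif enumeration."""
    grn = load_grn(outdir / "grn.tsv")
    if cfg.outlier_method != "none":
        grn, removed = remove_outlier_regulators(
            grn, cfg.outlier_method, cfg.outlier_param
        )
    else:
        removed = []
    write_grn(grn, outdir / "grn_screened.tsv")
    (outdir / "removed_regulators.txt").write_text(
        "".join(f"{r}\n" for r in removed)
    )
    _write_tsv(
        regulator_statistics(grn, cfg.synergy_threshold),
        outdir / "regulator_stats.tsv",
    )
    motifs = _all_motifs(grn, cfg.synergy_threshold)
    rows = [
        (
            m.motif_type, m.class_combo, m.regulators[0],
            m.regulators[1] if len(m.regulators) > 1 else "",
            len(m.shared), len(m.private_a), len(m.private_b),
            n_tested_pairs(m),
        )
        for m in sorted(motifs, key=lambda m: m.key)
    ]
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=[
                "motif_type", "class_combo", "reg_a", "reg_b",
                "n_shared", "n_private_a", "n_private_b", "n_tested_pairs",
            ],
        ),
        outdir / "motifs.tsv",
    )
    logger.info("screen: %d motifs (%d regulators removed)", len(rows), len(removed))


def stage_enrich(cfg: RunConfig, outdir: Path) -> None:
    """Top-down and bottom-up PPI enrichment, threshold sweep, decomposition."""
    grn = load_grn(outdir / "grn_screened.tsv")
    pin = read_ppis(outdir / "pin.tsv")
    universe = frozenset(grn.targets & set(pin.nodes))
    motifs = _all_motifs(grn, cfg.synergy_threshold)

    topdown = topdown_scores(motifs, pin, universe)
    _write_tsv(results_to_frame(topdown), outdir / "topdown.tsv")
    medians = [
        (mtype, combo, median_z([
            r for r in topdown
            if r.motif_type == mtype and r.class_combo == combo
        ]))
        for mtype in MOTIF_TYPES
        for combo in CLASS_COMBOS
        if not (mtype == SINGLE_REGULATION and combo == TF_MIRNA)
    ]
    _write_tsv(
        pd.DataFrame(medians, columns=["motif_type", "class_combo", "median_z"]),
        outdir / "topdown_medians.tsv",
    )

    bottomup = bottomup_scores(motifs, pin, universe)
    _write_tsv(results_to_frame(bottomup), outdir / "bottomup.tsv")

    sweeps = []
    for combo in CLASS_COMBOS:
        sweep = threshold_sweep(
            grn, pin, universe, CO_REGULATION, combo, cfg.sweep_thresholds
        )
        sweep.insert(0, "class_combo", combo)
        sweeps.append(sweep)
    _write_tsv(pd.concat(sweeps, ignore_index=True), outdir / "sweep.tsv")

    # decompose the PPIs of the highest-scoring crosstalk motif
    crosstalk = [
        (r, m) for r, m in zip(topdown, motifs)
        if m.motif_type == CROSSTALK and math.isfinite(r.z)
    ]
    decomp: dict = {}
    if crosstalk:
        best_r, best_m = max(crosstalk, key=lambda rm: (rm[0].z, rm[1].key))
        d = crosstalk_ppi_decomposition(best_m, pin)
        decomp = {
            "motif": list(best_m.key),
            "z": best_r.z,
            "n_edges": d.n_edges,
            "counts": {
                "intra_a": d.intra_a, "intra_b": d.intra_b,
                "inter": d.inter, "involving_shared": d.involving_shared,
            },
            "fractions": dict(zip(
                ("intra_a", "intra_b", "inter", "involving_shared"),
                d.fractions,
            )),
        }
    with open(outdir / "decomposition.json", "w") as fh:
        json.dump(decomp, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("enrich: %d top-down scores", len(topdown))


def _top_crosstalk_motifs(cfg: RunConfig, outdir: Path, limit: int):
    grn = load_grn(outdir / "grn_screened.tsv")
    pin = read_ppis(outdir / "pin.tsv")
    universe = frozenset(grn.targets & set(pin.nodes))
    motifs = []
    for combo in CLASS_COMBOS:
        motifs.extend(enumerate_motifs(grn, CROSSTALK, combo, cfg.synergy_threshold))
    scores = topdown_scores(motifs, pin, universe)
    scored = [
        (r, m) for r, m in zip(scores, motifs) if math.isfinite(r.z)
    ]
    scored.sort(key=lambda rm: (-rm[0].z, rm[1].key))
    return grn, pin, universe, scored[:limit], dict(
        (m.key, r.z) for r, m in zip(scores, motifs)
    )


def stage_netprops(cfg: RunConfig, outdir: Path) -> None:
    """Network-property significance for the top-scoring crosstalk motifs."""
    grn, pin, universe, top, _ = _top_crosstalk_motifs(
        cfg, outdir, cfg.netprops_max_motifs
    )
    cache = PinPropertyCache(pin)
    rows = []
    for res, motif in top:
        genes = motif.genes & universe
        if len(genes) < 2:
            continue
        prof = property_z(
            pin, universe, genes,
            n_samples=cfg.n_background_samples,
            seed=cfg.seed,
            cache=cache,
        )
        for name in sorted(prof.values):
            rows.append(
                (
                    "|".join(motif.key), name, prof.values[name],
                    prof.background_mean[name], prof.background_sd[name],
                    prof.z[name], prof.n_samples, cfg.seed,
                )
            )
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=[
                "motif_id", "property", "value", "background_mean",
                "background_sd", "z", "n_samples", "seed",
            ],
        ),
        outdir / "netprops.tsv",
    )
    logger.info("netprops: %d motifs profiled", len(top))


def stage_functions(cfg: RunConfig, outdir: Path) -> None:
    """Functional similarity of crosstalk regulator pairs, the zero/non-zero
    comparison, per-motif crosstalk functions and the process ranking."""
    grn, pin, universe, top, zmap = _top_crosstalk_motifs(
        cfg, outdir, cfg.functions_max_motifs
    )
    annotation = read_gmt(cfg.annotations)

    # regulator-level enrichment over the full target set
    reg_terms = {}
    for reg in grn.regulators:
        try:
            reg_terms[reg] = enrich_terms(
                grn.targets_of[reg], annotation, cfg.alpha
            )
        except ValueError:
            continue

    motifs = [m for _, m in top]
    similarities = {}
    for m in motifs:
        a, b = m.regulators
        if a in reg_terms and b in reg_terms:
            similarities[m.key] = functional_similarity(
                reg_terms[a], reg_terms[b], cfg.similarity_method
            )
    sim_rows = [
        ("|".join(k), v) for k, v in sorted(similarities.items())
    ]
    _write_tsv(
        pd.DataFrame(sim_rows, columns=["motif_id", "similarity"]),
        outdir / "similarity.tsv",
    )

    # averaged property z where netprops were computed
    prop_z: dict[tuple[str, ...], float] = {}
    netprops_path = outdir / "netprops.tsv"
    if netprops_path.exists():
        np_df = pd.read_csv(netprops_path, sep="\t")
        if len(np_df):
            for motif_id, sub in np_df.groupby("motif_id"):
                vals = sub.loc[sub.property != "path_unreachable_pairs", "z"]
                prop_z[tuple(motif_id.split("|"))] = float(vals.mean())

    table = build_similarity_table(motifs, similarities, zmap, prop_z)
    _write_tsv(compare_zero_vs_nonzero(table), outdir / "zero_vs_nonzero.tsv")

    per_motif_terms = {}
    term_rows = []
    for m in motifs:
        terms = crosstalk_functions(m, pin, annotation, cfg.alpha)
        per_motif_terms["|".join(m.key)] = terms.reported
        for t in sorted(terms.reported):
            term_rows.append(("|".join(m.key), t))
    _write_tsv(
        pd.DataFrame(term_rows, columns=["motif_id", "term_id"]),
        outdir / "crosstalk_terms.tsv",
    )
    motifs_with_terms = {k: v for k, v in per_motif_terms.items() if v}
    if motifs_with_terms:
        ranked, coverage = rank_processes(motifs_with_terms, cfg.top_k)
    else:
        ranked = pd.DataFrame(columns=["term_id", "n_motifs", "proportion"])
        coverage = float("nan")
    _write_tsv(ranked, outdir / "ranked_processes.tsv")
    with open(outdir / "functions_summary.json", "w") as fh:
        json.dump(
            {
                "n_motifs_analyzed": len(motifs),
                "n_motifs_with_terms": len(motifs_with_terms),
                "top_k": cfg.top_k,
                "coverage": coverage,
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    logger.info("functions: %d motifs analysed", len(motifs))


_STAGE_FUNCS = {
    "build": stage_build,
    "screen": stage_screen,
    "enrich": stage_enrich,
    "netprops": stage_netprops,
    "functions": stage_functions,
}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the pipeline (or a subset of stages) into cfg.outdir.

    Stage errors abort with a stage-tagged message; partial outputs are
    retained together with an INCOMPLETE marker file.
    """
    cfg.validate()
    stages = list(stages or STAGES)
    for s in stages:
        if s not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {s!r}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress or aborted\n")
    for s in stages:
        try:
            _STAGE_FUNCS[s](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {s!r} failed: {exc}") from exc
    marker.unlink()
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "stages": stages,
        "input_digests": {p: _sha256(p) for p in cfg.input_paths()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_summary(cfg, outdir)
    return outdir


def _write_summary(cfg: RunConfig, outdir: Path) -> None:
    lines = [f"regmotif run (seed {cfg.seed}, threshold {cfg.synergy_threshold})"]
    build_path = outdir / "build_summary.json"
    if build_path.exists():
        b = json.loads(build_path.read_text())
        lines.append(
            f"universe: {b['n_universe']} genes, {b['n_pin_edges']} PPIs, "
            f"{b['n_regulators']} regulators"
        )
    motifs_path = outdir / "motifs.tsv"
    if motifs_path.exists():
        m = pd.read_csv(motifs_path, sep="\t")
        counts = m.groupby(["motif_type", "class_combo"]).size()
        for (mtype, combo), n in counts.items():
            lines.append(f"{mtype:>18} {combo:<12} {n} motifs")
    med_path = outdir / "topdown_medians.tsv"
    if med_path.exists():
        med = pd.read_csv(med_path, sep="\t")
        for r in med.itertuples():
            lines.append(
                f"median z {r.motif_type:>18} {r.class_combo:<12} {r.median_z:.3f}"
            )
    (outdir / "summary.txt").write_text("".join(f"{l}\n" for l in lines))
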
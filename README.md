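# regmotif

Combinatorial gene regulation analysed on the protein interactome: `regmotif`
screens an integrated gene regulatory network (GRN) of transcription factors
(TFs) and miRNA families for four regulatory motif types and asks whether the
genes each motif controls are unusually connected in a protein–protein
interaction network (PIN).

It is aimed at systems biologists studying TF/miRNA cooperation: you supply
regulator→target edge lists (or TF binding sites plus gene annotations for
promoter-based target assignment), one or more PPI edge lists and a GMT
annotation file; the package assembles and restricts the networks, screens
motifs, scores PPI enrichment, profiles PIN topology, and analyses the
functions shared by cooperating regulators. A synthetic generator produces
coupled GRN/PIN/annotation fixtures with a plantable crosstalk signal, so the
entire pipeline is testable without any database access.

## The motifs and the statistic

Two regulators are **synergistic** when they share at least θ (default 2)
common targets. Four motif types are screened per regulator-class
combination (TF–TF, miRNA–miRNA, TF–miRNA):

| motif | regulators | tested gene pairs |
|---|---|---|
| single-regulation | one | all pairs within its targets |
| co-regulation | synergistic pair | pairs within the shared targets |
| crosstalk | synergistic pair | pairs across the two private target sets |
| independent | non-synergistic pair | pairs across the private sets |

(Single-regulation is undefined for the mixed TF–miRNA combination.)

Each tested pair is treated as a Bernoulli trial with success probability
*p*, the PIN density on the analysis universe (GRN targets ∩ PIN nodes).
With *N* tested pairs of which *O* are PIN edges, the enrichment score is

    z = (O − N·p) / sqrt(N·p·(1 − p))

computed in constant time — no resampling. A seeded permutation oracle
(random gene sets of the same shape) is included and is used by the tests to
bound the approximation error of the analytic score. Enrichment is scored
top-down (one z per motif) and bottom-up (one z per motif category over the
deduplicated union of tested pairs, with gene coverage), plus a synergy-
threshold sweep, a per-motif PPI decomposition (intra/inter private-set
fractions), five PIN topology properties (degree, closeness, density, clique
level, characteristic path length) with z-scores against size-matched random
gene sets, and hypergeometric/BH term enrichment with Jaccard functional
similarity between regulators.

## Worked example

Generate a fixture with ten planted crosstalk pairs (inter-private PPI
density five times background) and run the pipeline:

```sh
regmotif fixtures --outdir fx --seed 11 --planted 10 --multiplier 5
regmotif run --config run.yaml          # paths pointing at fx/, seed 11
```

`summary.txt` from that run begins:

```
regmotif run (seed 11, threshold 2)
universe: 390 genes, 1813 PPIs, 40 regulators
     co_regulation TF-TF        101 motifs
     ...
         crosstalk TF-miRNA     219 motifs
median z          crosstalk TF-miRNA     0.111
```

The motif counts say how many instances of each type survived screening at
threshold 2; the medians summarise the per-motif z distributions (near 0
here because all but the planted pairs are background). `topdown.tsv` holds
the per-motif scores — the ten planted pairs stand out (z ≈ 8–26 at
multiplier 5). `decomposition.json` classifies the PPIs among the
highest-scoring crosstalk motif's targets; in this run that is the planted
pair TF09–miR09 (z = 10.9) with 61% of its PPIs forming inter-connections
between the two private target sets — the planted excess, recovered:

```json
"fractions": {"inter": 0.613, "intra_a": 0.120, "intra_b": 0.0,
              "involving_shared": 0.267}
```

Every stage is also available as a subcommand (`build`, `screen`, `enrich`,
`netprops`, `functions`, `fixtures`); stage-wise execution is byte-identical
to the monolithic `run`.

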
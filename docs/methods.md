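# Methods

## Networks and the analysis universe

The gene regulatory network (GRN) is a directed bipartite map from
regulators — transcription factors (TFs) and miRNA families, the latter
treated as opaque single regulator ids — to target genes. Inputs are
regulator→target TSVs; TF targets can alternatively be derived from binding
sites and gene annotations: a gene is a TF target when its promoter window
(default 1000 bp upstream and 500 bp downstream of the TSS, strand-aware,
0-based half-open BED convention) overlaps at least one binding site of that
TF by at least `min_overlap_bp` (default 1) base pairs. Networks from
several sources are unioned with per-edge provenance; a regulator may not
change class between sources. Self-regulation edges are retained but can
never enter a tested gene pair (pairs need two distinct genes). The protein
interaction network (PIN) is an undirected simple graph; (a,b)/(b,a)
duplicates collapse and self-loops are dropped. Gene identifiers are matched
by exact string comparison — namespace reconciliation is the caller's
responsibility.

All enrichment statistics are computed on the **analysis universe**: GRN
target genes ∩ PIN nodes. Genes absent from either network carry no
interaction evidence; counting them as non-edges would mistake missing data
for absence of interaction. `restrict_to_universe` induces the PIN on the
universe, intersects each regulator's targets with it, and drops regulators
left without targets; it is idempotent.

## Motif screening

Two regulators are synergistic when they share ≥ θ targets (θ = 2 by
default, adjustable for threshold sweeps). Motifs and their tested-pair
universes:

* **single-regulation** — one regulator with ≥ 2 targets; all C(n,2) pairs
  within its targets;
* **co-regulation** — a synergistic pair; pairs within the shared targets;
* **crosstalk** — a synergistic pair with both private (non-shared) sets
  non-empty; the cross pairs private_a × private_b only;
* **independent** — a non-synergistic pair with both private sets non-empty;
  cross pairs as above. A non-synergistic pair may share up to θ − 1
  targets; those genes are excluded from both private sets.

Single-regulation is undefined for the TF–miRNA combination (its one
regulator is either a TF or a miRNA). All enumerations are sorted
lexicographically (the TF first in mixed pairs) so outputs are byte-stable.

Outlier regulators — those with extreme target counts, which flood the
crosstalk category until its coverage approaches the whole universe — can be
removed per regulator class before screening. The default rule removes
regulators above Q3 + 1.5·IQR of their class's target-size distribution; a
top-percentile rule is available. This is a one-shot procedure: re-applying
it can remove more, so idempotence is deliberately not promised.

## PPI enrichment

Each tested pair is modelled as an independent Bernoulli trial with success
probability p = (PIN edges within the universe) / C(|universe|, 2). With N
tested pairs (both genes present in the PIN) and O observed edges,

    z = (O − N·p) / √(N·p·(1 − p)).

The variance uses the independent-trials approximation; pairs sharing a gene
are weakly dependent, and the included permutation oracle — n_samples
(default 10⁴) random gene sets of the motif's shape drawn uniformly from the
universe, seeded — is used in the test suite to bound the resulting error
(|analytic − permutation| ≤ 0.3 on ER PINs with n = 200, density 0.05,
15 + 15-gene tested sets, in ≥ 95% of 20 trials). z is reported as missing
(NaN), never silently 0, when N = 0 or p ∈ {0, 1}.

Top-down scoring assigns one z per motif instance; figure-style summaries
report medians of the per-motif z. Bottom-up scoring assigns one z per
(motif type, class combination) category over the deduplicated union of its
instances' tested pairs, with coverage = percentage of universe genes
appearing in that pair universe. The threshold sweep re-screens and
re-scores one motif family at each θ of an ascending list; the motif count
is non-increasing in θ by construction. The crosstalk decomposition
classifies every PIN edge whose endpoints both lie in shared ∪ private_a ∪
private_b as intra_a, intra_b, inter (one endpoint in each private set) or
involving_shared (≥ 1 endpoint shared); the four fractions partition the
qualifying edges, and any edge touching a shared target is assigned to
involving_shared regardless of its other endpoint.

No multiple-testing layer is applied to z-scores; they are reported raw, and
significance thresholds are left to the caller.

## Network properties

Five PIN properties are scored for a gene set: mean degree, mean closeness
centrality (Wasserman–Faust component normalisation, so disconnected PINs
are handled and isolated genes score 0), induced-subgraph density, mean
clique level (size of the largest maximal clique containing each gene,
computed exactly by maximal-clique enumeration with a per-gene enumeration
budget that falls back to the best clique seen, logged, on pathological
inputs), and characteristic path length — the mean shortest-path distance
between set members **in the full PIN**, so proximity through non-member
proteins counts. Unreachable pairs are excluded from the path-length mean
(their count is reported) rather than imputed; the value is missing when no
pair is reachable.

Significance is a z-score per property against n_samples (default 1000)
size-matched gene sets drawn uniformly from the universe. Degree-matched
sampling (log2 degree bins) is available as an option for hub-rich target
sets, but uniform size-matching is the default. Background path lengths
average reachable pairs only, matching the foreground definition; a property
with zero background variance is flagged missing. Per-node values and BFS
distance maps are cached across gene sets, so profiling many motifs against
one PIN costs one closeness pass plus lazy clique/BFS fills.

## Functional analysis

Term enrichment is a one-sided hypergeometric test over the annotation
universe (the union of all term gene sets, read from GMT), with
Benjamini–Hochberg correction across the tested terms; terms with adjusted
p ≤ α (default 0.05) and overlap ≥ 1 are reported. Functional similarity
between two regulators is the Jaccard index of the enriched term-id sets of
their full target sets (an overlap-coefficient variant is available); zero
similarity means no common enriched function. Crosstalk-function analysis
enriches the genes participating in a motif's inter-private PPIs — the
endpoints of tested pairs that are PIN edges. Process ranking orders terms
by the proportion of motifs whose enriched set contains them, takes the top
k (ties broken lexicographically) and reports the fraction of motifs covered
by at least one top-k term. The zero-vs-nonzero comparison contrasts PPI and
averaged property z between motifs with zero and positive similarity, per
class combination, with a two-sided Mann–Whitney test; groups with fewer
than two members are flagged.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any particular organism's networks:

* **PIN** — Erdős–Rényi at density 0.02 by default (preferential attachment
  optional). Real interactomes are heavier-tailed and modular; the ER choice
  makes the null calibration exact, which is what the fixture is for.
* **Target sizes** — shifted zipf: `target_min − 1 + Zipf(α)` with α = 2,
  floor 5 and cap n_genes/4, giving the observed pattern of many small
  regulators and a few large ones. The floor keeps private sets non-empty
  after sharing, so the crosstalk category is well populated.
* **Synergy** — 40% of regulator pairs are designated synergistic; each
  copies half of the smaller partner's *original* target draw (at least θ
  genes, always leaving ≥ 1 private target on the source side) into the
  other. Copying from the original draws rather than the accumulated sets
  prevents designations from compounding into near-identical target sets.
* **Planted signal** — for each planted pair with multiplier m, edges are
  added between its private sets until the inter-set density reaches
  ≈ m·p. Edges are only added, never removed, so the planted excess
  slightly inflates the background estimate and makes recovery tests
  conservative. Planted regulators are kept out of the general designation
  web so the signal stays localised to the planted pairs, and are given at
  least 30 targets so their tested universes are informative.
* **Annotations** — 30 random terms of 25 genes, optionally one term
  concentrated on chosen genes as recoverable ground truth.

Defaults (500 genes, 20 TFs, 20 miRNA families) run the full pipeline in
seconds and yield several hundred motifs of every type. Everything is
deterministic under a fixed (config, seed); fixture bundles are
byte-reproducible, with a manifest of config and file digests.

Because the fixtures are ER-based and identifier-clean, passing tests
demonstrate the statistics and the screening semantics, not robustness to
the degree heterogeneity, ascertainment bias and identifier noise of real
interactome and target-prediction data.

## Numerical and design choices

* Background p uses the universe-induced PIN density — the standard
  Bernoulli reading, validated end-to-end against the permutation oracle
  rather than derived from combinatorics over dependent pairs.
* Tested pairs with a gene absent from the PIN are dropped from N.
* Enumeration order, TSV float formatting (%.6g) and sorted serialisation
  make all pipeline outputs byte-stable; the run manifest echoes the full
  configuration, input digests and package version.
* The pipeline profiles network properties for the top-scoring crosstalk
  motifs (default 10) and analyses functions for the top 50, at 1000
  background samples by default; the test and acceptance runs use smaller
  settings (documented in their configs) since the statistics they check
  concentrate well below those sizes.
* The acceptance script pools three unplanted fixtures (≈ 1800 crosstalk
  motifs) for its null-calibration estimate: per-motif z-scores within one
  fixture share the background estimate and many PIN edges, so replicate
  fixtures tighten the estimate where more motifs from one fixture would
  not.

## Known limitations

* The Bernoulli variance ignores pair dependence through shared genes; the
  oracle bounds show the error is small for desk-scale sets but it grows
  with set overlap.
* Closeness and path length are recomputed per PIN; very large interactomes
  (10⁵+ edges) would need the property cache swapped for sampled BFS.
* Functional similarity reflects the annotation's granularity: coarse GMTs
  compress similarity toward {0, 1}.
* No GO DAG propagation or semantic similarity — terms are flat gene sets.
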
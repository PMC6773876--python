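# Methods

pinora implements active-subnetwork-oriented pathway enrichment for
class-comparison omics experiments: instead of testing a flat list of
differentially expressed genes (DEGs) against pathways, it first finds
connected subnetworks of a protein–protein interaction network (PIN)
that concentrate statistical significance, and then tests *those* for
pathway over-representation. This document records the model, the
numerical choices and the limitations; the README shows usage.

## Model and procedure

**Inputs.** An undirected PIN over gene symbols (SIF); a gene-set
collection (GMT); a DEG table of gene symbols, optional log-fold
changes, and adjusted p values; optionally an expression matrix
(genes × samples) and an alias→canonical symbol map.

**Input processing.** Rows with adjusted p ≤ the significance threshold
(default 0.05, boundary inclusive) are kept. Symbols absent from the
PIN are renamed through the alias map when the canonical symbol is a
PIN node, otherwise dropped and logged with a reason code. Duplicate
symbols — from multiple probes or alias collisions — resolve to the
record with the lowest p.

**Subnetwork scoring.** Each significant gene's p value maps to
z_i = Φ⁻¹(1 − p_i). A subnetwork A of k genes scores

    z_A = k^(−1/2) · Σ_{i∈A} z_i,

the jActiveModules-style aggregate; genes that are not significant
inputs (connector nodes) contribute z = 0 and therefore dilute the
score. Raw scores are calibrated against a Monte-Carlo background: for
each size k, 2,000 uniformly random k-subsets of PIN nodes are scored,
and s_A = (z_A − μ_k)/σ_k.

**Search.** Three algorithms maximize s_A:

* *Greedy* (default): every significant gene seeds an expansion; at
  each step the candidate within graph distance d (default 1) of the
  current members and within the maximum depth (default 1) of the seed
  that most increases s_A is added, only while the increase is strict.
  Candidate ties break alphabetically. Subnetworks overlapping a
  higher-scoring one by more than 0.5 (overlap = |A∩B|/min(|A|,|B|),
  boundary kept) are discarded.
* *Simulated annealing*: a random on/off assignment over all PIN nodes
  (on-probability 0.1) is perturbed one node per iteration; a worse
  solution is accepted with probability exp(Δ/T) under geometric
  cooling (T₀ = 1.0, factor 0.995, 10,000 iterations by default). The
  solution's scalar fitness is the maximum calibrated score over its
  connected components; all components of the best solution are
  returned.
* *Genetic algorithm*: a population (default 400) of on/off bit
  strings evolves for a default 200 generations by linear rank
  selection and uniform crossover; mutation is off by default. The
  previous best individual is restored whenever a generation's best is
  worse (elitism), and every 10th generation the worst 10% are replaced
  by fresh random individuals.

**Enrichment.** Per iteration, subnetworks are kept when their
calibrated score strictly exceeds the empirical 0.80 score quantile
(linear-interpolation convention; a lone subnetwork is kept, since the
criterion is vacuous) and they contain ≥ 10 significant genes. Each
kept subnetwork is tested against every gene set with a one-sided
hypergeometric test whose background pool is the PIN node set; fold
enrichment is (x/n)/(K/N). P values are Bonferroni-adjusted (BH
optional) within each subnetwork's family of tests, records above the
enrichment threshold (default 0.05, boundary kept) are dropped, and
pathways are aggregated by lowest adjusted p. The cycle repeats for 10
iterations (1 for the genetic algorithm), each with its own RNG
substream derived from the master seed; the final table reports per
pathway the lowest/highest adjusted p, the occurrence count
(iterations, not subnetworks), the fold enrichment of the lowest-p
record, and the significant input genes in the pathway split by change
sign. When change values are absent the schema is unchanged and all
involved genes appear in the Up_regulated column.

**Clustering.** Pathways become binary membership vectors over the
significant input genes; pairs are compared by Cohen's kappa. The
default mode is agglomerative clustering (average linkage) on distance
1 − kappa with the cluster count chosen by maximum average silhouette
width over all cuts k ∈ 2..n−1 (ties to the smallest k; two pathways
fall back to one cluster, where the silhouette is undefined). The
fuzzy mode follows the DAVID-style heuristic: pathways with ≥ 3 close
neighbors (kappa ≥ 0.35) seed groups, groups sharing > 50% of the
smaller group's members merge until stable, and a pathway may belong
to several final groups. Each cluster's representative is its
lowest-p pathway (ties: higher fold enrichment, then id). Degenerate
pairs with chance agreement P_e = 1 get kappa 1 if the vectors are
identical, else 0, keeping the matrix total.

**Per-sample pathway scores.** Gene scores standardize each expression
row, GS(g,s) = (EM(g,s) − mean_g)/sd_g with the sample (n−1) standard
deviation; zero-variance rows score 0 rather than being dropped so the
pathway gene count k is stable. A pathway's score in a sample is the
mean GS over its genes present in the matrix. Because each GS row has
zero mean across samples, so does each pathway row, and case/control
contrasts read directly off the sign.

## Numerical choices

* **p clamping**: p is clamped to [1e-15, 1 − 1e-15] before the normal
  inverse so z is always finite.
* **Common random numbers in calibration.** The 2,000 background draws
  are realized as 2,000 random node permutations shared across sizes:
  the size-k subset of draw d is the first k elements of permutation
  d, an exact uniform k-subset. With independent per-size streams, the
  Monte-Carlo error of σ_k (inflated by the heavy-tailed z
  distribution: most nodes score 0, a few score ≈ 4) exceeds the score
  increment of adding one gene, so greedy expansion can stop early for
  no structural reason; the shared permutations make μ_k and σ_k
  smooth in k while leaving each size's marginal background exactly as
  specified. The table is built lazily per size and cached per run.
* **Degenerate σ_k = 0** (e.g. k = |PIN|, where every draw is the full
  node set): the calibrated score is 0 when z_A = μ_k and otherwise a
  ±1e9 sentinel, keeping score comparisons total. Draws whose scores
  are all identical are snapped to σ = 0 exactly (naive summation
  leaves ~1e-16 artifacts).
* **Background subsets** are uniform node subsets without a
  connectivity requirement; a connectivity-constrained sampler (random
  neighbor growth) is available via `CalibrationTable(connected=True)`.
* **Determinism**: all randomness flows from numpy Generators seeded
  from explicit integers; per-iteration substreams come from
  `SeedSequence([master, iteration])`, so any single iteration can be
  reproduced independently. Greedy is deterministic given the
  calibration table; candidate and representative ties break
  lexicographically.

## Synthetic data

The generator builds the structure the method is designed to detect: a
300-node background graph (mean degree 4) with a 15-gene planted
module that is fully interconnected — a planted clique on a random
background. Module genes draw p from U(1e-6, 1e-3) with positive
changes; background genes draw p from U(0, 1) with signed changes. The
clique topology is deliberate: the default depth-1 greedy search
expands a star around each seed, so recoverable modules must be
locally dense, exactly the regime the depth-1 "local subnetwork"
approach targets. Gene sets are 50 decoys of 10–40 random genes plus
one 25-gene target set containing the module; the expression matrix is
unit-variance Gaussian with the module genes shifted by δ = 1 in 10
cases versus 10 controls. `permute_gene_labels` reassigns a table's
symbols to a random draw from a gene universe, the negative control
that preserves the p-value distribution while destroying its network
correspondence.

What the fixture does *not* emulate: scale-free degree structure,
correlated noise and probe-level artifacts of real arrays, overlapping
true modules, and pathway collections with heavy mutual overlap.
Passing tests therefore demonstrate algorithmic correctness and
recoverability under clean planted structure, not performance on real
PINs, where score calibration and overlap filtering face much larger
k and heavier pathway redundancy.

## Problem sizes used in tests

The shipped tests and the acceptance script run the default 300-node
fixture; the annealing runs there use 1,500–2,000 iterations and the
genetic runs populations of 30–50 for up to 200 generations, sizes at
which the planted module is comfortably recovered in seconds. The
package defaults (10,000 annealing iterations, population 400) are
sized for real PINs of 10⁴ nodes.

## Known limitations

* "Each possible size" for calibration is unbounded on large PINs; the
  table is lazy and only materializes sizes the search actually
  queries. The permutation matrix costs draws × |PIN| int32, ~80 MB
  for a 10⁴-node PIN.
* The per-subnetwork adjustment family (m = number of gene sets) is a
  stated convention; a global family across subnetworks would be more
  conservative and can be obtained by adjusting the aggregated raw
  table externally.
* The fuzzy heuristic's parameters (kappa 0.35, neighborhood 3, merge
  50%) are conventions of the cited heuristic, configurable but not
  validated here.
* Enrichment requires the in-process calibration table, so the CLI has
  no standalone `enrich` subcommand on intermediate files; use
  `pinora run`, which writes every intermediate table.
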
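# Methods

## The two-state co-expression analysis

The pipeline compares how genes co-express under two experimental
conditions — normally grown and salt-stressed rice — and prioritizes
genes whose connectivity changes between the two states.  The analysis
proceeds in five stages, each a library module:

1. **Expression screen** (`ricenet.expression`).  Counts are filtered
   (genes with zero counts in every sample are non-informative and
   removed), normalized by median-of-ratios size factors, and tested per
   developmental stage (seedling, booting) for stress-vs-normal
   differential expression.  The DE engine is a Welch two-sample t-test
   on `log2(normalized + 1)` with Benjamini–Hochberg adjustment within
   each stage's family and a significance cutoff of adjusted p < 0.01.
   This is a deliberate stand-in for a count-based negative-binomial
   test: downstream stages consume only the resulting gene lists and
   fold-change signs, and `read_de_table` imports externally computed DE
   tables when fidelity to a dedicated engine matters.
2. **Network construction** (`ricenet.network_build`).  The node
   universe is the union of the two stages' significant genes.  For each
   condition, all of that condition's samples (both stages pooled) give
   a complete signed graph of pairwise Pearson correlations; the binary
   view keeps pairs with |r| ≥ τ (default 0.9, inclusive); nodes with no
   binary edge are dropped.  Correlations are computed on
   `log2(normalized + 1)`: the same scale as the DE test, and the scale
   on which the generator's latent structure is linear.  A gene with
   zero variance across the chosen samples has undefined correlations;
   they are set to 0 with a warning.
3. **Network properties** (`ricenet.network_metrics`).  Per node: binary
   degree k_i; weighted degree (sum of signed weights over binary
   neighbours); the Watts–Strogatz clustering coefficient
   C(i) = Σ_j Σ_{q≠j} a_ij a_iq a_jq / (k_i(k_i−1)); and the Onnela
   signed weighted clustering coefficient, which replaces each closed
   triple by the geometric mean of its three absolute edge weights,
   C_w(i) = Σ_j Σ_{q≠j} |w_ij w_iq w_jq|^{1/3} / (k_i(k_i−1)).
   Both are evaluated on the thresholded edge set with the binary
   degree in the denominator, so with |w| ≤ 1 the weighted value is
   bounded by the binary value node-wise — the property that makes the
   two distributions directly comparable.  Network level: edge/node
   counts, connections per node (E/N) and average degree (2E/N), hub
   count (degree > 200 by default), end-node count (degree = 1), degree
   assortativity (Pearson correlation over ordered endpoint-degree
   pairs, both orientations per edge), and the diameter of the largest
   connected component.
4. **Candidate selection** (`ricenet.candidate_selection`).  A candidate
   "switch" gene has degree strictly below a low threshold in the
   normal-state network and strictly above a high threshold in the
   stress-state network.  Reference thresholds are 50 and 700 on
   networks of ~1446 connected nodes; `scale_thresholds` carries the
   same fractions (50/1446, 700/1446) to any network size.  Genes
   dropped from one network as isolates count as degree 0 there —
   being partnerless is the normal-state half of the phenotype.
5. **Enrichment** (`ricenet.go_enrichment`).  One-sided Fisher's exact
   test (upper hypergeometric tail) per annotation term against a fixed
   universe, sample odds ratio ad/bc, BH adjustment across all tested
   terms capped at 1.

## The synthetic-data generator

`ricenet.synthetic_data` emulates a two-condition × two-stage
replicated RNA-seq experiment with the structure the analysis keys on
planted explicitly.  Latent model per condition c and sample s: one
standard-normal factor f per module; a gene g in module m has
z = sign_g·√ρ_c·f_{m,s} + √(1−ρ_c)·ε; unassigned genes are pure noise.
Counts are negative binomial with mean
μ = libsize_s · exp(m₀ + β_g·1[c = stress] + z) and variance
μ + αμ², with β_g = ±log2fc·ln 2 in the gene's DE stage and per-sample
library sizes log-uniform on [0.5, 2].

Defaults (the package's standard regime) and why:

| parameter | default | rationale |
|---|---|---|
| n_genes | 600 | desk-scale version of a genome-wide screen |
| module_sizes | (60,) | one coherent salt-response program |
| n_switch | 20 | module members silenced (loading zeroed) under normal |
| rho_stress | 0.95 | tight stress co-expression; most pairs clear \|r\| ≥ 0.9 at n = 20 |
| rho_normal | 0.90 | co-expression present but weaker under normal, so the normal network is sparser yet non-empty |
| frac_negative | 0.2 | planted negative correlations (signed edges) |
| frac_de | 0.25 | 150 DE genes; the network universe stays desk-scale |
| log2fc_range | (2, 5) | at least two-fold shifts; module members draw from the upper half (3.5–5) as the strongly responding program |
| nb_dispersion | 0.01 | residual overdispersion typical of well-expressed genes; keeps count-noise attenuation of the latent correlation near 1% so the hard 0.9 threshold stays meaningful |
| mean_log_expression | 8.0 | mean counts ≈ 3000: expressed genes, small Poisson noise |
| replicates_per_cell | 10 | 20 samples per condition, enough for stable correlation at the 0.9 threshold |

Module members are all DE (up, both stages): a coherent stress-induced
program whose correlations are not broken by stage-specific mean
shifts.  Switch genes are module members whose loading is zeroed under
the normal condition; they are thereby near-isolated in the normal-state
network and hubs in the stress-state network, and being module members
they are DE by construction, so the candidate filter's intersection
with DE genes is non-empty.

What the generator does *not* emulate: read-level artifacts (GC bias,
mapping ambiguity, gene length), dispersion varying with expression
level, more than one latent factor per module, batch structure, or a
realistic fold-change distribution.  Passing tests therefore show that
the pipeline recovers the planted two-state structure under idealized
noise, not that a specific biological dataset would yield specific
counts.

## Numerical and degenerate-input conventions

- Nodes with k < 2 get clustering 0 (not undefined), keeping the
  clustering distribution total over all network nodes.
- Degree assortativity is NaN (with a warning) when endpoint degrees
  have zero variance (regular graphs).
- The diameter of a disconnected graph is reported for the largest
  component with an explicit `connected=False` flag (the mathematical
  value would be infinite); both hop count and traversed-node count
  (hops + 1) are emitted since reports differ in convention.
- Global clustering defaults to the mean binary local clustering over
  nodes with k ≥ 2; the triangle-to-triple ratio (transitivity) is
  available as a config option.  Which convention a given published
  table used is generally not recoverable; both are exposed.
- Welch test with zero variance in both groups: p = 1 for equal means,
  0 otherwise.
- Sample odds ratio: NaN whenever b·c = 0 (no finite estimate, e.g.
  term = universe), 0 for a list disjoint from the term; a
  conditional-MLE estimator is available as an option.
- The threshold comparison |r| ≥ τ is inclusive; the candidate filters
  (< low, > high) are strict.
- `scale_thresholds` clamps the low threshold to ≥ 1, since a value of
  0 can select no gene (degrees are non-negative and the comparison is
  strict).
- All randomness flows from one `numpy` generator seeded by the config;
  identical configs produce bit-identical datasets, and pipeline
  outputs are written with fixed float formatting so repeat runs are
  byte-identical.

## Problem sizes

The test suite and the acceptance script run entirely on generated
data: the standard regime is 600 genes × 40 samples, metric oracles use
200 random graphs of up to 30 nodes, and the Fisher sweep enumerates
every 2×2 table with universe ≤ 60.  These sizes make every check a
from-scratch computation while keeping the whole suite in the
seconds-to-minutes range.

## Known limitations

- Hard-thresholding correlations at |r| ≥ 0.9 with ~20 samples per
  condition is intrinsically unstable: all module pairs share one
  factor realization per condition, so the realized factor variance
  shifts every correlation coherently, and planted values near the
  threshold make network density vary substantially between
  realizations.  (Small replicate numbers affecting correlation-network
  structure is a recognized caveat of this design in general.)  The
  stochastic recovery checks are therefore specified at a fixed seed; a
  soft threshold or larger n would trade fidelity to the two-state
  design for stability.
- The Welch stand-in has less power than a count-based NB test at few
  replicates; at 3 replicates per cell only strong (≫2-fold) shifts
  are detectable at adjusted p < 0.01.
- Fractional threshold scaling assumes hub-ness scales linearly with
  network size, which is a heuristic, not a calibrated result.
- Enrichment treats annotation terms as flat sets (no ontology-graph
  propagation).
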
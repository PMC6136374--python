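# Methods

## Problem and model

Two disjoint gene sets are called from expression contrasts on the same
organism: A, drought-responsive genes that also respond to exogenous ABA
(ABA-dependent), and B, drought-responsive genes that do not
(ABA-independent). The question is whether A and B interact physically —
through edges of a protein–protein interaction (PPI) network — more often
than expected for gene sets of the same size and connectivity.

"Expected" is defined by a degree-preserving null model: an ensemble of
R randomized networks obtained from the observed network by double-edge
swaps, so that every protein keeps its exact number of interactions while
the wiring is otherwise randomized. All enrichment statistics are
functionals of the observed network and this ensemble:

* **Per-gene empirical p.** For gene *i* in A, the statistic is the number
  of distinct neighbors of *i* in B (and symmetrically for B vs A). The
  empirical p-value is the proportion of ensemble replicates whose null
  count is **greater than or equal to** the observed count (ties in the
  numerator). Genes with p < α (default 0.05) form the *core interacting
  components*. The minimum resolvable p is 1/R and is reported with every
  record; a (r+1)/(R+1) pseudocount variant is available but is not the
  default.
* **Global Z.** Z = (N_obs − μ_null) / SD_null, where N_obs is the number
  of distinct A–B edges and μ_null, SD_null are the ensemble mean and
  sample standard deviation (denominator R − 1). SD_null = 0 yields a
  flagged NaN, never a division error.
* **DEG vs non-DEG comparison.** A Welch t-test between Z-scores derived
  from the DEG pair (A, B) and Z-scores of size-matched gene-set pairs
  drawn from the non-DEG pool (see *Design choices*).
* **Co-expression enrichment.** Pearson correlations on log-transformed
  abundances; the link threshold is the (1 − q) quantile (q default 0.01)
  of the pooled pair-correlation distribution over A ∪ B ∪ the sampled
  non-DEG sets; fold enrichment is the observed number of A–B links over
  the mean among size-matched non-DEG set pairs.

Counts are unweighted throughout: a PPI edge either exists or it does not.
Edge confidence weights are carried to exports (SIF line width semantics,
GraphML attributes) and can filter the input (`--min-edge-weight`), but
never enter a statistic.

## DEG classification rules

A gene is a DEG in a contrast when |log2FC| ≥ log2(min_fold_change) and
p < max_p (defaults: fold change 2, p 0.05). Boundary reading: "at least
two-fold" is inclusive (|log2FC| = 1 qualifies); the p threshold is
strict (p = 0.05 does not). Drought-responsive means DEG at drought day
10 **or** day 12. "Recovered by rewatering" is operationalized as failing
the DEG criteria in the rewatered contrast; the recovery filter applies
to both ABA-dependent and ABA-independent candidates, and non-recovered
genes are set aside as their own class. Sign concordance between the
drought and ABA responses is **not** required by default
(`require_concordant_sign` enables it; discordant genes then fall back to
ABA-independent). A gene with missing values in a contrast is simply not
a DEG in that contrast (logged), so it can still be classified through
the other drought time point.

## Synthetic study conditions

The generators emulate the pipeline's real inputs at reduced scale with
known ground truth.

* **Network.** Configuration model with Poisson degrees (Erdős–Rényi and
  preferential-attachment generators are also available). Default
  n = 2000 nodes and **mean degree 50**: the real interactome substrate
  for this analysis carries ≈50 interactions per protein
  (2 × 316,747 / 12,574), and scaling down the node count while keeping
  per-gene degree preserves the effective sample size of every per-gene
  statistic. Edge confidences are uniform on (0.5, 1.0], mimicking a
  high-confidence subnetwork. Erased multi-edges make the realized mean
  degree fall ≈2% short of nominal at this density.
* **Planted crosstalk.** Sets A (default 50) and B (default 200) receive
  (enrichment_factor − 1) × |A||B| × density extra A–B edges; each
  designated core gene is additionally topped up to core_excess (default
  10) times its expected background cross-count. Planting **adds** edges
  rather than rewiring, keeping background degree statistics
  interpretable; the manifest records every realized count so all planted
  quantities are recomputable by brute force. enrichment_factor = 1 with
  no cores returns the input graph unchanged (the exact null).
* **Contrast table.** True DEGs draw |log2FC| = 1 + Exp(mean
  effect_log2fc − 1) (default mean 2.5) and p from Beta(0.5, 20)
  truncated below 0.05; non-responsive contrasts draw uniform p and
  N(0, 0.35) log fold changes, rejection-sampled to fail the calling
  rule. With label_noise = 0 every gene therefore classifies back to its
  true class under the default thresholds — by construction, which is
  what makes the round-trip test exact. Label noise re-emits a fraction
  of genes under a random other class while the manifest keeps the truth.
* **Expression matrix.** Log-normal abundances with a latent factor per
  responsive class (within-class log-scale correlation default 0.6) and
  an optional factor shared by the two drought classes
  (drought_shared_corr) to plant cross-class co-expression. NON_DEG genes
  are mutually independent — the realistic regime for a random background
  pool, and the regime in which the co-expression null (fold ≈ 1 when
  nothing is planted) is well defined.

What the generators do **not** emulate: read-level noise (contrast tables
are drawn directly, not via a count model), dependence between fold
change and expression level, modular or scale-free fine structure of real
interactomes beyond the degree sequence, and condition-specific
co-expression. Passing tests therefore demonstrate correctness of the
statistics under a known generative model, not biological validity on
any real data set.

## Design choices

* **Null ensemble.** Double-edge swap with swap_multiplier × |E| attempts
  (default 10 per edge, common practice); rejected proposals (self-loop,
  duplicate, same edge pair) are counted but not retried, and the
  acceptance rate is logged. The proposal picks two edges uniformly and
  one of the two rewirings with probability 1/2, making the chain
  symmetric; on the fully enumerable 6-node 2-regular space the sampled
  frequencies match the uniform distribution over all 70 reachable
  labeled graphs. Replicate seeds derive from the master seed via
  `SeedSequence(master).spawn(i)`, so any replicate is replayable in
  isolation. Edge weights travel with the array slot of the first parent
  edge — a cosmetic choice, since no statistic reads weights. One
  ensemble serves the global Z, the per-gene p-values, and all set-pair
  Z-scores.
* **DEG-side Z-score distribution.** The t-test needs a *sample* of
  Z-scores for the DEG side, but only one (A, B) pair is observed.
  Generating that sample by subsampling a fixed fraction of A and B is
  pseudoreplication: every subsample inherits the one observed pair's
  deviation (correlation ≈ fraction² between subsample Z-scores), so
  under the null the t-test rejects far above its nominal level
  (measured ~50–80% at the 5% level). The default construction instead
  **splits** A and B into n_splits (default 5) disjoint sub-pairs and
  computes one Z per sub-pair; disjoint sub-pairs give nearly independent
  Z-scores that are exchangeable with size-matched non-DEG pairs under
  the null, and the test holds its level (measured 2/50 null rejections)
  while retaining power (planted fixtures reject at p < 1e-9). The
  subsample construction remains available (`deg_resample="subsample"`),
  and with fraction 1.0 reproduces the global Z exactly.
* **Empirical p discreteness.** With the tie-inclusive proportion rule on
  integer cross-counts, P(p < α) under the null is strictly below α
  (super-uniform p-values). On the default null fixture the expected
  fraction of genes at p < 0.05 is ≈0.026 rather than 0.05 — the
  selection is conservative, never anti-conservative. Users comparing
  core-gene counts across networks of very different density should keep
  this in mind; the pseudocount option makes p-values strictly positive
  but even more conservative.
* **Multiple testing.** Core selection uses raw empirical p < α. A
  Benjamini–Hochberg q-value column is emitted alongside for the user but
  does not drive the selection.
* **Degenerate inputs.** Networks with fewer than two edges cannot be
  rewired and are returned as identical copies with a warning. Genes
  absent from the network are "unscorable": excluded from per-gene
  records and from set-size matching, with counts logged. Zero-variance
  genes are dropped from co-expression with a warning. Pools too small
  for size matching raise errors naming required vs available.
* **Determinism.** Every stochastic stage is a pure function of its spec
  and seed; the pipeline derives all stage seeds from one master seed,
  and writers use fixed column order and `%.6g` floats, so a fixed config
  reproduces byte-identical TSV/SIF/GraphML outputs.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` exercise the pipeline at
2000-node scale with R = 1000 replicates (the statistical operating point
of the analysis), plus small enumerable fixtures for exact oracles. The
acceptance script's co-expression fixture uses moderate co-regulation
(within-class 0.2, shared 0.1): with strong co-regulation the top-1%
threshold falls inside the co-regulated block itself and the null link
count degenerates toward zero, making fold enrichment numerically
unstable; the moderate regime keeps the threshold in the bulk pair
population, as in a genome-wide co-expression network.

## Limitations

* The null model preserves degrees only; strength-preserving (weighted)
  or community-preserving nulls are out of scope, as are directed or
  bipartite networks.
* Empirical p-values are bounded below by 1/R; genes whose observed count
  exceeds every null count report p = 0 with the 1/R floor attached.
* The split-based t-test uses n_splits Z-scores on the DEG side; with
  very small DEG sets the split degenerates (sub-pairs of one gene) and
  the test loses power before it loses validity.
* Co-expression enrichment computes correlations from the provided
  matrix; it does not reproduce mutual-rank or database-derived
  co-expression networks.
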
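# Methods

## Model and procedure

The package analyses a genes × samples expression matrix (log scale)
with group labels, in five stages.

**1. Gene universe (differential expression).** A two-group moderated
t-statistic selects the genes responsive to the contrast of interest
(e.g. pre-treatment vs late-treatment samples). Per-gene pooled
variances s²_g (residual df d = n₁ + n₂ − 2) are shrunk toward a prior
variance s₀² with prior df d₀ estimated by the method of moments on
log s²_g: writing e_g = log s²_g − ψ(d/2) + log(d/2), the excess of
var(e) over ψ′(d/2) identifies d₀ through the inverse trigamma, and
mean(e) identifies s₀². The moderated statistic uses the posterior
variance (d₀ s₀² + d s²_g)/(d₀ + d) and is referred to t with d + d₀ df
(normal when d₀ = ∞). Benjamini–Hochberg step-up control at FDR 0.05
defines the gene set. Sample groups are treated as independent; paired
(same-patient) structure across time points is not modeled. When the
empirical spread of log-variances does not exceed ψ′(d/2) the prior df
is infinite and all genes share s₀²; `prior_df=0` disables shrinkage and
recovers the ordinary pooled t exactly. Genes with zero variance in both
groups are assigned p = 1 with a warning — a deliberate degenerate-input
policy (such rows are almost always duplicated constants rather than
signal).

**2. Coexpression network.** Within one sample group (minimum n = 5),
values are rank-transformed per gene (average ranks for ties; constant
genes are excluded with a warning). An edge i–j requires the Spearman
correlation and *all* first-order partial correlations pcor(i, j | k) to
be significant at α (default 0.01, two-sided): the edge p-value is the
maximum over the marginal and the G − 2 partial tests. Significance uses
the Fisher z-transform with standard error 1/√(n − k − 3), k ∈ {0, 1}.
The edge weight is |pcor| at the conditioner with the largest p-value —
the most conservative surviving value; a `zeroth_order` weight rule
(plain |r|) is available, as the choice of which first-order value to
report as "the" weight is a convention, not a theorem. Conditioners
perfectly correlated with either pair member are skipped with a warning.
The screen costs O(G³); an optional `max_conditioners` cap (random
subset, fixed seed) trades exactness for speed on large gene sets and is
off by default.

**3. Permutation validation.** Each replicate permutes every gene's
values independently across the group's samples and recounts significant
pairs under the identical criterion. The empirical p-value uses the
add-one rule (1 + #{replicates ≥ observed}) / (1 + R), so it is never 0.
Replicate r draws from `default_rng(seed + 1 + r)`.

**4. Influence network and scores.** Influence(A, B) =
w(A, B) / Σ_X w(B, X), the denominator running over all of B's
neighbors including A. This normalization makes every connected node's
incoming influences sum to exactly 1 (each node distributes one unit of
"being influenced"), makes the total cumulative score equal the number
of connected nodes, and renders the scores invariant to positive
rescaling of the coexpression weights. It is a one-step proportion, not
a PageRank-style fixed point. Influential genes are scores above the
upper Tukey fence Q3 + 1.5·IQR (quartiles by linear interpolation), or a
top-k cut; ranks break ties by ascending gene ID; isolated genes appear
with score 0 so downstream joins are stable.

**5. Comparison statistics.** Out-degree counts outgoing directed edges
(equal to undirected degree since every edge is bidirectional).
Betweenness is computed on the weighted directed graph; because
shortest-path algorithms read weights as lengths while influence
measures strength, the default converts strength→length by reciprocal,
and an `as_distance` mode passes weights through unchanged for
compatibility with toolchains that do so. Essential genes have p ≤ 0.05
(inclusive) in ≥ 1 cell line; genes with only missing values are
excluded with a warning. Enrichment of a selected set is the upper-tail
cumulative binomial against p₀ = essential fraction among the network's
*non-selected* genes; two selections are compared by two-sided
(minimum-likelihood) Fisher's exact test. Cross-condition comparison
scores each condition's top set under every condition (genes absent
from a network score 0) and applies a Student's t-test, paired by
default since the same genes are measured under both conditions
(unpaired available); identical score vectors are reported as p = 1 and
a constant nonzero shift as p = 0, cases the t machinery cannot
represent. The random-set control draws equal-size gene sets from the
union of the conditions' gene universes, computes the same change
statistic — mean over the set of (own-condition score − mean
other-condition score) — and reports the add-one percentile of the
observed value.

## Synthetic data generator

Expression is drawn from a Gaussian graphical model: precision matrix
with unit diagonal and ±strength at the chosen edges (signs drawn from
the seed), where any row whose off-diagonal absolute sum reaches 0.95
has its diagonal raised to (row sum)/0.95. This guarantees strict
diagonal dominance — hence positive definiteness — without rejection
sampling, and keeps the effective partial correlation of an edge local
to its endpoints: a global off-diagonal rescaling was rejected because a
single high-degree node would shrink *every* edge's partial correlation
(with 40 edges on 50 genes at strength 0.5, to ≈ 0.16, degrading edge
recovery network-wide); with diagonal inflation only edges touching
high-degree nodes are attenuated (by 1/√ of the inflated diagonals).
Differential expression is a mean shift added to chosen genes in the
treated group; a monotone `exponential` marginal transform exercises the
rank invariance of the Spearman machinery; a multi-group mode draws each
group from its own edge set over a fixed gene universe, emulating
treatment-induced rewiring. Essentiality tables guarantee each planted
essential gene one cell line with p ~ U(0, 0.05] and fill all other
entries with U(0.05, 1]. All randomness descends from one integer seed
via `SeedSequence.spawn` (child 0: edge signs, 1: expression draw,
2: essentiality).

What the generator does *not* emulate: probe/batch effects, heavy-tailed
microarray noise, correlated essentiality across related cell lines, and
paired-sample (same patient over time) covariance. Tests passing on this
generator therefore demonstrate correctness of the statistical machinery
under the model's own assumptions, not robustness to those artifacts.

Defaults: strength 0.5 (a moderate direct dependence), 58 samples per
group (a typical neoadjuvant-trial arm), effect size 1.0 (about
two-fold on a log2 scale), 29 cell lines in the essentiality examples
(the size of a standard breast-cancer shRNA panel).

## Numerical choices and test-problem sizes

* Correlations are clipped to 1 − 1e−15 before atanh, so |r| = 1 yields
  p = 0 (significant) rather than overflow.
* Tukey quartiles use linear interpolation; ranking ties break by gene
  ID; edge keys are sorted pairs — all pinned for byte-reproducible
  outputs.
* Edge-list TSVs write weights via `repr` and are read back with
  round-trip float parsing, so write→read is the identity.
* The inverse trigamma uses Newton iteration from the 1/y asymptote
  (relative tolerance 1e−10).
* Verification problem sizes: influence laws on 1,000 random graphs of
  ≤ 50 nodes; edge recovery on 50-gene/40-edge models at n = 500 over
  20 seeds (measured recall ≈ 1.0, precision ≈ 0.92); betweenness
  against exhaustive path enumeration on 200 graphs of ≤ 8 nodes;
  Fisher/binomial against exact enumeration on 500 random tables;
  permutation nulls at 100–200 replicates on 12–20-gene networks. These
  sizes give stable Monte-Carlo estimates while keeping the whole suite
  in the tens of seconds.

## Known limitations

* The first-order screen cannot remove dependencies that require
  conditioning on two or more genes simultaneously (e.g. pairs connected
  by two disjoint paths); higher-order screens are out of scope.
* At α = 0.01 the screen admits the corresponding share of false
  edges among truly independent pairs (measured ≈ 0.005–0.007 of pairs);
  on sparse graphs this bounds attainable edge precision.
* The moderated t stage is a self-contained two-group analogue of the
  standard linear-model workflow; exact numerical equality with any
  specific implementation of that workflow is not a contract.
* Influence is a one-step measure: a gene two steps away contributes
  nothing directly to a gene's score.
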
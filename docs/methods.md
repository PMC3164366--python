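# Methods

## Model and procedure

Two experiments are compared through their ranked gene lists: genes ordered
by |log2 fold-change| between treatment and control, one list per direction
of change. The universe size `N` is the number of genes measured and
retained after filtering in the *shared* universe of the two experiments —
genes absent from either platform are dropped before ranking, which is the
only convention under which the hypergeometric model below is coherent
(both top-`m` selections are subsets of the same population).

Under the null that the two lists are unrelated, the top-`m` blocks are
independent uniform `m`-subsets of the universe, and their overlap `X` is
hypergeometric:

    P(X = k) = C(m, k) C(N − m, m − k) / C(N, m),
    significance of an observed k*:  P(X ≥ k*) = Σ_{k = k*}^{m} P(X = k).

The marching procedure evaluates depths `m = step, 2·step, …` up to the
shorter list's length (a shorter final step covers the remainder). A step
passes if (criterion 1) the overlap tail probability is below `alpha`, and
(criterion 2, from the second step on) the *increment* test below is also
below `alpha`. The march stops at the first failure; the selected depth
`m*` is the last passing step, and the result is the intersection of the
two top-`m*` blocks. If the first step already fails, the verdict is
`no_significant_overlap` with an empty gene set. We deliberately stop at
the first failure rather than scanning all depths for the deepest passing
one: the procedure is sequential, and scanning would change its error
properties.

### The increment test

Conditional on the previous step (top-`m_prev` blocks overlapping in
`k_prev` genes), the null extends each list by `Δm` ranks drawn uniformly
without replacement from that list's remaining `N − m_prev` genes,
independently between lists. Writing `a = m_prev − k_prev` for each list's
private genes, the overlap increase decomposes exactly:

* `X` = new A-genes that were already in B's block: `X ~ HG(N−m_prev, a, Δm)`;
* `H` = new B-genes landing anywhere in A's enlarged block (its `a` private
  genes plus the `Δm − X` A-additions outside B):
  `H | X ~ HG(N−m_prev, a + Δm − X, Δm)`.

`Δk = X + H`, and the reported p-value is the exact double sum
`P(Δk ≥ observed)`. This conditional null is the minimal one consistent
with asking whether the growth of the overlap is explainable by chance; it
is validated against a permutation oracle (simulated random list
extensions, 10^5 draws) rather than assumed — agreement is within 1.4
Monte-Carlo standard errors across a 10-configuration grid spanning
`N` from 150 to 2000.

### Numerical choices

All binomial coefficients are computed in log space (`gammaln`); tail sums
add their terms smallest-first to limit floating-point cancellation. Tail
probabilities that underflow double precision are clamped to the smallest
positive float so comparisons against `alpha` remain meaningful. A tail
threshold below the hypergeometric support minimum (e.g. `k* = 0`) returns
exactly 1. A generalized pmf `C(m_A,k) C(N−m_A, m_B−k) / C(N,m_B)` is
available for unequal selections; the marching algorithm itself always uses
`m_A = m_B`.

When both lists cover the entire universe and the march reaches `m = N`,
the overlap is forced (`P = 1`) and the step cannot pass — the distribution
is degenerate and carries no evidence. Real directional lists cover only
part of the universe, so this arises only in synthetic full-universe
comparisons, where the march then selects the last informative depth.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `step` | 100 genes | ranks added to each list per step |
| `alpha` | 0.05 | significance level for both criteria, raw per step |
| `percentile` | 0.25 | low-expression filter quantile (per condition) |
| `fold_change_mode` | `log_diff` | difference of log2 replicate means |
| `window` | — | max rank displacement of the constrained shuffle |

No multiple-testing correction is applied across steps by default: the
procedure is sequential, each step gating the next, and the type-I error of
the *verdict* is controlled by the first step alone (measured 0.02–0.03 at
`alpha = 0.05`). A Bonferroni-across-steps option (`bonferroni_steps`)
exists for users who want the selected depth itself to be conservative.
`alpha = 0.05` is a conventional choice; the verdict is insensitive to it
in both validation regimes.

## Preprocessing

Expression scores are consumed already normalized, on the log2 scale.
A probeset is discarded iff its mean score is strictly below the
25th-percentile quantile of per-probeset means in *both* treatment and
control (linear-interpolation quantile, the numpy default, fixed by a
regression test). Fold-change is the difference of log2 replicate means —
i.e. the log2 ratio of geometric means. We read "ratio of average
expression scores" on log2-scale data this way because a literal ratio of
log2 scores is scale-dependent and breaks sign symmetry; the literal
alternative remains available as `fold_change_mode="raw_ratio"`. Genes
with several probesets get the arithmetic mean of probeset fold-changes.
Genes with fold-change exactly 0 join neither directional list but count
toward `N`: they are measured (part of the sampling universe) but have no
direction. Magnitude ties rank lexicographically by gene symbol so every
run is deterministic. Any replicate count ≥ 1 per condition is accepted.

## Synthetic data: what it emulates and what it does not

The generators reproduce the validation scheme for the method, not
microarray physics:

* `make_ranked_list(N)` — a complete ranking of a universe, list A of the
  shuffle designs.
* `shuffle_unconstrained` — an unrelated list B (the null regime): the
  verdict's false-positive rate over 500 seeded pairs at `N = 2000` is
  0.02–0.03 against the 0.079 envelope.
* `shuffle_windowed(window)` — a related list B in which no gene moves more
  than `window` ranks. The sampler fills output ranks left to right,
  drawing uniformly among unplaced genes whose original rank is within
  `window`, with a forced-deadline rule (a gene must be placed when its
  deadline rank `orig + window` arrives) that guarantees feasibility and
  the hard displacement bound by construction. It reduces exactly to
  Fisher–Yates when `window = L − 1`; for smaller windows it is near- but
  not exactly uniform over bound-respecting permutations, which is
  irrelevant to its role of producing related list pairs. (A
  jitter-keys-then-rerank sampler with whole-draw rejection was rejected:
  at `N = 5000`, `window = 100` the expected number of bound violations per
  draw is far above one, so rejection essentially never terminates.)
* `make_related_tables(N, frac_shared, effect_size, noise_sd)` — two
  fold-change tables with a planted shared signature: planted genes get a
  shared signed effect `±effect_size` plus the same independent
  `Normal(0, noise_sd)` noise every gene gets, per table. Defaults used in
  validation: `N = 5000`, `frac_shared = 0.3`, `effect_size = 2`,
  `noise_sd = 0.5` — a strong intervention signature over a realistic
  noise floor; recovery F1 is ~0.97 median over 50 seeds.
* `make_expression_matrix` — expands a fold-change table to replicate-level
  scores (baseline 8.0 log2 units, three replicates by default) so the full
  pipeline runs end to end; with zero noise the preprocessing round trip is
  exact.
* `make_tissue_panel` — conditions grouped by tissue, each tissue owning a
  disjoint planted signature; used to check that overlap-distance
  clustering recovers the tissue split as the top bipartition (100/100
  seeds at `N = 1000`, signature 200, two tissues × three conditions).

None of these model probe affinity, batch effects, inter-gene correlation
or platform-specific noise; passing tests demonstrate the statistical
machinery's calibration, power and exactness under its own null, not
performance guarantees on any particular real dataset.

Problem sizes of the validation suites (N = 2000/5000 universes, 100–500
seeded replicates, 10^5 oracle draws) were chosen so each suite completes
in minutes on one CPU while leaving Monte-Carlo standard errors well below
the margins being tested.

## Clustering

`k_ij` is the total common-gene count (up + down) of the pair's directional
comparison, 0 for non-significant pairs; a per-direction matrix is
available. The distance is `d_ij = max_{(l,m)} k_lm − k_ij` with the max
over off-diagonal pairs only — including self-pairs would add a constant
(`k_ii` = universe size) to every distance without changing the topology,
and the metric is meant to compare distinct conditions. Complete linkage is
delegated to `scipy.cluster.hierarchy` and cross-checked in the test suite
against an independently written O(C³) agglomerator (identical merge sets,
heights within 1e-15 on random matrices). Dendrograms serialize to Newick
with branch length = parent merge height − child merge height.

## Cross-species signatures

Homolog tables are two-column TSV (`gene_a`, `gene_b`), or three-column
with a group id whose pairs are the within-group cross product
(HomoloGene-style). Conservation is counted at the homolog-*pair* level: a
pair with both endpoints inside their species' signatures is concordant-up,
concordant-down, or discordant. Collapsing pairs to reporting-species gene
ids gives "any homolog agrees" semantics for multi-homolog genes — the
inclusive choice — while the discordant pairs are preserved in the output
rather than silently dropped, since they are informative about
direction-flipped regulation. The pair-level accounting identity
|up| + |down| + |discordant| = |pairs with both endpoints in signatures|
is enforced by tests.

## Known limitations

* The increment-test null treats each list's next ranks as exchangeable
  draws from its remaining genes; rank-dependent selection intensity within
  a step is not modeled.
* Overlap p-values across the *steps* of one march are dependent by
  construction; the trace is a diagnostic, not a family of independent
  tests.
* The windowed shuffle is near-uniform, not exactly uniform, over
  bound-respecting permutations.
* Cross-platform comparisons assume gene identifiers have already been
  harmonized; the package intersects identifiers literally.
* `raw_ratio` fold changes are centred at 1 and do not feed directional
  ranking; the mode exists for completeness only.
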
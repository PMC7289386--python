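# Methods

## Model and scope

`protnet` treats a z-scored protein-expression matrix (p proteins × n
samples) as draws from a multivariate normal whose conditional-independence
structure is encoded by a directed acyclic graph. Under that model a zero
partial correlation ρ(i, j | S) is exactly conditional independence, which
is what the constraint-based learner queries. The package learns the
*pattern* (CPDAG) of the Markov equivalence class, not a unique DAG: edges
whose orientation is shared by every member of the class are reported
directed ("guided"), the rest undirected ("undetermined"). Causal language
therefore means "consistent with the observed independence structure",
under the usual assumptions (causal sufficiency, faithfulness,
approximately linear-Gaussian expression after preprocessing).

## Preprocessing

* **Quantifiability filter**: a protein is kept when it has at least
  `min_unique_peptides` (default 2) and its detection fraction reaches
  `min_detect_fraction` (default 0.75) within at least one sample-type
  group. The filter only removes rows, so it is idempotent.
* **Imputation** operates per sample column, drawing missing entries from
  N(μ<sub>obs</sub> − `downshift_factor`·σ<sub>obs</sub>,
  (`width_factor`·σ<sub>obs</sub>)²), defaults 1.8 and 0.3 — the documented
  defaults of the standard label-free workflow. Per-column (not
  per-protein) imputation reflects that label-free dropout is
  intensity-dependent per MS run. Columns with fewer than 3 observed values
  cannot support the estimate and raise.
* **z-scoring** is per protein with the population (n) denominator; a
  `ddof=1` switch exists. Per-protein scaling is the convention that makes
  downstream correlations comparable across proteins; the alternative
  (per-sample) is not offered because the learner consumes per-variable
  standardised data.

## Conditional-independence testing

Partial correlations come from inverting the {i, j} ∪ S submatrix of the
correlation matrix (precision-matrix formula); a recursive evaluation is
kept as an internal cross-check (agreement ~1e-10). Near-singular
submatrices (condition number > 1e12) fall back to pseudo-inversion with a
logged warning; exactly rank-deficient ones raise. The Fisher z statistic
√(n−|S|−3)·|arctanh r| is referred to a standard normal, two-sided.
Working level α defaults to 0.01 — the customary choice for PC at
p ≈ 1,000 variables — and is recorded in every output. Queries with
n − |S| − 3 < 1 are *skipped conservatively*: the edge is kept and the skip
counted, so small samples yield denser, not arbitrarily sparse, graphs.
Correlations are Pearson on the z-scored matrix (the Gaussian test's
assumption); Spearman is available for robustness checks.

## Structure learning

The skeleton phase is PC-stable: at each conditioning level the adjacency
sets are frozen before any deletion, which removes the classical
order-dependence of PC. On top of that, all pair and subset enumeration is
lexicographic in protein identifiers, so runs are bit-reproducible and the
output is invariant under row/column permutations of the input (verified
as a test invariant). The first separating set found at the lowest level is
recorded.

V-structures i→k←j are oriented for unshielded triples with
k ∉ sepset(i, j). Conflicting arrowhead demands (possible on finite data)
are resolved conservatively: an existing arrowhead is never overwritten;
the edge is reset to undirected, logged, and locked for the phase.
Meek rules R1–R4 then run to a fixed point; an orientation that would close
a directed cycle is refused and logged. The output graph never contains a
directed cycle or a 2-cycle.

Two independent oracles validate this path:

* `d_separated` — reachability-based d-separation (delegated to networkx),
  cross-checked in the tests against a brute-force path-enumeration
  implementation on small graphs;
* `dag_to_cpdag` — Chickering's compelled-edge labelling, sharing no code
  with the PC phases. Oracle-driven PC equals this construction exactly on
  200 random DAGs of up to 7 nodes (an acceptance test).

`max_cond_size` caps the conditioning level (default unlimited; useful at
p ≈ 1,000).

## Components, annotation, activity

Components are connected components of the mixed graph ignoring edge
direction; isolated proteins are size-1 components. Naming follows the
node-count convention with letter suffixes on ties. The default size filter
dismisses components under 9 nodes as uninformative; an optional
`max_component_size` exists because very large components (hundreds of
nodes) are typically excluded from functional tables, and the reproduction
config makes that an explicit, logged choice rather than an implicit one.

Enrichment is a one-sided hypergeometric tail P(X ≥ k) with the component's
annotated member count m, term size K and a fixed background N (default
20,000, the order of the annotated human genome). Ranking uses the raw p
(ties: larger overlap, then term id); Benjamini–Hochberg q-values are
reported alongside but deliberately do not drive the ranking, since the
major-function call is a labelling step, not an inference. A manual
override exists because curated component labels are often summaries
("Membrane and mitochondria") rather than single ontology terms.

Component activity is the per-sample mean z-score of the members annotated
to the major-function term (term closure is precomputed into the annotation
table). When no member carries the term the computation falls back to all
members, logged. Activity is linear in the expression rows and has
approximately zero mean across samples on z-scored input.

## Subtype comparisons

Two-sided Mann–Whitney per component and subtype pair; the exact null is
used when the pooled sample is ≤ 20 without ties (threshold configurable),
otherwise the normal approximation with midrank-tie and continuity
corrections. Raw p-values are the primary readout (matching the field's
reporting convention); BH q across the whole comparison table is attached.

## Survival validation

* **Ranking**: per component, a univariate Cox fit gives the adverse
  direction; the cohort is split at the `threshold_percentile` cutoff
  (default the median; ties at the cutoff go to low risk) and the two-group
  log-rank p (hypergeometric variance, simultaneous-event ties) ranks the
  components, ties broken by |log HR|.
* **Cox regression** maximises the Efron partial likelihood with a
  safeguarded Newton iteration implemented in numpy (the permutation
  procedure needs ~10⁶ univariate fits, so fits are vectorised across
  covariate batches over a precomputed risk-set structure). Agreement with
  lifelines is pinned to 1e-6 on shared fixtures. Reported p is the score
  test; monotone likelihood (|β| beyond 15) yields a flagged, not thrown,
  result.
* **LOO permutation validation**: each sample's risk label comes from a
  model fitted without it — direction from the left-out fit, cutoff the
  percentile of the remaining activities. The direction uses the sign of
  the Cox score at β = 0, which equals the sign of the MLE because the
  univariate partial likelihood is concave; this makes the score a linear
  functional of the covariate and the whole LOO sweep a matrix product.
  The cross-validated statistic is the **signed** standardised log-rank
  excess of the predicted high-risk group, (O − E)/√V. The sign matters:
  under permuted (null) data the left-out direction estimate is unstable
  and systematically *anti*-predictive, so an unsigned statistic acquires a
  heavy spurious null tail and loses power, whereas the directional
  question — do predicted-high-risk patients fail sooner? — is the one a
  risk predictor must answer. The permutation null permutes (time, event)
  pairs jointly against the activities (preserving the censoring
  distribution), repeats the *entire* LOO sweep per permutation, and
  reports p = (1 + #{perm ≥ observed})/(B + 1), which has the 1/(B+1)
  floor and is never 0. B defaults to 1,000; tests use 200.
* **Percentile scan**: optionally the split percentile is scanned over a
  range (e.g. 30–70 in steps of 5) taking the best split — and every
  permutation repeats the same scan, so the selection is built into the
  null rather than biasing it.

Measured operating characteristics (recomputed by the acceptance suite):
null rejection at the 0.05 level ≈ 0.05 over 100 replicates; power 1.0 for
log-HR 1.5 at n = 96, B = 200.

## Synthetic data

The generator samples a random DAG (lower-triangular Bernoulli adjacency
under a random permutation; expected edges `edge_prob`·p(p−1)/2), draws
edge weights uniform in ±[0.5, 1.5] and unit-variance Gaussian noise, and
simulates the SEM in topological order; the model-implied covariance
(I−B)⁻¹D(I−B)⁻ᵀ is available in closed form for oracle checks. The
linear-Gaussian family is chosen because the Fisher-z test is exact there:
recovery results measure the learner, not model misfit.

Cohort emulation: subtype labels in 50/21/25 proportions; a designated
*target module* — a connected subgraph of up to 8 nodes with its internal
edge weights forced positive, so that it behaves like a co-regulated
functional module whose mean is a meaningful activity — receives subtype
mean shifts (+1 σ for TN-like, +0.5 σ for TNBC by default) on its exogenous
noise; survival is exponential with hazard baseline·exp(log-HR·activity)
and independent exponential censoring calibrated by bisection to the target
censoring fraction (default 25 %). Missingness is logistic in the negative
standardised intensity (left censoring), with the intercept calibrated to
the overall rate; mapped back to a raw intensity scale
2^(z + per-protein abundance) it exercises the full preprocessing path.

What the generator does *not* emulate: peptide-level quantification noise,
batch effects, non-Gaussian expression, correlated censoring, and
annotation incompleteness beyond a fixed term table. Passing recovery tests
therefore demonstrate algorithmic correctness under the model's own
assumptions, not robustness to real-data violations of them.

Default problem sizes keep the test suite fast and were fixed as the
package's own study conditions: structure recovery at p = 15, n = 5,000
(10 seeds, mean skeleton F1 ≥ 0.9); order-independence at p = 30, n = 500;
survival calibration at n = 96 with B = 200; the pipeline demo preset is
p = 60, n = 96, with a p = 1,095 preset for benchmarking only.

## Numerical and degenerate-case policy

* Correlations at ±1 are clamped to 1 − 1e-12 with a warning.
* Degenerate (constant) activities raise rather than silently split.
* Log-rank with zero events raises; label rows that put every sample in one
  group score 0.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence.spawn`); same seed ⇒
  bit-identical matrices, permutations and manifests.
* The run manifest echoes every parameter and contains no timestamps, so a
  rerun is byte-identical and self-describing.

## Known limitations

* PC-stable at cohort scale (n ≈ 100) fragments large true modules; the
  components found are conservative pieces of the truth (the worked example
  shows exactly this behaviour).
* The conservative v-structure conflict policy can leave extra undirected
  edges relative to an oracle pattern on noisy data.
* The hypergeometric enrichment ignores annotation dependence between
  terms; it ranks, it does not test a global hypothesis.
* Univariate survival only: no multivariable Cox with clinical covariates,
  no competing risks.
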
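# Methods

## Data model

A dataset's discrete structure enters as a k-column *combination table*: one
row per attribute combination observed in the data.  Rows are kept as a set —
a combination either occurs or it does not — and duplicates collapse
silently.  The table becomes a k-partite hypergraph: column *i* is vertex
part `V_i`, each category label is a vertex identified by *(column index,
label)* (so an `unknown` label in two different columns never merges), and
each row is a hyperedge meeting every part exactly once.  Rows with missing
or blank entries are a hard error naming the row index: a missing entry has
no hypergraph meaning and silently dropping it would corrupt the
completeness guarantee downstream.  Column order fixes the part indices but
is cosmetic — every output reports attributes by name, and the enumeration
is column-permutation invariant (tested).

Given per-part thresholds θ₁…θ_k ≥ 1, a *solution* is a vertex subset S with
`|S_i| ≥ θ_i` for every part and all cross-combinations `Π_k(S)` present as
hyperedges.  The package default θ_i = 2 everywhere: a sub-dataset is only
useful for isolating an attribute's effect if at least two values of every
attribute vary within it.

## Enumeration algorithm

Maximal solutions are enumerated recursively:

1. **Base case k = 1.**  The unique maximal solution is the set of vertices
   covered by hyperedges, returned iff its size reaches θ₁.
2. **Reduction.**  For k ≥ 2, build the auxiliary bipartite graph
   `B_H = (V_k ∪ W_H, E_H)` whose right side is the family of hyperedge
   remainders `Ê(v) = {H∖{v} : v ∈ H}` (deduplicated by set identity) and
   whose edges record which remainder recombines with which last-part
   vertex.  Two necessary conditions prune the search: the last part `S_k`
   of any maximal solution equals `B ∩ V_k` for some maximal solution B of
   the auxiliary instance `(B_H; θ_k, 1)`, and the rest `S∖S_k` must be a
   maximal solution of the reduced (k−1)-partite instance whose hyperedges
   are the common remainders `Ê(S_k)`.
3. **Candidates and filtering.**  Candidates `K ∪ Ĥ` are pooled in a hash
   set keyed by canonical sorted form and filtered once per recursion level
   to the inclusion-wise maximal ones.

The default mode iterates only `K = B ∩ V_k` per auxiliary maximal solution,
which the two conditions above already make complete; an `exhaustive` flag
additionally iterates every admissible subset `K ⊆ B ∩ V_k` with
`|K| ≥ θ_k`.  Both modes are verified equal to an exhaustive brute-force
oracle on randomized instances; the default is the one used in production
because it explores strictly fewer branches.

The inner biclique enumerator is a depth-first branch-and-bound over the
right vertex set (MBEA-style): each branch extends the current right set,
shrinks the left side to the common neighbourhood, absorbs right vertices
adjacent to all of it, and rejects non-maximal branches via the
processed-vertex list.  Reported bicliques have both sides non-empty.  Side
thresholds are applied as a post-filter, justified by the *filter law*: a
superset of a qualifying biclique always qualifies, so thresholded
maximality coincides with plain maximality (this law is also a tested
invariant of the k-partite enumeration).

Deciding whether any solution exists is NP-complete already for k = 2 with
equal thresholds, and crown graphs (complete bipartite minus a perfect
matching) carry `2ⁿ − 2` maximal bicliques with non-empty sides — the count
the test suite pins for n = 2…5.  Worst-case `O*(2ⁿ)` time and space is
therefore accepted; a candidate-count guard (default 10⁶) raises a clean
error instead of exhausting memory, surfaced as exit code 3 in the CLI.

## Sub-dataset construction

Combination tables are built from per-cell metadata by counting cells per
attribute combination and keeping combinations with **strictly more than**
`min_cells` cells; boundary counts (exactly 10, exactly 25) are excluded,
and this strictness is unit-tested.  The two standard pipelines are:

* *tissue effect* — attributes (individual, tissue, cell type), cells from
  3-month donors, `min_cells = 10`;
* *aging* — attributes (sex, tissue, cell type, age group),
  `min_cells = 25`, where age grouping precedes counting: 3 months →
  "Young", ≥ 18 months → "Old", 1-month donors dropped, any other age an
  error (it would indicate data outside the declared study design).

For a solution, the sub-dataset is exactly the cells whose attribute tuple
lies in `Π_k(S)`.  By construction every combination of the solution must
have at least one cell; a violation means the cell table and the enumerated
table are out of sync and is raised as an error rather than silently
producing an incomplete design.

## Statistical model

Per sub-dataset and per gene, expression is fit by ordinary least squares
with an intercept and dummy-coded categorical covariates; the reference
(dropped) level of each covariate is the lexicographically smallest label
and is recorded in the output so coefficient signs are interpretable.  The
formula the model implements omits an intercept in its textbook form; one is
included here because standard GLM fitting routines include it by default,
and it is switchable (`intercept=False`).

Significance per variable is Type II ANOVA.  With main effects only, the
Type II statistic for a variable is the drop-one-term F test: the full model
versus the model with that variable's columns removed and all other main
effects retained.  Because the design matrix is shared by all genes of a
sub-dataset, the implementation solves one least-squares problem per model
for the whole genes × cells matrix at once; the single-gene path and the
vectorized path are tested against each other and against an independent
formula-interface ANOVA implementation.

Numerical conventions:

* a rank-deficient design flags the fit (coefficients NaN) rather than
  silently returning one of infinitely many solutions;
* genes with zero variance within a sub-dataset get undefined (NaN)
  p-values and a flag — skipped and logged, not failed;
* in the noise-free limit (residual sum of squares below `1e-10` relative to
  the response magnitude but a real RSS change when the term is dropped) the
  p-value is reported as exactly 0.  Zero p-values stay 0 in all result
  tables; only the QQ-plot helper substitutes the minimum non-zero p-value
  before log transformation;
* FDR adjustment is Benjamini–Hochberg (the conventional default), applied
  per sub-dataset, per variable, across genes — matching the per-sub-dataset
  analysis unit.  NaN p-values pass through unadjusted.

**Susceptible genes.**  A gene is tissue-environment-susceptible when its
tissue-effect FDR is below 0.05 in at least `min_subdatasets` of the
analysed sub-datasets; the default of 13 encodes "more than 12 of 24".

**Divergent aging.**  Within a solution spanning two tissues, each tissue's
cells are fit separately with covariates age group plus sex and cell type
when they vary within that tissue (the covariate list is configurable; the
reference "Old" makes the Young coefficient the young-versus-old shift).  A
gene is divergent when the two Young coefficients have opposite signs and
both tissue-wise FDRs are below 0.05.  A tissue containing a single age
group cannot support the contrast and is an error.

The 3-month tissue-effect model's covariate set is genuinely ambiguous in
its textbook statement (individual/tissue/cell-type versus
sex/tissue/cell-type); both are supported via the `covariates` argument and
the pipelines default to using the enumeration attributes themselves, which
keeps the model aligned with the combinations that define the sub-dataset.

## Effect DAGs

For a gene, each sub-dataset with at least two of its tissues contributes
the ordered pairs u → v whenever the fitted effect of u is smaller than that
of v (reference tissue at 0; exact ties contribute no edge, so a single
sub-dataset never yields antiparallel edges).  Sub-datasets contribute
regardless of their per-gene significance — no per-edge significance gate is
applied by default, though an FDR gate is available — and DAG construction
is intended for susceptible genes but accepts any gene.  The union graph's
acyclicity is decided by topological sort; an acyclic graph admits a chain
exactly when every peeling step of Kahn's algorithm has a unique source, in
which case the chain is printed largest-effect first.  Both the acyclicity
decision and chain recovery are cross-checked against an independent
depth-first cycle detector and against planted total orders.

## Synthetic data

The generator module defines the conditions under which the statistical
claims are tested:

* **Planted-atlas cells.**  Cells are laid down for every cross-combination
  of each planted solution, a fixed count per combination, with study-design
  defaults mimicking a multi-age mouse atlas: sexes male/female, Young = 3
  months, Old drawn from {18, 21, 24, 30}, optional 1-month distractor
  cells, adipose-style tissue labels (BAT/SCAT/GAT/MAT), and a default
  solution of 2 sexes × 2 tissues × 3 cell types × 2 age groups.
* **Expression.**  `y = intercept + Σ planted additive level effects
  (+ Young-by-tissue interaction shifts) + N(0, σ²)`, Gaussian to match the
  model's error assumption; default σ = 1 on the log scale, default 200
  cells per combination for power-sensitive scenarios and smaller counts for
  purely combinatorial tests.  Effects are planted only on non-reference
  levels so noise-free fits recover them exactly as coefficients.
* **Susceptible-gene scenario.**  24 independently generated sub-datasets
  (2 individuals × 2 tissues × 2 cell types, 30 cells per combination, σ = 1,
  effect size 2.0); by default 50 of the genes carry a tissue effect in 13
  to 24 of the sub-datasets and the rest are globally null.  The noisy
  scenario deliberately plants no gene at exactly 12 of 24: null p-values
  are uniform at any noise level, so a gene one false positive from the
  boundary would make exact set recovery a coin flip rather than a test of
  the rule.  The 13-versus-12 boundary is instead exercised noise-free
  (where per-sub-dataset significance is deterministic) and on a directly
  constructed effect table.
* **Order coefficients.**  Per-sub-dataset tissue coefficient maps drawn
  from one global order, each sub-dataset observing a random subset of
  tissues; conflict mode appends a sub-dataset with two effects swapped,
  guaranteeing a direct order reversal.

What the simulations do **not** emulate: count-level scRNA-seq noise
(dropout, library-size variation), correlated genes, cluster structure
within cell types, or unbalanced cell counts across combinations.  Passing
tests therefore demonstrate correctness of the combinatorics and of the
estimation/decision rules under the stated Gaussian design — not robustness
to the full messiness of real atlas data.

## Problem sizes and reproducibility

The test suite and the acceptance script run the enumeration-versus-oracle
comparison on 100 random instances with n ≤ 12 vertices, k ∈ {2, 3, 4} and
θ ∈ {1, 2} (brute force is exponential, so the oracle stays small); null
uniformity uses 2000 genes on a 240-cell sub-dataset; recovery scenarios use
the generator defaults above.  All randomness flows from explicit seeds;
generators are pure functions of (config, seed) and re-runs are
byte-identical.  Atlas-scale coverage statistics are computed on random
bipartite tables constrained to the published part sizes and edge counts
(23 × 120 with 207 edges; 20 × 123 with 169 edges) — the statistics depend
only on those counts.  One published figure is arithmetically inconsistent
with its own printed counts (a mean tissue degree of 10.6 against 169 edges
over 20 tissues = 8.45); the summary reports the value computed from its
input.

## Known limitations

* Enumeration is exact but exponential in the worst case; the guard makes
  failure explicit rather than graceful.
* The GLM treats cells as independent observations; individual is available
  as a fixed effect, but no mixed/random-effect structure is offered.
* Gaussian errors on log-transformed expression are assumed throughout; no
  count-family models.
* DAG chains are point-estimate orderings with no uncertainty statement.
* Gene-set enrichment of called genes is out of scope.
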
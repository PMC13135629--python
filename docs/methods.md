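# Methods

## Problem and model

Given n samples with covariates x₁,…,x_L (categorical or continuous,
possibly missing) and a batch capacity k, we seek an assignment of every
sample to one of m = ⌈n/k⌉ batches (each holding ≤ k samples; batches
are indistinguishable) maximizing a composite *balance score*. Balance
of a single covariate is the p-value of a test of that covariate against
the batch labels — the more the covariate's distribution differs between
batches, the smaller the p — and the score is the harmonic mean of the
per-covariate p-values. The p-values are used purely as a monotone,
comparable-across-covariates measure of imbalance on (0, 1]; no
hypothesis is being tested and no layout is classified as "balanced" or
"unbalanced" at a significance level.

Per-covariate tests:

* **continuous** — Kruskal–Wallis with tie correction,
  H = [12/(N(N+1)) · Σⱼ Rⱼ²/nⱼ − 3(N+1)] / C, C = 1 − Σ(t³−t)/(N³−N),
  p = P(χ²₍g−1₎ ≥ H) with g the number of batches containing at least
  one non-missing value. The χ² approximation is used at all sample
  sizes; with very small batches it is approximate (and any rank test
  has little power there), which is a known caveat of score
  interpretation at tiny n, not of the optimizer.
* **categorical** — Fisher's exact test, two-sided in the
  probability-ordering sense: p = Σ P(T) over fixed-margin tables T
  with P(T) ≤ P(observed). Exact for 2×2; for larger r×c tables a
  Monte-Carlo estimate with B replicates,
  p = (1 + #{simulated T with P(T) ≤ P(obs)})/(B + 1), which is always
  ≥ 1/(B+1) > 0. Default B = 10 000.

Effect-size mode replaces p-values by 1 − η (η = √(SS_between/SS_total))
for continuous and 1 − Cramér's V (V = √(χ²/(N·(min(r,c)−1)))) for
categorical covariates; these are combined with the same harmonic-mean
combiner so that all three scoring modes live on (0, 1] with higher =
better. The product combiner Π pᵢ is available for independent
covariates.

**Missing data.** Complete-case per covariate: a sample missing
covariate x is dropped from x's test only; it is still allocated, and
still contributes to every other covariate's test. A covariate left
with a single observed category/value, or fewer than two non-empty
batches, contributes p = 1 (effect 0): it cannot be unbalanced, and
erroring would reject valid designs.

**Blocking.** A blocking column groups samples that must share a batch
(subjects, donors). Blocks are the optimizer's move unit; unblocked
samples are singleton blocks (mixed designs are allowed). A block
larger than k is reported as infeasible. Covariate tests are always
computed at the sample level, also under blocking.

## Optimizer

Simulated annealing over block-to-batch assignments:

* **initialisation** — randomized first-fit-decreasing: shuffle blocks,
  sort by decreasing size (random tie order), place each block into a
  uniformly chosen batch with remaining capacity; bounded retries, then
  infeasibility is reported.
* **neighbourhood** — per proposal a fair coin chooses between swapping
  one uniformly chosen block between two distinct uniformly chosen
  batches, and relocating one uniformly chosen block to another batch;
  capacity-violating draws are redrawn (≤ 100 attempts, then the state
  is kept). Relocation matters because pure swaps cannot change batch
  sizes, and unequal sizes are sometimes where the optimum lies.
* **acceptance** — Metropolis for maximization: improving or equal
  moves always accepted, worsening moves with probability exp(Δ/T).
* **schedule** — geometric cooling every iteration, T_t = T₀·c^t;
  defaults T₀ = 1, c = 0.975, 1000 iterations (one score evaluation per
  iteration). At these defaults the acceptance probability of a
  worsening move of a given Δ falls by ~10⁻¹¹ over the run, giving early
  exploration and late hill-climbing.
* **result** — the best layout over *all* evaluated states (including
  rejected proposals), not the final state; its report is recomputed
  from scratch and equals the traced best score exactly.

The random-search baseline scores independent random packings and keeps
the best; comparisons against annealing are made at a matched number of
score evaluations (1000 layouts vs 1000 iterations), since evaluation
cost dominates both methods.

**Determinism.** One master seed; sub-seeds for the annealer stream and
for each covariate's Monte-Carlo Fisher null are derived by stable
(blake2b) hashing of (seed, label), so the optimizer's move stream and
the test nulls never alias, reruns are bit-identical, and
`balance_score(..., seed=s)` reproduces exactly the score an optimizer
run with master seed s reports.

**Monte-Carlo Fisher implementation.** Null tables at fixed margins are
generated by permuting a canonical category vector built from the sorted
row margins; each permutation segmented at the batch-size boundaries
yields one null table. The B permutations are drawn once per covariate
and their per-category cumulative counts cached, so the sorted null
statistics for a new column-margin multiset cost O(B·m·r); during
annealing only a handful of margin multisets occur, which is what keeps
10 000-replicate tests inside a 1000-iteration run at interactive speed.
Consequences: the null depends only on (row-margin multiset,
column-margin multiset, sub-seed), making the p-value invariant under
batch relabelling and sample reordering, and the same cached null is
reused whenever margins recur. Simulated-vs-observed probability ties
are counted as "at most as probable" with a 10⁻⁷ log-scale tolerance.

## Layout counting

The number of distinct allocations of n distinguishable samples into
m = ⌈n/k⌉ indistinguishable batches of capacity ≤ k is
Σ n!/(Π sᵢ!)/(Π_d m_d!) over integer partitions (s₁,…,s_m) of n with
parts ≤ k, where m_d is the multiplicity of part size d. Because m is
minimal, the total slack m·k − n is < k, so valid partitions biject with
partitions of the slack — enumeration stays trivial at any n. Terms are
accumulated in log-space (log-factorials + log-sum-exp) for stability;
an exact big-integer count is carried alongside and the two are checked
against each other in the tests.

## Synthetic cohorts

The generators define the study conditions for all tests and
experiments; no external data is used.

* **basic cohort** — age ~ N(55, 10), BMI ~ N(30, 5), sex a fair coin;
  the 98-sample / batch-size-13 version is the demonstration instance.
* **analog A (serial biopsies)** — 40 subjects × 5 timepoints = 200
  samples blocked by subject; timepoint categorical with each level
  exactly once per subject; two subject-level binaries with default
  prevalences 0.3 (diabetes) and 0.25 (chronic allograft dysfunction).
* **analog B (donor pairs)** — 100 donors × 2 kidneys = 200 samples
  blocked by donor; trial arm constant within pair (P(treated) = 0.5),
  delayed graft function (0.3) and acute rejection (0.2) per recipient;
  eGFR ~ N(50, 15) and perfusion duration ~ N(300, 60) min per sample.

Only the *design structure* of the analogs (sample counts, block
layout, covariate kinds) mirrors the real case studies; the prevalences
and continuous distributions are plausible clinical defaults, because
the real clinical metadata is not distributed. Passing tests therefore
demonstrate the method's behaviour under realistic structure, not
agreement with any particular real cohort. `inject_missingness` blanks
an exact fraction of covariate cells for robustness checks.

A structural consequence worth knowing: in analog A the subject-level
binaries can only move between batches five samples at a time (whole
blocks), so their sample-level Fisher tables generally cannot reach the
most probable (modal) table and their p-values are capped below 1 — an
exhaustive scan over feasible configurations caps the analog's best
achievable score near 0.93, whereas the real serial-biopsy cohort was
reported at 0.997. Analog B has no such misalignment and optimizes to
> 0.999.

## Numerical choices and edge cases

* p-values/effect complements are floored at ε = 10⁻¹² before
  combination (a zero would annihilate the harmonic mean).
* Kruskal–Wallis H is clamped at 0 against floating-point negatives;
  all-tied values give C = 0 and p = 1.
* Equal-score proposals are accepted (plateau drift is harmless and
  helps mixing).
* Batch indices are 0-based internally and 1-based in all output files.
* Number of batches is always ⌈n/k⌉; the trailing batches may be
  smaller; requesting more than the minimum number of batches is not
  supported.
* Input missing markers ("", "NA", "NaN", case-insensitive) are
  preserved verbatim on output.

## Problem sizes used in the tests

The shipped suite runs the full-scale checks — 10 000 random layouts
for the score-uniformity check, 20 paired replicates of
1000-evaluation annealing vs random search, and both 200-sample
case-study analogs at default settings with five seeds — in about a
minute total; unit tests use smaller Monte-Carlo replicate counts where
only determinism or invariance is at stake.

## Known limitations

* No covariate weighting, no standardized-mean-difference metrics.
* No within-batch (well-position) layout, no nested batch factors, no
  restarts/parallel tempering.
* The χ² approximation of the rank test is rough for batches of only a
  few samples; scores remain comparable between layouts but should not
  be read as calibrated probabilities there.
* Blocked designs quantize the reachable contingency tables (see analog
  A above); the score ceiling of a design can be well below 1 through
  no fault of the search.
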
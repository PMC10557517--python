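# Methods

## Problem setting

The package grades the mental-health (MH) status of college students from a
vector of psychometric indicator scores. Each student is scored on a set of
indicators on a 0–10 scale (higher = healthier); each single score has a
three-band reading (normal ≥ 8, average in [3, 8), obstacle < 3), and the
final outcome is one of four grades — normal, mild anxiety, moderate anxiety,
severe anxiety. Grades are not predicted by a supervised model: the cohort is
clustered into four groups in indicator space, and the clusters are mapped to
grades by ordering their mean scores (highest mean → normal, lowest → severe).

One indicator, *temporal perception*, is derived from duration-estimation
trials: per trial the relative error |estimated − true| / true is computed,
trials are aggregated by the **median** (robust to single wild trials), and
the score is the linear ramp `10 · max(0, 1 − E / max_relative_error)` with
`max_relative_error = 1.0` by default. The median-plus-ramp construction was a
genuinely open design point; it was chosen because the result stays
interpretable against the printed 3/8 band cut-offs and degrades gracefully:
perfect estimation scores 10, a median error at or beyond the cap scores 0.

## The clustering model

K-means minimizes the sum of squared Euclidean errors

    L = Σ_i Σ_{x ∈ c_i} ‖x − c_i‖²

by alternating nearest-centroid assignment and mean updates. Lloyd iteration
is a local search: from a poor initialization it converges to a poor local
optimum, and with strongly unequal cluster sizes (a student cohort is mostly
"normal") random initialization frequently misses the small severe-anxiety
cluster entirely.

The hybrid method replaces the initialization with a global search by the
**fireworks algorithm (FWA)**. Each firework encodes a complete set of K
centroids as one flat vector of length K·d; its fitness is the SSE of the
decoded centroid set under nearest assignment. Per generation:

1. **Explosion radii** — `r_i = (f_i − f_min) / Σ_j (f_j − f_min) · r̄`:
   the best firework searches a vanishing radius (exploitation), the worst
   the full amplitude `r̄` (exploration). A floor of `1e-8 · r̄` keeps the
   best firework's radius non-zero. If all fitnesses are equal every radius
   is `r̄ / n`.
2. **Spark counts** — `s_i = (f_max − f_i) / Σ_j (f_max − f_j) · k`, rounded
   half-to-even and clamped to `[round(0.1k), round(0.5k)]` with a hard
   minimum of one spark, so no firework monopolizes or loses the budget.
3. **Explosion sparks** — each spark perturbs `z ~ U{1..D}` randomly chosen
   dimensions by `radius · U(−1, 1)` (fresh draw per dimension).
4. **Gaussian mutation sparks** — multiply `z` chosen coordinates by
   `g ~ N(1, 1)` (default `canonical` mode). An `as_printed` mode with
   `g ~ N(0, 1)` is kept for fidelity to the original formulation, but that
   variant destroys position information in expectation and is not the
   default.
5. **Bounds** — out-of-box coordinates map back via
   `lo + (|x − lo| mod (hi − lo))`. The box is the data's per-dimension
   min/max tiled K times: centroids outside the data hull are never
   SSE-optimal.
6. **Selection** — the best candidate always survives (elitism; ties broken
   by lowest index); the remaining slots are sampled without replacement with
   probability proportional to each candidate's summed distance to all
   others, preferring sparse regions.

After `T` generations the best firework is decoded into the K initial centers
of a standard K-means run. Because K-means only descends from its start, the
final loss never exceeds the best firework's fitness, and elitism makes the
per-generation best-fitness history non-increasing.

### Default hyperparameters

| Parameter | Default | Meaning |
|---|---|---|
| `n_fireworks` | 6 | population size (fireworks scale n) |
| `spark_budget` | 6 | total explosion sparks k per generation |
| `amplitude` | 25 | maximum explosion radius r̄ (score units) |
| `n_mutation_sparks` | 6 | Gaussian sparks per generation (total, not per firework) |
| `max_iterations` | 100 | generations T |
| `clamp_low_frac`, `clamp_high_frac` | 0.1, 0.5 | spark-count clamp as fractions of k |
| `K` (application layer) | 4 | one cluster per MH grade |
| `loss_tolerance` | 1e-6 | relative loss change that stops K-means |
| `max_iterations` (K-means) | 100 | Lloyd iteration cap |

The amplitude is treated as a user constant rather than recomputed from the
radii themselves (the self-referential alternative is circular and has no
fixed point worth preserving). With 0–10 score data an amplitude of 25
exceeds the box width, so low-fitness fireworks effectively restart uniformly
after modular mapping while good fireworks refine locally — an intended
exploration/exploitation split. `K = 4` is the application default (one
cluster per grade); any K is accepted by the library, but the cluster→grade
mapping is only defined for K = 4 and raises otherwise rather than inventing
a merging heuristic.

### Numerical choices and degenerate inputs

- Assignment ties break to the lowest centroid index (deterministic).
- An empty cluster is re-seeded with the sample currently farthest from its
  own centroid, taken from a donor cluster of size > 1; means are then
  recomputed. This keeps K fixed and cannot increase the loss.
- Convergence uses the *relative* loss change `(L_prev − L) / L_prev ≤ tol`,
  so the criterion is scale-free in the data units; the comparison is
  non-strict so exact fixed points terminate even at `tol = 0`.
- All randomness flows from one seeded `numpy.random.Generator` per run; no
  global state. Equal seed and config ⇒ bit-identical results.
- Spark-count rounding is half-to-even (`np.rint`), applied identically to
  the raw counts and the clamp limits.

## Cluster-to-grade accuracy

Cluster indices are arbitrary, so accuracy against known grades is computed
after finding the one-to-one cluster→grade correspondence that maximizes
total agreement — Hungarian assignment on the contingency table (rectangular
tables are handled directly). Majority-vote mapping was rejected: it can send
two clusters to the same grade and inflate the score. Hungarian-matched
accuracy is invariant under any relabeling of clusters or grades. Note that
with a one-to-one matching the score can fall *below* the largest-grade
frequency when the clustering splits the majority grade — it is bounded below
by (largest contingency cell)/n, not by the majority share.

## The synthetic cohort generator

Real pre-labeled survey data of this kind is not publicly available, so the
generator emulates the study design: 6 colleges × 200 students, ten
indicators (nine conventional + temporal perception), four latent grades with
proportions 0.55 / 0.25 / 0.15 / 0.05 skewed toward "normal" as in a
plausible student body. Each student draws a grade, then scores every
indicator as the grade's mean profile (8.5 / 6.5 / 4.5 / 2.0 by default) plus
independent N(0, 0.8) noise, clipped to [0, 10].

This is the weakest structure under which "clustering recovers grades" is a
testable claim: grade-conditional isotropic Gaussians. With the defaults the
adjacent-grade separation is 2.5σ per indicator (≈ 7.9σ in 10-dimensional
Euclidean distance), so grades are recoverable by construction — nearest-
profile classification exceeds 99% accuracy, which pins the regime where the
clustering benchmark is meaningful rather than circular. What the generator
does **not** emulate: item-level questionnaire structure, correlated
indicators, unequal covariances per grade, missing data, longitudinal drift
across assessment stages, or college-level effects (colleges differ only in
their random draws). Passing benchmarks on these cohorts therefore
demonstrates correctness of the machinery, not clinical validity on real
survey data; harder regimes (smaller separation, different mixes, custom
profiles) are one `CohortConfig` away. Clipping to [0, 10] rather than
truncated-normal resampling leaves a mild boundary mass at 0 for
severe-grade scores (≈ 2.5σ event) — accepted for simplicity.

## Problem sizes used in the shipped checks

The benchmark and acceptance computations run the full default cohort
(n = 1200, d = 10, K = 4) over 20 paired run seeds per method; the
brute-force partition oracle is applied to instances of n ≤ 8 (its enumeration
is capped at 10⁵ partitions); optimizer sanity checks use the 5-D sphere over
[−10, 10]⁵ across 100 seeds. These sizes make the whole suite complete in a
few minutes on one CPU while still exercising the study-scale design.

## Known limitations

- The fireworks stage evaluates the SSE objective serially; no parallel or
  mini-batch evaluation.
- Only minimization is supported (negate the objective to maximize).
- No automatic selection of K, and no heuristic for mapping K ≠ 4 clusterings
  to the four grades.
- The per-college stratified benchmark reuses the pooled protocol per
  college; no hierarchical modeling of college effects.
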
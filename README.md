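# mhcluster

Grading college students' mental-health (MH) status from psychometric
indicator profiles with a **fireworks-algorithm-seeded K-means** hybrid.

Students are scored on a set of indicators on a 0–10 scale (including a
*temporal perception* indicator quantified from duration-estimation error);
the cohort is clustered into K = 4 groups in indicator space, and the
clusters are mapped to the four MH grades — normal, mild anxiety, moderate
anxiety, severe anxiety — by ordering their mean scores. The package is aimed
at methodologists evaluating screening pipelines of this kind: it ships the
optimizer, the clustering, the index layer, a synthetic labeled cohort
generator that emulates a 6-college × 200-student study design, and a
benchmark harness comparing the hybrid against plain and K-means++ seeded
K-means.

## The method

K-means minimizes the within-cluster sum of squared errors

    L = Σ_i Σ_{x ∈ c_i} ‖x − c_i‖²

but converges to a local optimum of L from a poor start. The hybrid first
runs the **fireworks algorithm (FWA)** — a swarm optimizer in which candidate
solutions ("fireworks") explode into "sparks": firework i gets explosion
radius `r_i = (f_i − f_min)/Σ(f_j − f_min) · r̄` (better fitness → smaller
radius) and spark count `s_i = (f_max − f_i)/Σ(f_max − f_j) · k` (better
fitness → more sparks), plus Gaussian mutation sparks and elitist
distance-proportional selection. Each firework encodes all K centroids as one
flat vector with fitness L; after T generations the best firework seeds a
standard K-means run, so the final loss never exceeds the best firework's
fitness. Defaults: 6 fireworks, spark budget 6, amplitude r̄ = 25, 6 mutation
sparks, T = 100. See `docs/methods.md` for the full model description.

## Worked example

```
$ mhcluster simulate --seed 0 -o cohort.csv
wrote 1200 students to cohort.csv

$ mhcluster cluster cohort.csv --method fwa_kmeans --k 4 --seed 0 -o result.json
clustered 1200 students into 4 clusters (loss 7407.022492) -> result.json

$ mhcluster evaluate --result result.json --cohort cohort.csv -o metrics.json
accuracy 1.0000 -> metrics.json

$ mhcluster benchmark cohort.csv --n-seeds 5 -o report.json
kmeans_random: median accuracy 0.7025, median loss 10386.4638
kmeans_pp: median accuracy 1.0000, median loss 7407.0225
fwa_kmeans: median accuracy 1.0000, median loss 7407.0225
report -> report.json
```

`simulate` draws a labeled synthetic cohort (6 colleges × 200 students, ten
indicators, four grades with mean profiles 8.5/6.5/4.5/2.0 and noise sd 0.8).
`cluster` runs the hybrid and, for K = 4, emits each cluster's grade and every
student's predicted grade; the reported loss is the converged SSE L.
`evaluate` computes Hungarian-matched accuracy — the best one-to-one
cluster↔grade correspondence — against the planted grades (1.0000 here: the
clustering recovered the planted partition exactly). `benchmark` repeats each
method over paired seeds; random-init K-means frequently misses the small
severe-anxiety cluster (median accuracy 0.70), while the fireworks-seeded
start recovers the planted grades.

The same functionality is available as a library:

```python
from mhcluster import CohortConfig, generate_cohort, fwa_kmeans, \
    map_clusters_to_grades, match_accuracy

cohort = generate_cohort(CohortConfig(seed=0))
data = cohort.scores_matrix()
result = fwa_kmeans(data, K=4)
grades = map_clusters_to_grades(result, data)
print(match_accuracy(result.labels, cohort.grade_values()))   # 1.0
```

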
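# paintraj

Clustering and transition analysis of **weekly ordinal pain-severity
trajectories** built from daily symptom diaries, for epidemiologists and
biostatisticians working with mHealth patient-generated data.

People with chronic pain report a daily severity score on a 5-point
ordinal scale (1 = no pain … 5 = very severe pain). `paintraj` compiles
these diaries into *complete participant weeks* — seven consecutive
daily scores from one participant over an aligned calendar week — and
asks three questions:

1. **What weekly pain patterns are common?**  Each week is a 7-dimensional
   feature vector x ∈ {1..5}⁷ compared with the Manhattan distance
   d(x, y) = Σᵢ |xᵢ − yᵢ| (respecting the ordinal scale) and clustered
   with an alternating k-medoids algorithm wrapped in CLARA subsampling
   for large n.  Medoids are observed weeks, so cluster centers stay
   interpretable.  k is chosen by scanning k = 1..20 with 20 random
   restarts per k (lowest within-cluster dispersion, WSS, kept), taking
   the elbow of the WSS-vs-k curve, and requiring every cluster to hold
   ≥ 5% of trajectories (with a downward fallback when the elbow k fails).
2. **Is the answer an artifact of the metric assumptions?**  Three
   sensitivity analyses rerun the pipeline treating the scale as
   continuous (longitudinal k-means with mean centers, Euclidean
   distance), as unordered categorical (one-hot (day, score) indicators,
   Jaccard distance), and with the week redefined to start on each of
   the seven days.  Solutions are compared by the percentage of
   trajectories assigned to corresponding clusters after optimal label
   matching (plus the adjusted Rand index).
3. **How do people move between patterns?**  Over consecutive-week
   pairs a row-normalised k×k transition matrix P(cluster this week |
   cluster last week) is estimated and contrasted with the uniform
   100/k % baseline; cluster descriptions (severity-ordered letters,
   shares, weighted spaghetti paths, per-demographic mean time in
   cluster with participant-level percentile bootstrap CIs) round out
   the picture.

Because daily diary data of this kind are rarely public, the package
ships a first-class synthetic cohort generator: participants join at
staggered dates, stay for a geometric number of weeks, miss days at
random, and carry a latent weekly severity state evolving by a planted
Markov transition matrix with noisy ordinal emissions.  Ground-truth
states are returned so the whole pipeline can be validated as a
parameter-recovery exercise.

## Worked example

```python
import numpy as np
from paintraj import (SyntheticConfig, generate_cohort, extract_complete_weeks,
                      consecutive_pairs, encode_weeks, select_k, cluster_shares,
                      assignment_map, transition_matrix, stay_percentage)
from paintraj.describe import assignment_letters

cfg = SyntheticConfig(n_participants=200, seed=7)
dataset, truth = generate_cohort(cfg)
weeks = extract_complete_weeks(dataset)          # complete Monday-Sunday weeks
print(f"{len(weeks)} complete participant weeks from {len(dataset.participants)} participants")

X = encode_weeks(weeks, "ordinal7")
report = select_k(X, k_range=(1, 12), method="clara", metric="manhattan",
                  n_runs=20, base_seed=0)
print(f"elbow at k={report.elbow_k}; chosen k={report.chosen_k}; "
      f"{report.variability_explained_pct}% of variability explained")
print("cluster shares:", {k: round(v, 2) for k, v in cluster_shares(report.solution).items()})

letters = assignment_letters(report.solution)
pairs = consecutive_pairs(weeks)
m = transition_matrix(pairs, assignment_map(weeks, letters), labels=list("ABCD"))
stay, _ = stay_percentage(m)
print(f"{len(pairs)} consecutive-week pairs; {stay:.2f}% stay in the same cluster")
print(np.round(m.percentages, 1))
```

Output:

```
1577 complete participant weeks from 200 participants
elbow at k=4; chosen k=4; 79.4% of variability explained
cluster shares: {'A': 18.52, 'B': 33.29, 'C': 30.69, 'D': 17.5}
715 consecutive-week pairs; 68.39% stay in the same cluster
[[70.  20.   7.7  2.3]
 [13.3 71.7 10.   5. ]
 [ 3.5 17.2 66.1 13.2]
 [ 2.5  5.1 28.  64.4]]
```

The generator planted four latent severity states with a
strong-diagonal transition matrix; the pipeline recovers the elbow at
k = 4, letters the clusters A (lowest pain) through D (highest), and
the estimated transition matrix shows the stay-and-move-to-adjacent
structure of the planted process.  Rows are *last week*, columns *this
week*, in percent.

A command line mirrors the library —
`paintraj {simulate, extract-weeks, cluster, select-k, describe,
transitions, sensitivity, full-run}` — with `full-run` producing a
complete report bundle (CSV tables, elbow and spaghetti plots,
transition heatmap, `summary.json`) from one YAML config and one master
seed.

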
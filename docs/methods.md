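# Methods

## Data model

The unit of analysis is the **complete participant week**: seven
consecutive daily ordinal pain scores (1–5) from one participant over a
calendar week aligned to a configurable start day (Monday by default).
A week enters the analysis only if (1) the participant joined the study
on or before the week start, (2) remained in the study through the week
end, and (3) scored every one of the seven days.  "Remained in the
study" is operationalised as the participant's `last_date` (their final
recorded presence) being on or after the week end; diary apps rarely
expose uninstall telemetry, so the last record is the available proxy.
No imputation is performed — the analysis is complete-case by design,
and the known selection effects of that choice (missingness correlated
with very low or very high pain) are inherited by anything downstream.

Duplicate same-day entries are resolved by keeping the last row in file
order, mirroring a diary app where the day's final answer stands.  Dates
are timezone-free calendar dates; age is consumed as a group label.

## Clustering

Weeks are encoded as 7-vectors of raw scores and compared with the
Manhattan distance, which depends only on rank differences along the
ordinal scale.  Clustering is **alternating k-medoids**: k initial
medoids are drawn uniformly from the distinct weeks, then assignment to
the nearest medoid and per-cluster medoid recomputation (the member
minimising total within-cluster distance) alternate until assignments
stabilise.  This "Voronoi" variant is implemented deliberately instead
of PAM's swap search; a greedy swap refinement exists behind a flag
(`swap_refine`, off by default) for small-data checks.  Both tie-break
rules are deterministic: nearest-center ties and medoid ties resolve to
the lowest index.  The assignment-step objective is recorded per
iteration and is provably non-increasing.

**CLARA** scales this to large n: k-medoids runs on `n_samples = 5`
subsamples of size `min(n, 40 + 2k)` (the classical defaults), every
week is assigned to each candidate medoid set, and the set with the
lowest full-data distance-to-medoid cost is kept.  Subsample indices are
kept in ascending order so index tie-breaks carry over; with
`sample_size >= n` and one subsample, CLARA is bit-identical to a single
k-medoids run with the same seed.

The **longitudinal k-means** variant (KmL-style) used in sensitivity
analysis 1 swaps medoids for coordinate-wise means under the Euclidean
distance; an emptied cluster is re-seeded at the point farthest from its
nearest center.

Random initialisation makes single runs volatile, so every reported
solution is the best of `n_runs = 20` seeded restarts (seeds
`base_seed + 0..n_runs-1`; ties to the lowest seed).  All randomness in
the package flows from explicit seeds — there is no global random
state anywhere.

## Within-cluster dispersion (WSS)

Three selectable modes are provided because "within-cluster sum of
squares" is genuinely ambiguous for medoid methods: `to_center`
(Σ d(x, center)), `to_center_squared` (Σ d²), and `pairwise` (all
unordered within-cluster pair distances).  The default is `to_center`
for medoid methods and `to_center_squared` for k-means.  `to_center`
was chosen for the k-selection curve because, combined with the
warm-start protocol below, it makes the curve provably non-increasing
in k and hence the elbow well defined; the variability-explained
statistic 100·(1 − WSS_k / WSS_1) is a ratio and does not depend on
which printed convention produced the WSS pair.

## Choosing k

For each k in 1..20 the best-of-20-runs solution is computed; each k
additionally tries one **warm start** built from the previous k's
centers plus the point farthest from its nearest center, which
guarantees WSS(k) ≤ WSS(k−1).  The elbow — visually chosen in practice
— is automated as the k maximising the vertical deviation below the
chord joining the curve's endpoints (invariant to affine rescaling of
the WSS axis; ties and degenerate linear curves resolve to the smallest
interior k; all-identical data cap the scan at the number of distinct
points and fall back to k_min).  Every cluster must hold at least 5% of
the trajectories; if the elbow k fails, selection walks downward to the
nearest smaller k that passes.  The third criterion used in practice —
clinical interpretability of the centers — is inherently human:
the report exposes the full curve, deviation profile and center
summaries, and a `force_k` override, but never decides it automatically.

## Sensitivity analyses and agreement

Analyses 1 (continuous + longitudinal: k-means/Euclidean) and 2
(categorical: one-hot (day, score) indicators/Jaccard/CLARA) rerun the
full k-selection on the same week set; analysis 3 re-extracts weeks for
each of the seven start days and compares cluster share distributions
only, because the week sets differ by construction.  Agreement between
two solutions over the same weeks is the percentage assigned to
corresponding clusters under the **optimal label matching** (linear
assignment on the contingency table).  The correspondence rule is a
design choice — severity-rank matching is also computed when both
solutions have equal k, and by construction can never beat the optimal
matching.  The adjusted Rand index is reported as a
matching-free supplement.

For the one-hot encoding the Jaccard distance is computed through an
exact algebraic reduction: both vectors carry exactly one indicator per
day block, so with m matching days the union has 14 − m elements and
d = 1 − m/(14 − m).  This is a fast path, not an approximation, and is
tested against the generic set-based formula.

## Descriptions and the bootstrap

Clusters are lettered A, B, C… by ascending mean severity of their
center.  Time in cluster is participant-level: each participant's
proportion of complete weeks per cluster, averaged **unweighted** over
the participants of a demographic group, so heavy diarists do not
dominate group contrasts.  Condition groups are multi-membership.
Uncertainty uses a percentile bootstrap resampling **participants**
(respecting within-person correlation of weeks), B = 1000, 95% level —
variant and B are design choices, made once.  Calibration is checked by
simulation: at group size 50 over 300 replicates the CIs cover the true
group mean at roughly 94%, inside the 95 ± 3 band expected of a
percentile bootstrap on moderately skewed proportions.

## Transition analysis

Consecutive-week pairs are weeks of the same participant exactly 7 days
apart; a week flanked on both sides contributes to two pairs.  The
transition matrix is a post-hoc tally over clustered labels — no
hidden-Markov smoothing, no joint estimation — with rows normalised to
percentages and empty rows reported as missing rather than imputed.
Deviations are read against the uniform 100/k baseline.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
cohort.  Defaults (chosen once as the study conditions and not
revisited): 500 participants over a 64-week span; joins uniform over
the span; participation duration geometric with mean 26 weeks (a
six-month tracking request is typical of diary studies); per-day
missingness 0.1; four latent severity states anchored at scores
1, 2, 3, 4; emission probability 0.8 on the anchor with the remainder
split onto anchor±1 (clipped at the scale ends and renormalised);
initial state distribution (0.08, 0.38, 0.38, 0.16); and a
tridiagonal-dominant planted transition matrix with 0.65 diagonals, so
stays dominate and moves are mostly to adjacent severity states.
Demographics (sex 83/17, six age bands, nine multi-label conditions)
are sampled from fixed marginals, with optional log-linear tilts of the
initial state distribution for condition carriers (fibromyalgia and
neuropathic pain toward the severe state, rheumatoid arthritis toward
the mild end) so demographic contrasts in time-in-cluster are
reproducible.

The latent state is constant within Monday-aligned calendar weeks and
moves only at week boundaries.  Two consequences matter for
interpreting tests: recovery is easier than in real data (real pain has
no four-point latent grid, no week-synchronised switching, and
missingness is not at random), and weeks extracted on non-Monday start
days straddle state switches, genuinely blurring their cluster
structure — the day-of-week robustness test therefore uses a sticky
(0.9-diagonal) planted transition so that blur reflects the pipeline,
not the grid.  Passing recovery tests shows the pipeline is correct and
well calibrated under its own assumptions; it does not certify the
clinical claims of any particular cohort.

## Problem sizes and numerics

Validation runs use cohorts of 500 participants (≈ 3,700–4,000 complete
weeks) for k-selection and sensitivity recovery, 2,000 participants
(≈ 6,800 pairs) for transition recovery where the ≥ 5,000-pair regime
keeps every cell's sampling error under ~1 percentage point at 3 SE,
200 small instances (n ≤ 10, k ≤ 3) for exhaustive-enumeration
optimality of the restart heuristic, and 300 replicates for bootstrap
calibration.  Floating-point comparisons use absolute tolerances of
1e-9 in optimality checks; Manhattan distances on ordinal input are
exact integers, which most equality assertions exploit.

## Known limitations

- The elbow criterion is a formalisation of a visual judgement; on flat
  or nearly linear curves the maximum-chord-deviation rule can sit on a
  near-tie (its full deviation profile is reported for exactly this
  reason).
- Alternating k-medoids converges to local optima; the restart protocol
  empirically attains the exhaustive global optimum on small instances,
  but no guarantee exists at scale.
- The transition matrix conditions only on the previous week
  (first-order), and estimation is post hoc on clustered labels, so
  assignment error propagates into transition estimates.
- Complete-case week selection can bias both cluster shares and
  transitions when missingness is informative; the generator's
  missingness is uninformative by default, so this bias is not
  exercised by the tests.
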
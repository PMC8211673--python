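# Methods

## Distances

The Jensen-Shannon distance (JSD) is computed in natural-log units: the
square root of the Jensen-Shannon divergence, itself the average of the
two Kullback-Leibler divergences to the mixture m = (x+y)/2. A
pseudocount of 1e-7 is added to every abundance and each distribution is
renormalized **before** the mixture is formed — the pseudocount protects
the KLD logarithms, and applying it to the inputs (rather than to m)
keeps m exactly the average of the vectors actually compared. With
natural logs the distance is bounded by √(ln 2) ≈ 0.83255; the
classification threshold 0.4 and all reported medians are on this scale
(base-2 logs would rescale everything by √(1/ln 2)).

Bray-Curtis dissimilarity is computed on relative abundances in its
quantitative form 1 − 2·Σmin/Σ(a+b). No pseudocount is applied there:
the formula is zero-safe, and adding one would only dilute genuinely
disjoint supports.

Numerical details: the all-pairs JSD matrix uses the entropy identity
JSd(x,y) = H(m) − (H(x)+H(y))/2, clipped at zero before the square root
(roundoff can produce −1e-17 for near-identical profiles); the
elementwise and matrix routes agree to 1e-12 and both are tested against
scipy's independent base-e implementation. Exact symmetry of the matrix
is enforced by averaging with its transpose (last-bit asymmetry from
summation order).

Intra-individual distances default to consecutive wave pairs (1→2, 2→3)
plus the explicit 1→3 pair needed by the persistence subtype; arbitrary
increasing pairs are accepted. Inter-individual distances are always
within a single wave — mixing waves would confound between-person
differences with within-person drift.

## Classification and persistence

A subject is *changed* iff their intra-individual JSD ≥ threshold, with
the boundary inclusive. The default threshold is the fixed constant 0.4;
`derive_threshold` reports the median inter-individual distance for
other cohorts but never silently replaces the constant, so published
classifications stay reproducible. Over three waves, subjects are typed
`stable_both` (both intervals below), `transient` (exactly one at/above,
not subdivided by which), or continuous (both at/above), the latter
split into `continuous_reverted` / `continuous_progressive` by whether
the wave-1→wave-3 distance fell back below the threshold. A continuous
subject with no wave-1→wave-3 distance gets subtype `NA` with a warning
rather than an error.

No quantitative criterion for "predominant-family replacement" is
implemented: the changed class is defined purely by the distance
threshold, and replacement is a description of what such changes look
like, not an extra filter.

## Statistical procedures

Closed-form tests delegate to scipy/statsmodels behind a uniform
result type: Fisher's exact (two-sided by probability-mass summation —
conventions differ, so this is pinned and oracle-tested against exact
integer enumeration), Pearson chi-square without continuity correction
(df = 1), classic mean-centered Levene (`center="median"` gives
Brown-Forsythe), Spearman with the t approximation (an exact permutation
option exists for n ≤ 10), and the covariate-adjusted group comparison
as an OLS fit of y on intercept + group + covariates with a t-test on
the group coefficient — numerically identical to the classic 1-df
adjusted ANCOVA F. Rank-deficient designs raise an error naming the
first collinear column; incomplete cases are dropped listwise,
mirroring per-analysis n's in observational tables.

Two procedures are implemented in-package as seeded permutation tests:

- **Steel's many-to-one rank test**: each treatment is compared with the
  control via the tie-corrected standardized Wilcoxon rank-sum on the
  jointly ranked pair; the familywise p of treatment k is the fraction
  of label permutations whose maximum absolute standardized statistic
  across all treatments reaches k's observed value (single-step max-T).
  Tabulated critical values do not cover arbitrary group sizes, and the
  permutation analogue is calibrated by construction; it is documented
  as a variant, not a table lookup.
- **PERMANOVA**: the pseudo-F from the within/between decomposition of
  summed squared dissimilarities read directly off the distance matrix
  (no ordination), with label permutation and the (count+1)/(n+1)
  p-value convention. The statistic is cross-checked against
  scikit-bio's implementation in a test.

Both are bitwise-deterministic given (seed, n_permutations); permutation
p-values are bounded below by 1/(n_permutations+1).

## Synthetic cohorts

The generator emulates a two-to-three-wave yearly cohort of 218 elderly
subjects. Compositions are logistic-normal — softmax(log_mean +
between-subject Gaussian) — rather than Dirichlet, because independent
control of between-subject heterogeneity and within-subject drift is
what the stability analysis stresses, and the softmax parameterization
provides exactly that. Year over year a subject either drifts
(log-abundances gain N(0, σ_w²) noise — a random walk on the log scale)
or, with a small intake-group-dependent probability, undergoes a
replacement event: the composition is redrawn from the cohort prior,
rejection-sampled until its JSD from the previous year reaches the 0.4
threshold. Unconditional redraws would land below 0.4 about half the
time (the between-subject median sits at ≈0.4), which would break the
interpretation of an event as a substantial change and make the
configured event rate unrecoverable from the classifier; the rejection
step makes "event" and "changed" coincide by construction. Event
recurrence across consecutive intervals follows a separate persistence
probability (default 8/14).

Parameters, units and defaults:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 218 | cohort size |
| `n_years` | 2 | waves; 3 extends the first `n_subjects_third_year`=135 subjects |
| `between_subject_sd` | 1.10 | log-scale sd of baseline heterogeneity (frozen) |
| `within_subject_sd` | 0.75 | log-scale sd of yearly drift (frozen) |
| `event_prob_lt3` / `event_prob_ge3` | 0.113 / 0.017 | per-year replacement odds by intake group |
| `prop_ge3` | 58/218 | fraction in the ≥3 days/week group (deterministically spread) |
| `event_persistence` | 8/14 | recurrence odds given an event last interval |
| `event_min_jsd` | 0.4 | rejection-sampling floor for replacement draws |

The two noise scales were frozen once by a grid search
(`analysis/05_calibration_search.py`) targeting a median intra-individual
JSD of 0.205 and a median inter-individual JSD (wave 1) of 0.401 at the
study sizes; the best grid point (1.10, 0.75) reproduces those medians
within ±0.01 averaged over seeds. The 15 default families and their
log-mean abundances are order-of-magnitude typical for the elderly gut
(a Ruminococcaceae/Lachnospiraceae/Bacteroidaceae-dominated community);
they are illustrative, not estimates of any dataset. Covariates (age,
sex, BMI, smoking, alcohol, intake days/week per 1-month/5-year/10-year
recall window) are drawn with cohort-like marginals; the intake covariate
influences *only* the event probability — drift scale is group-independent.

Each subject owns an RNG sub-stream seeded by (seed, subject index), so
cohorts are reproducible under subject-count changes and bitwise
identical across runs.

**What the generator does not emulate.** No sequencing noise (read
counts, rarefaction); no per-subject volatility heterogeneity, so the
continuous-scale correlation between consecutive interval distances is
much weaker than in real cohorts (the association there comes almost
entirely from event recurrence); between-subject spread grows slightly
by wave 2 because drift is a non-mean-reverting random walk, so the
wave-2 inter-individual median sits a bit above wave 1's rather than
marginally below; no antibiotic/disease covariates. Consequently,
passing tests demonstrate that the pipeline recovers structure the
generator encodes (event rates, group contrasts, typology counts), not
that it would reproduce any particular real cohort's covariate-specific
dispersion patterns.

## Input handling

Wide abundance tables (first column `sample_id`, one column per family)
with rows summing to 1 within 1e-6 are accepted and renormalized to
exactly 1 — sequencing pipelines emit rounded fractions, so a stricter
tolerance would reject legitimate exports while a looser one would mask
real errors. Rows further from 1, negative entries, metadata/abundance
mismatches and duplicate (subject, wave) pairs are hard errors. Wave
indexes are ordinal (1, 2, 3), assumed ≈1 year apart; calendar dates are
out of scope. Missing covariates propagate as missing and are dropped
listwise per analysis. All readers/writers round-trip within 1e-12
(the distance-matrix reader symmetrizes the last decimal digit and
zeroes the diagonal).

## Known limitations

- The 0.4 threshold is a convention anchored to one cohort's
  inter-individual median; `derive_threshold` exposes the data-driven
  analogue but classification defaults stay fixed.
- Steel's test here is the permutation max-T variant, not the tabulated
  procedure; p-values agree with a two-sided rank-sum permutation test
  in the single-treatment case but are not the textbook critical-value
  construction.
- PERMANOVA permutes labels freely (one-way design); no strata or
  repeated-measures restriction, so mixing both waves of the same
  subject in one matrix would pseudo-replicate — the pipeline therefore
  always runs it within a single wave.
- Family-level only; no per-genus classification, no phylogeny-aware
  metrics, no enterotype clustering.
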
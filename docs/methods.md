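# Methods

This note records the modeling assumptions, numerical conventions and
known limitations behind `trajmorbid`. It states no empirical result
that the test suite does not itself compute.

## State sequences

A person's trajectory is a sequence of cumulative diagnosis sets on an
**age grid**: interval boundaries are birthdays, not calendar dates, so
individuals born in different years are directly comparable and
follow-up differences appear only as differing observed lengths. The
state at interval *t* is the set of categories first diagnosed *strictly
before* the start of interval *t*; a diagnosis falling exactly on a grid
point counts from the next interval. The default grid is yearly with a
common target length of 36 intervals; 6-month and 4-month grids are
supported, and coarsening a finer grid at year starts reproduces the
yearly sequence exactly (tested). Observed length is
`floor((censor − birth) / increment)`, capped at the target.

Diagnosis removal or revision is not modeled: first-diagnosis dates are
final, so sequences are monotone in the subset order by construction.

## Substitution costs: Dice vs Jaccard

The default scheme (`paper_overlap`) prices a substitution of composite
state *a* for *b* at the Sørensen–Dice dissimilarity
`1 − 2|a∩b|/(|a|+|b|)` (0 when both are empty), because this is the
function consistent with the canonical worked examples for this method
({F1}↔{F3} = 1, {F1,F3}↔{F4,F50} = 1, {F1,F3}↔{F3,F4} = 0.5). A
set-theoretic Jaccard scheme (`1 − |a∩b|/|a∪b|`, giving 2/3 for the
third example) and a constant 0/1 scheme are provided for sensitivity
analyses. Indels cost 1 unit; all substitution costs are ≤ 1, so a
substitution is never dearer than an indel pair.

**A consequence worth knowing:** the Dice dissimilarity is *not* a
metric — `d({a},{b}) = 1` exceeds `d({a},{a,b}) + d({a,b},{b}) = 2/3` —
so the optimal-matching distance under the default scheme can violate
the triangle inequality on a small fraction of triples (empirically
~0.1% of sampled triples on synthetic cohorts). Under the Jaccard
scheme the substitution cost is a metric and no violation was observed
on any sampled triple. Analyses that require a genuine metric (or
near-Euclidean) input should use `scheme="jaccard"`; the default is kept
for fidelity to the worked examples. Classical MDS tolerates mild
non-metricity: negative eigenvalues are dropped and their relative mass
is reported (`EmbeddingResult.negative_mass`).

## Censored tails

Sequences are right-censored at death, emigration or end of follow-up.
Each censored sequence is extended to the target length with a
first-order, time-homogeneous Markov chain estimated by maximum
likelihood from all observed transitions, pooled over persons and
intervals; states never observed as an origin receive a self-loop. The
first imputed interval is one transition step from the last observed
state, and each later interval one further step.

A censored position is thus a probability distribution over states. Its
substitution cost against an observed state is the expectation of the
deterministic cost; between two censored positions it is the **double
expectation under independence** (no joint modeling of the two chains).
Point masses reproduce deterministic costs exactly (tested). Note that a
distribution aligned against itself has positive expected cost — the
expected cost of two i.i.d. draws — so distances involving heavily
censored pairs are mildly inflated; this is the second, smaller source
of approximate metricity alongside the Dice issue above. Age-dependent
transition estimation and alternative distribution-distance costs are
deliberately out of scope.

The alignment itself is a Needleman–Wunsch dynamic program over the two
tail-extended position vectors; indels apply to imputed positions at the
same unit cost, and floating-point ties are broken in the fixed order
diagonal, up, left (this affects scripts, not distances). The inner loop
is JIT-compiled when numba is available, with a pure-Python fallback.

## MDS, projection, stability

Classical (Torgerson) scaling double-centers the squared-distance matrix
and retains the leading eigenvectors scaled by the square roots of their
eigenvalues. Variance-explained fractions are computed over the
positive spectrum only. Requesting more dimensions than there are
positive eigenvalues is an error that names the usable maximum.

Dimension signs are fixed deterministically (largest-magnitude loading
positive); the model layer then re-orients dimension 1 to correlate
positively with total comorbidity count, dimension 2 with
childhood-onset category indicators, dimension 3 with substance use,
matching the conventional reading of these axes.

Out-of-sample individuals (replication cohorts) are placed by Gower
interpolation from their OM distances to the training cohort; this is
exact for training points (tested to 1e-8). Because a censored
sequence's expected self-distance is positive, projecting an exact copy
of a censored training person is exact only up to that inflation;
for fully observed sequences it is exact to machine precision.

Jackknife stability re-embeds the configuration after each single
deletion (subsampled to `max_leave_out` deletions for large cohorts,
default 200), aligns it to the full solution by similarity Procrustes
(translation, rotation/reflection, scaling), and reports
`1 − mean squared displacement / total score variance`, clipped to
[0, 1]. The permutation test of embedding stability is a documented
placeholder (symmetric shuffling of off-diagonal distances, comparing
top-k variance concentration); its equivalence to any canonical test is
unknown.

## Clustering

Ward's minimum-variance agglomerative clustering runs on the retained
MDS dimensions (Euclidean scores, "Ward.D2"-equivalent), never on the
raw dissimilarity matrix. Cluster ids are relabeled by descending size
for run-to-run comparability. The R² profile is the between-cluster
over total score sum of squares for k = 1..k_max (default 13).

The elbow rule returns the smallest k (≥ 3) whose marginal R² gain has
dropped to at most a fraction (default 0.25) of the previous gain; a
profile with no such level-off (linear, flat) returns 1 with a warning.
Two semantics caveats, verified empirically: when an elbow is sharp and
all gains up to the true k are comparable, the rule fires one past the
true k; and smoothly decaying profiles (typical of trajectory scores)
may never trigger at the default fraction. The selected k and rule are
logged; `n_clusters` can always be fixed explicitly.

Bootstrap stability follows the cluster-wise Jaccard scheme: each
resample is re-clustered, every original cluster is matched to its
best-Jaccard counterpart (index sets compared on the resampled points),
and coefficients are averaged per cluster. The surrogate classifier is
a depth-limited CART (Gini) tree on interpretable features — per
category, indicators of diagnosis before/after the index diagnosis and
age at first diagnosis (never-diagnosed encoded as a sentinel age of
99) — with agreement to the input clustering reported as the Rand
index. The feature set is a documented assumption.

## Epidemiology

Cumulative incidence is one minus Kaplan–Meier on the age scale,
censoring at the first of death, emigration or end of follow-up;
competing risk of death is handled by censoring, not by a
sub-distribution estimator. The before/after-index decomposition
apportions the overall estimate by the observed fraction of first events
preceding the index diagnosis — a display convention, not a Fine–Gray
model. Relative risks are simple proportion ratios with log-method CIs,
`exp(ln RR ± z √(1/a − 1/n1 + 1/b − 1/n2))`.

Pairwise hazards: for each ordered category pair (A, B), a Cox model for
the first B diagnosis with age as the time scale (so age adjustment is
absorbed into the baseline hazard), sex as the only fixed covariate, and
prior-A as a time-varying indicator realized by splitting follow-up at
the first A date. Episode splitting preserves per-person person-time
exactly (tested). Other diagnoses are deliberately not adjusted for.
Non-convergent or inestimable pairs are flagged and excluded from the
significance count; the Bonferroni threshold is α / (C·(C−1)), displayed
at two significant digits.

## Association layer

The joint test per risk variable is a MANCOVA of the retained dimension
scores with Pillai's trace and its standard F approximation, computed
directly from the hypothesis and residual SSCP matrices (an exact linear
dependence yields Pillai → 1, F = ∞, p = 0 rather than numerical
breakdown; cross-checked against statsmodels on regular designs).
Missing predictor or covariate values are deleted listwise per variable,
with the non-missing count reported. Post-hoc per-dimension OLS effects
are filled only when the joint p passes the Bonferroni threshold
(default 0.002 for a 25-test family). Cluster membership is analyzed by
multinomial logistic regression against a reference cluster, with
separation flagged. Hospitalization outcomes enter as events per year
of post-index follow-up. Default covariates are age at censoring and
sex; richer covariate sets (ancestry components, genotyping batch) can
be passed through but are the caller's responsibility.

## Synthetic registries

The generator emulates a national-registry birth cohort: births uniform
over 1981–2002, follow-up to 2016-12-31, so observed sequence lengths
span ~14–35 years; per-year death and emigration probabilities default
to 0.001 and 0.0005 (matching the order of magnitude of such cohorts'
censoring counts); two controls per case, matched by duplicating the
case's birth date and sex (incidence-density matching is not
implemented). Comorbidity onsets are drawn in continuous time from
piecewise-constant exponential rates `λ = −ln(1 − h)` equivalent to the
configured per-year probabilities `h`, so a constant hazard yields the
geometric cumulative incidence `1 − (1−h)^t` exactly; a pairwise
multiplier switches the target category's *rate* at the exact prior
diagnosis date and is therefore the true Cox hazard ratio (recovered by
the Cox stage in tests). Cases' index diagnoses are truncated-normal
ages (class-specific mean, bounds 10–34), and censoring is drawn
conditionally after the index diagnosis, since registry cohort
membership requires it. Controls use population-average hazards scaled
by 0.15 and no multipliers. Covariates are normal (continuous) or
Bernoulli (binary, logit-shifted per class); hospitalization counts are
negative binomial (dispersion 2) with class-specific yearly means, since
overdispersed counts are the registry norm.

The default five latent classes mirror the canonical trajectory
subgroups — childhood-onset comorbidity, multiple adult comorbidities,
mood-only, substance abuse, little comorbidity — with mixture weights
~0.11/0.29/0.14/0.13/0.33 following the relative subgroup sizes
reported for cohorts of this kind.

What the generator does **not** emulate: absolute Danish register
prevalences, calendar effects (the ICD-8→ICD-10 switch, outpatient
coverage from 1995), diagnostic drift by birth year, incidence-density
control matching, or within-person correlation of covariates beyond the
planted class structure. A green pipeline test therefore establishes
that the machinery recovers planted structure of realistic shape and
size — not that it would reproduce any particular register's numbers.

## Numerical conventions

- Dates are ISO-8601; a year is 365.25 days.
- Transition rows are validated to sum to 1 within 1e-12; position
  distributions within 1e-9.
- Eigenvalue positivity uses a relative tolerance of `n·eps·|λ_max|`.
- Ward ties follow scipy's deterministic lowest-index merge; bootstrap
  and jackknife subsampling are seeded.
- Dissimilarity matrices are written as TSV with an id header
  row/column; cohorts above 2000 sequences fall back to a binary `.npy`
  container in the pipeline output.

## Known limitations

- The default Dice cost is non-metric (see above); use `jaccard` where a
  metric is required.
- Time-homogeneous transition estimation ignores age dependence of
  diagnosis rates; tails imputed for early-censored individuals inherit
  this bias.
- The before/after cumulative-incidence split and the MDS permutation
  test are conventions/placeholders, not estimators with established
  theory.
- The elbow rule's semantics (first k past a collapse in marginal gain)
  can overshoot a sharp elbow by one; inspect the R² profile.
- MANCOVA assumes multivariate-normal residuals of the scores; with
  strongly clustered scores the F approximation is only approximate.
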
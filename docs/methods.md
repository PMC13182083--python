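# Methods

## The compositional model

A subject's day is the composition **x** = (MVPA, LPA, NSST, SLP, ST),
strictly positive minutes closed to 1440. All inference is done in
Aitchison geometry: the centred log-ratio clr(**x**) = ln **x** − mean(ln **x**),
and an orthonormal ILR basis built by sequential binary partition in pivot
form, where coordinate k contrasts part k against the geometric mean of all
later parts with scale factor √((D−k)/(D−k+1)). The canonical part order is
(mvpa, lpa, nsst, slp, st); any permutation is supported, and the
per-component coefficient table is produced by rotating each part to the
front and refitting — all D rotations describe the same fitted surface, a
fact the tests assert to 1e-10.

The outcome model is OLS of the PHQ-9 total on the four ILR coordinates
plus treatment-coded covariate dummies (reference level = first category).
Standard errors, t-based p-values (n−p df) and the coefficient covariance
are classical OLS quantities (statsmodels). The clr coefficient vector
**a** = Bβ sums to zero by construction and converts any prediction
difference into the log-contrast form **a**·Δln **x**, which is how
substitution estimates are computed.

Substitution estimates: moving Δ minutes from part i to part j at baseline
**G** gives Δŷ = **a**·(ln **G\*** − ln **G**). Confidence intervals use the
delta method on the contrast c = ilr(**G\***) − ilr(**G**) (variance c'Σc with
the ILR block of the coefficient covariance; intercept and covariate rows
enter with weight zero). When a model is reconstructed from a published
per-component table ("external-coefficients mode": a_k = √((D−1)/D)·β_k,
re-centred to exact sum zero, tolerating a printing-error sum of up to
0.01), no covariance exists and estimates are reported without CIs rather
than with a fabricated one.

## Instrument scoring

PHQ-9: total = item sum (0–27), severity bands 0–4 / 5–9 / 10–14 / 15–27
(none/mild/moderate/severe). Screen time: school-day minutes weighted 5 and
weekend minutes weighted 2, divided by 7. Composition assembly: MVPA =
moderate + vigorous; LPA = walking; NSST = total sedentary − daily screen
average; SLP = reported sleep. The sleep value is used as reported, without
school-day/weekend weighting, since the instrument yields a single habitual
duration. Non-positive parts (including negative NSST when reported screen
time exceeds reported sedentary time) are floored at `zero_floor`
(default 1 min — small enough to be epidemiologically negligible, large
enough to keep log-ratios finite) before multiplicative closure to 1440.
Records with any missing or invalid required field are dropped
(complete-case) and counted in the run log.

## Synthetic cohorts

The generator draws ILR coordinates from a multivariate normal centred at
ilr(mean composition) — the unique simplex law under which the ILR-linear
regression is correctly specified — and maps them back through the inverse
ILR, closing to 1440. Outcomes are y = β₀ + **a**·clr(**x**) + covariate
effects + N(0, σ²).

Defaults emulate the published reference cohort whose summary statistics
ship in `cism24._reference` (a cross-sectional survey of 6,666 urban
Chinese adolescents):

- mean composition = the cohort's geometric-mean day
  (44.11, 32.02, 385.04, 658.24, 320.59 min);
- ILR covariance = the exact reconstruction from the cohort's published
  pairwise log-ratio variation matrix. A variation matrix T determines the
  clr covariance uniquely by double-centering, Σ_clr = −½·H·T·H with
  H = I − J/D, and here the implied ILR covariance is positive definite, so
  the generator's theoretical dispersion equals the published matrix to
  machine precision (a diagonal ILR covariance was considered and rejected:
  its best fit leaves a residual of ~2.3 on the 10 free entries);
- true clr coefficients = the published per-component pivot coefficients
  rescaled by √(4/5) and re-centred;
- intercept chosen so the expected score at the mean composition and the
  covariate mix equals the published mean score of 6.18 points;
- noise σ = 5 points, approximating the published score SD (5.79) net of
  what composition and covariates explain;
- covariates (sex, grade, BMI class) drawn independently of composition at
  the published frequencies, with modest additive effects in the direction
  of the published group medians (girls ≈ +2 points, higher grades up to
  +3, small BMI gradient). A per-level ILR-shift knob exists to induce
  confounding for adjustment tests, off by default.

Scores are continuous by default so parameter-recovery tests are clean;
`discretize=True` rounds and clips to the 0–27 integer range, which
attenuates coefficients slightly (the clip at 0 bites, since the score
distribution has mass near zero) — tests bound this bias loosely rather
than pretending it away. What the generator does **not** emulate:
item-level PHQ-9 response processes, recall bias and the 10-minute
recording threshold of self-reported activity, school-day/weekend activity
structure, or nonlinear composition–outcome relationships. Passing recovery
tests therefore shows the estimator is correct under its own assumptions,
not that those assumptions hold in field data.

## Descriptive statistics

Mann–Whitney U uses midranks, the tie-corrected normal approximation and no
continuity correction, reported as (U, Z, two-sided p) — the standard form
at epidemiological sample sizes; at group sizes ≤ 8 the approximation sits
within ~0.05–0.08 of the exact permutation p because the discrete null has
probability steps of that order. Kruskal–Wallis is the tie-corrected H with
a χ²(k−1) reference (scipy). Cronbach's α uses the classical
k/(k−1)·(1 − Σ item variances / total variance) formula with n−1
denominators, cross-checked against pingouin in the tests. Variation-matrix
entries are sample variances (n−1) of pairwise log-ratios.

## Numerical choices and degenerate inputs

- Natural logarithms throughout; the pivot scale factors are only
  orthonormal under ln.
- Closure is multiplicative and idempotent; compositions validate positivity
  and the 1440 total to 1e-6.
- Reallocations that would exhaust the donor part raise, naming the part and
  the maximum feasible delta; substitution-matrix cells that are infeasible
  are flagged (NaN estimate, `feasible=False`) instead of raising, and
  curve grids are clipped to the feasible range with a warning. The default
  curve range is ±60 min in 5-min steps; at the reference baseline the
  donor bounds clip MVPA curves at −40 and LPA curves at −30 min.
- Default substitution grid (10, 20, 30 min), configurable.
- Report rounding is 2 decimal places, banker's (half-even).
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  config and seed give bit-identical cohorts and artifacts.

## Known limitations

- The severity label of a continuous (non-discretized) synthetic score is
  derived from the rounded, clipped value and is only meaningful in
  discretized mode.
- External-coefficients mode inherits the printing precision of its source
  table; reconstructed substitution estimates are exact only to roughly
  ±0.01 points.
- No zero-imputation machinery beyond the floor rule; heavily zero-inflated
  activity data would need a dedicated treatment.
- Classical (non-robust) OLS standard errors; no multiple-testing
  adjustment across the 60-cell substitution matrix.
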
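# Methods

## The evaluation model

`greypsy` implements a fixed-weight grey-clustering evaluation of
psychological state for patients recovering from transurethral resection
of the prostate (TURP), together with the statistical comparison layer of
a two-arm nursing trial built around that evaluation.

A patient's psychological state is measured on `m` aggregate indices
(anxiety, depression, sleep quality, …).  Index `j` has a full score
`E_j` and four boundary points `a_1 < a_2 < a_3 < a_4` that partition its
range into three ordered grey classes — good, ordinary, morbid.  The
machinery is:

1. **Class centers.**  `λ_k = (a_k + a_{k+1}) / 2` for `k = 1, 2, 3`.
2. **Whitening weight functions.**  Membership of an observation `x` in
   class `k` is the center-point triangular function: zero outside
   `(λ_{k−1}, λ_{k+1})`, rising linearly to 1 at `λ_k`, falling linearly
   back to zero.  The extreme classes, which have no outer neighbour
   center, are *shoulder* functions: class 1 is constant 1 for
   `x ≤ λ_1`, class 3 constant 1 for `x ≥ λ_3`.  With this choice the
   three memberships sum to exactly 1 for every `x` — a partition of
   unity over the whole measurement range, not just `[a_1, a_4]`.
3. **Index weights.**  `Z_j = E_j / Σ_j E_j` (score proportions), so
   `Σ_j Z_j = 1`.
4. **Comprehensive clustering coefficient.**
   `σ_i^k = Σ_j f_j^k(x_{ij}) Z_j`.  Because of 2. and 3., each
   patient's three coefficients are in `[0, 1]` and sum to 1.  The
   assigned class is the argmax; exact ties resolve to the *most severe*
   tied class, on the grounds that a borderline patient should be
   flagged for intervention rather than waved through.

The raw overall score `Σ_j x_{ij}` (unweighted; weights enter only the
clustering coefficient) gives a coarse bifurcation: above 100 points a
patient leans morbid, below 100 ordinary, exactly 100 is reported as
`boundary` and left to the coefficients to resolve.

Assumptions worth stating: indicators are oriented so that *higher =
worse*; the class count is fixed at three; the index configuration (not
the data) fully determines the classifier — there is no training step,
which is why `GreyClusterEvaluator.fit` only validates the configuration
and precomputes `centers_` and `weights_`.

## The default index system

No canonical index table ships with the method, so the package provides a
configuration-driven system plus a documented default: six indices with
full scores (40, 40, 30, 30, 30, 30), Total = 200, and boundaries at
(0.2, 0.4, 0.6, 0.8) of each full score.  Consequences: each index's
ordinary center `λ_2` is half its full score, and the 100-point overall
threshold is exactly the all-indices-at-`λ_2` configuration, which makes
the score bifurcation and the clustering assignment agree in the
unweighted aggregate.  Any other system can be supplied as YAML/JSON
(`name`, `full_score`, `boundaries` per index) and is validated on load.

## The statistical layer

Between-arm comparisons use the battery standard for such trials:

- **t-test**: independent-sample, pooled-variance Student by default
  (the arms are equal-sized); Welch via `welch=True`.  Computable from
  raw columns or from published summary statistics.
- **One-way ANOVA**: between/within mean-square ratio; for two groups
  `F = t²`, which is property-tested at 1e-9.
- **Pearson χ²** with a Yates continuity-correction policy
  `auto | on | off`.  `auto` applies Yates exactly when any expected
  cell count is below 5.  This single rule reproduces all four published
  χ² statistics of the motivating study (complications 4.356 without
  correction, min expected 9.0; satisfaction 5.538 with Yates, min
  expected 3.5; education 0.042 and income 0.041 without, min expecteds
  > 20).
- **Fisher exact test**: two-sided, hypergeometric.  Tests cross-check
  it against a full enumeration over margin-fixed tables.
- Derived clinical quantities: satisfaction = (high + normal) / total ×
  100 (2 d.p.); complication incidence per category and in total;
  threshold flags — erectile dysfunction iff IIEF-5 < 22 (a score of
  exactly 22 counts as normal, taking the strict inequality of the
  instrument's published rule), anxiety iff HAMA ≥ 7, depression iff
  HAMD ≥ 7.

All p-values come from the exact t / F / χ² / hypergeometric
distributions.  The published t and F statistics of the motivating
study's baseline and scale tables are **not** reproducible from their
own printed means and SDs (e.g. a printed t of 3.254 paired with
P = 0.956 at df = 96 is arithmetically impossible), so the package does
not treat them as ground truth; correctness of the t/ANOVA code rests on
the algebraic identity `F = t²`, closed-form oracles, and Monte-Carlo
null calibration (10,000 replicates; Kolmogorov–Smirnov distance to the
uniform below 0.02 for the t-test and below 0.06 for χ², the latter
allowing for the discreteness of the statistic at a few hundred counts
per arm, which alone contributes ≈ 0.03).

## The synthetic cohort generator

Real patient-level data for this design are not publicly deposited, so
`greypsy.synth` generates cohorts with the study's published statistical
structure: 49 patients per arm; per-arm normal marginals for age,
prostate volume, IPSS, PVR, Qmax, IIEF-5 (screening and pre/post
nursing), HAMA and HAMD pre/post, with means and SDs taken verbatim from
the published tables; per-arm categorical distributions for education,
income, complications (six categories including none) and satisfaction
(high / normal / dissatisfied).  Pre/post scale pairs are bivariate
normal with correlation 0.5 (the source reports nothing about the joint
distribution; 0.5 gives plausible paired trajectories).

Two modes:

- `sample` — i.i.d. draws; sample means converge to the configured
  parameters (tested at n = 2000 per arm within 3 standard errors).
- `census` — categorical variables are exact multisets (largest-remainder
  allocation, then a seeded shuffle), so at n = 49 the published
  contingency tables are reproduced count-for-count and the χ² golden
  values emerge from a full simulate → compare run, not from hard-coded
  tables.

**Indicators.**  Each patient carries a latent baseline class: morbid
with probability 0.5 (exact half-split in census mode), ordinary
otherwise — the published score distribution is described as roughly
bimodal about 100 points.  Per index, ordinary patients are drawn around
0.45 × full score and morbid patients around 0.65 × full score (SD
0.075 × full score, clipped to `[0, full_score]`), i.e. overall-score
modes near 90 and 130.  Both centers sit safely inside their class's
membership region, away from the assignment tie points at 0.4 and 0.6 of
full score.  Post-intervention indicators are
`x_post = x_pre · (1 − δ) + noise` with improvement fractions δ of 0.45
(morbid) / 0.25 (ordinary) in the observation arm and 0.20 / 0.10 in the
control arm: everyone improves, and the good-class coefficient gain is
largest for baseline-morbid patients in the observation arm — the
qualitative signature the re-evaluation summary is designed to surface.

**Clamping.**  By default the scale marginals are *not* truncated to
instrument ranges, because the published post-nursing observation-arm
IIEF-5 (mean 24.87, SD 1.85) is unattainable on the instrument's support
[5, 25] — the largest SD any distribution on [5, 25] with that mean can
have is √((25 − 24.87)(24.87 − 5)) ≈ 1.61.  Matching the printed moments
therefore takes precedence; `clamp_scales=True` enforces the instrument
ranges (logging every clamp) for users who prefer admissible values over
exact marginals.

**What passing tests do and do not show.**  The generator matches
*marginals* (and one pairwise correlation); it encodes no joint
structure between scales, categories and indicators beyond the latent
baseline class, no site, time or measurement-error structure, and no
dropout (the study reports complete follow-up).  Green tests demonstrate
that the pipeline recovers what the generator put in; they say nothing
about how the method behaves on real, messier cohorts.

## Numerical and design choices

- Tolerances: coefficient normalization 1e-9; oracle equivalence of the
  clustering coefficients 1e-12; golden statistics compared after
  round-half-even to the printed number of decimals.
- Degenerate inputs raise typed errors naming the offending patient or
  index: non-increasing boundaries, observations outside
  `[0, full_score]`, missing observations, all-zero coefficient vectors,
  zero contingency-table marginals, empty arms or cohorts.
- The within-arm pre-versus-post scale comparisons are run as
  independent-sample tests (the design of the source tables is
  ambiguous); a paired analysis can be built from the raw columns.
- The pipeline writes a single JSON artifact as the source of truth;
  markdown/CSV tables are pure functions of it, so re-rendering a saved
  artifact is byte-identical.  Percentages print at 2 d.p., statistics
  at 3 d.p.
- Problem sizes in the test suite: distributional checks use 2000–4000
  patients per arm and 10,000 Monte-Carlo replicates, which keeps the
  whole suite in the tens of seconds while leaving the 3-standard-error
  recovery bands well clear of noise.

## Known limitations

- Three grey classes, triangular/shoulder whitening functions only; no
  s-class generalisation, trapezoidal or endpoint-measure variants.
- Whether the original method extends the extreme classes by boundary
  mirroring rather than shoulders cannot be determined from the source;
  shoulders were chosen because they preserve the partition of unity
  without inventing boundaries.
- The default index system is a documented stand-in: the study's real
  index table and boundary values are not published.
- No multiple-testing adjustment (the source applies none) and no
  reliability (Cronbach's α) computation, which would need item-level
  data.
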
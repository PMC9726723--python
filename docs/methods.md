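# Methods

## Study design being modelled

The package analyses cross-sectional egocentric support-network surveys of
NCD outpatients.  Each record set has three tables: egos (demographics,
insurance, chronic conditions, a binary 7-day medication-adherence
outcome, optional biometrics), alters (one row per named tie, 2–10 per
ego, carrying both alter attributes and tie attributes), and alter–alter
acquaintance.  Alter pairs absent from the tie table are treated as
acquainted: these networks are small and kin-dominated, and near-complete
interconnection is the observed norm, so the tie table stores exceptions.
This keeps raw files sparse and makes "no tie rows" mean "fully
interconnected", not "unknown".

## Frequency recoding

Contact and support frequencies are collected on a six-level scale and
converted to event-days per 30-day month: daily/almost daily → 30, a few
times a week → 10, weekly → 4, a few times a month → 2, monthly → 1.  The
mapping deliberately compensates for the unequal spacing of the categories
as collected.  *Less than once a month* is assigned 0 days: the monthly
dichotomisation (≥ 1 event-day/month) must classify it as "not monthly",
and 0 keeps ego-level aggregates interpretable as counts.  Whether it
should instead contribute a fractional day is undecidable from the scale
itself; the mapping is overridable per run and echoed into the manifest
for audit.

Emotional + informational event-days are pooled into non-material support
by **summation**, not maximum: the aggregate counts support events, and
summing preserves event counts when a tie provides both sub-types (the
pooled value may therefore exceed 30).

Alter age is collected in brackets, so the younger/older dichotomy uses
the only rule expressible from brackets: an alter is *younger* iff the
bracket's upper bound is ≤ the ego's age.  Brackets straddling the ego's
age count as *same-or-older* (conservative toward "older"); the open-ended
top bracket is never "younger".  Age homophily uses half-open brackets
[lower, upper), making boundary membership unambiguous.

## Composite tie strength

Tie weight is the arithmetic mean of eight components, each in [0, 1]:
proximity, duration, contact frequency, support frequency (the strongest
sub-type frequency the alter actually provides), reciprocity, non-material
provision, material provision, satisfaction.  Ordinal components are
scaled rank/(levels−1); proximity and frequency scales are reversed so
that closer/more frequent = stronger.  Missing components (e.g. support
frequency for a non-supporting alter) are dropped and the mean
renormalised — zero-imputation would conflate "unknown" with "weakest
possible".  Satisfaction is scaled over the instrument's declared level
count (default: 5-level Likert), not over the levels observed in a given
sample, so the score does not change meaning when a sample happens to use
only the top of the scale.

The weak/medium/strong split uses exact 1-D k-means: optimal clusters in
one dimension are contiguous in sorted order, so dynamic programming over
the sorted values attains the global minimum within-cluster SSE.  This
removes the seed-dependence of Lloyd-style k-means and makes the
three-class split bit-reproducible.  Boundary ties break toward the lower
cluster so equal values always share a class.  Egos are classified on
per-ego *mean* tie weights (the per-tie classification is also emitted).

## Association statistics

* **Welch t-test** — t = (x̄₁−x̄₂)/√(se₁²+se₂²), Satterthwaite df.  Accepts
  mean/SE/n summaries because published tables often print only those.
* **Cluster-robust OLS** — sandwich variance with cluster-summed scores,
  small-sample factor G/(G−1)·(N−1)/(N−K) and t inference on G−1 df,
  matching the convention of the major survey-analysis packages; with
  singleton clusters this reduces exactly to HC1, which the tests exploit
  as a cross-check against statsmodels.
* **Chi-square / Fisher** — Pearson X² without continuity correction; on a
  2×2 with any expected cell < 5 the p-value falls back to Fisher's exact
  test (every result carries its method label).  Default on, because
  ego-level tables at n ≈ 100 routinely produce sparse cells.
* **Katz risk-ratio CI** — log-scale interval
  exp(ln RR ± z√(b/(a·n₁) + d/(c·n₀))); zero cells are flagged rather than
  silently perturbed.
* **Cornfield odds-ratio CI** — for candidate ψ the fitted exposed-case
  cell solves ψ = A·D/(B·C) with the observed margins; the limits solve
  A = a ∓ cc ∓ z·√V(A), V(A) = (1/A + 1/B + 1/C + 1/D)⁻¹.  The default has
  no continuity correction (cc = 0), which is the convention of the
  standard epidemiological packages and what published lower limits
  reproduce; cc = ½ is available as a parameter.  Limits are found by the
  classical fixed-point iteration (tolerance 1e−8, budget 500 iterations).
  When a cell sits at or near its margin the quadratic approximation
  degenerates and the upper-limit iteration oscillates rather than
  converging; such an upper limit is reported as *unbounded*, matching the
  behaviour of classical implementations on sparse tables.  A
  non-convergent lower limit is re-solved by exact bisection of the same
  equation (the tests also use an independent root-finder as an oracle).
  Simulated coverage at the study's margins is ≈ 95% (see the acceptance
  suite).

Two-sided p-values throughout; no multiplicity adjustment — the analysis
is explicitly bivariate/exploratory, and at n = 100 egos there are too few
degrees of freedom for adjusted models.

## Synthetic generator

The generator's defaults are the study's marginal distributions: 100 egos;
age ~ TruncNormal(62.8, 8.2) on [30, 95]; P(woman) = 0.68; insurance 0.87;
marital, education, occupation, and disability categoricals at their
reported frequencies; alter counts on {2..7} with mean 3.0 and SD ≈ 1.0;
relation mix (child .641, partner .171, other-family .109, …); proximity,
time-known, contact and satisfaction categoricals from the reported tie
margins; provision probabilities .849/.734/.411 with conditional frequency
distributions per sub-type; money ~ log-normal matched by method of
moments to mean 50,861 / SD 64,163 TSH, rounded to 100 TSH; per-pair
unacquainted probability 0.007 (≈ 2 egos in 100 with an incomplete alter
graph at 3 alters/ego).  Where the tables report nothing, a value was
fixed once on plausibility grounds: reciprocity 0.8 (support networks of
this kind are heavily reciprocated), household size 1 + Poisson(3.7)
(mean 4.7).

Adherence is generated at the ego level from the *realised* monthly
support indicators: logit P(adherent) = β₀ + β_nm·1[monthly non-material]
+ β_mat·1[monthly material].  Defaults β₀ = −1.0, OR_nm = 8, OR_mat = 6
were calibrated analytically (closed form over the alter-count
distribution) to give ≈ 0.85 overall adherence, the reported margin.  No
temporal causality is simulated — the design is cross-sectional and the
generator does not pretend otherwise.

Sampling is driven by one root `SeedSequence`; per-ego substreams are
spawned from it, so datasets are prefix-stable in `n_egos` and
byte-reproducible.

**What the generator does not emulate.**  Attributes are sampled
independently within and across levels: there is no gender × marital
association, no age structure in relation types, no within-ego correlation
of support provision beyond the shared alter count.  Two consequences
matter for interpretation.  First, ego-level monthly-support prevalences
implied by independent ties are higher than the published ego-level
margins (real support provision is correlated within egos).  Second, the
two support exposures share the alter count, so the *crude* 2×2 odds
ratio equals the generative OR only when a single effect is active; the
parameter-recovery tests therefore use single-active-effect
configurations.  Passing tests demonstrate that the pipeline's
transformations and estimators are correct on data with the study's
margins — not that the generator reproduces the joint structure of the
real survey.  Correspondingly, data-dependent published summaries (mean
tie weight 0.77, the 12/39/49 class split, the exact bivariate means) are
emulation targets, not golden values.

## Problem sizes and numerical choices

The test suite exercises the generator at 100–10,000 egos: marginal
fidelity is asserted at 10,000 egos within three binomial standard errors
of each configured probability; interval coverage uses 2,000 simulated
2×2 tables; test calibration uses 10,000 Welch replicates; parameter
recovery pools three replicate 5,000-ego datasets and requires agreement
within two Monte-Carlo standard errors.  Exact k-means is verified against
exhaustive enumeration for n ≤ 10.  These sizes give stable Monte-Carlo
bands while keeping the full suite under a minute on one CPU.

Degenerate inputs fail loudly and early: all-zero tables, zero margins,
single clusters, rank-deficient designs (naming the collinear columns),
non-finite values, and out-of-vocabulary categories are all rejected with
specific errors; row-level survey defects are dropped into a validation
report with a per-row reason rather than aborting the run.

## Known limitations

* The validator's drop-report policy (e.g. an ego falling below 2 valid
  alters is dropped with its alters) is this package's convention; field
  practice for partial refusals varies and is rarely documented.
* The Cornfield "unbounded upper limit" report reproduces the classical
  iterative behaviour; the underlying score equation can have a large but
  finite root that the iteration cannot certify.  Users wanting a bounded
  limit on sparse tables should prefer an exact conditional method.
* Money conversion to USD is display-only and requires a rate supplied in
  configuration; all stored amounts are integer TSH.
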
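# Methods

## The counterfactual model

The analysis contrasts an observed surgical (RP) cohort with a hypothetical
surveillance (AS) cohort assumed identical except for treatment. The AS
cohort's cumulative event risk at every horizon t is modelled as a fixed
multiple of the RP cohort's:

    risk_AS(t) = k · risk_RP(t),    k ≥ 1.

All downstream quantities are arithmetic consequences: excess absolute risk
(k − 1)·x, scaled survival S′(t) = 1 − k·(1 − S(t)), and number needed to
harm 1/[(k − 1)·x]. Multipliers below 1 are rejected — the model describes
harm, and interpreting k < 1 as benefit (a number needed to treat) is out of
scope.

The scaling is on the risk scale, not the hazard scale. The two forms are
distinguishable from the published grid itself: at k = 2 the risk-scale
excess equals the baseline x exactly (2.17% at 15 years), whereas
proportional-hazards scaling S^k would give 1 − S² ≈ 2.12% total risk
at the same point. A hazard-ratio variant (`model="hazard-ratio"` in
`scale_survival_curve`) is provided for sensitivity analysis and documented
as not the study model. Whether the source analysis scaled the whole curve
pointwise or only the landmarks is not stated; pointwise scaling is assumed,
as it reproduces every landmark number and yields well-defined scaled
curves.

Scaled-curve variance uses the delta method on the risk scale (k² · Var S);
confidence bounds are mapped through the same affine transform and clipped
to [0, 1]. No confidence intervals are reported for excess risk or NNH.

## Baseline risk: two modes

Two sources of the baseline x are kept strictly separate:

* **printed-baselines** — x supplied directly (default: the published
  values 0.14% / 0.99% / 2.17% at 5/10/15 years for PCSM). All grid
  arithmetic is done in `decimal` at full precision, so reported cells are
  exact and the mode touches no random state. This is the reproduction
  surface. The published 5-year survival landmark (99.9%) and the published
  5-year baseline risk (x = 0.14%) disagree at the printed precision; the x
  values are authoritative for scenario arithmetic, the landmarks for
  generator calibration.
* **full-pipeline** — x read off a Kaplan–Meier fit of a (synthetic)
  cohort at the landmark horizons, subject to Monte-Carlo error.

For the secondary endpoints (CRPC, metastasis) no baseline-x column was
published; their default baselines are the complements of the published
survival landmarks (e.g. 3.40% for CRPC at 15 years). The source text quotes
slightly different 15-year excess values at k = 2 (3.35% for CRPC, 3.47% for
metastasis), which imply unrounded internal baselines that were never
printed; the package reports values computed from the printed landmarks and
does not chase those two numbers.

## Rounding

Reported percentages use round-half-up at 2 decimals and NNH uses
round-half-up to the nearest integer, both on `decimal` representations —
binary floats misround midpoint cells such as 0.105 → 0.11 and 1.085 → 1.09.
Under this rule 11 of the 12 published NNH cells reproduce; the 10-year/1.75×
cell computes to 1/0.007425 = 134.68 → 135 against a printed 134. No single
rounding convention yields 134 while also yielding 2857, 1429 and 404, so the
cell is treated as a documented inconsistency in the source table and the
package reports 135.

## Kaplan–Meier estimation

The product-limit estimator, Greenwood variance and complementary log-log
confidence intervals are implemented directly (vectorised over distinct
event times): S(t) = Π_{t_i ≤ t} (1 − d_i/n_i), Var S = S² Σ d_i/(n_i(n_i −
d_i)), bounds S^{exp(±z·se)} with se = √Var / (S·|ln S|). At tied times
events precede censorings. The cloglog transform keeps bounds inside [0, 1];
the source does not state its interval method, and its intervals are not a
reproduction target (they would require the original data). When S reaches 0
the Greenwood sum diverges; the variance is set to 0 there, matching the
degenerate limit. Life-table (actuarial) estimation, log-rank tests, Cox
regression, competing-risk estimators and left truncation are out of scope.

Landmark evaluation is right-continuous step evaluation; beyond the largest
observed time the last value is carried forward with an
`ExtrapolationWarning` rather than an error, because a 15-year landmark over
a cohort with ~6-year median potential follow-up necessarily extrapolates.

## Synthetic cohort generator

The generator emulates the structure of the source registry cohort so the
pipeline is testable end to end without the (undeposited) data. What it
matches:

* **Survival landmarks.** Event times are piecewise-exponential, calibrated
  so the survival function passes exactly through the published 5/10/15-year
  landmarks per endpoint (closed-form inversion; rate of the last interval
  extended beyond 15 years). Endpoints are sampled independently per
  subject: the published summaries are marginal per endpoint, no joint
  structure is specified, and the downstream analysis consumes only the
  marginals.
* **Censoring.** Surgery years 1988–2017 with quartiles (2008, 2011, 2014),
  drawn from a piecewise-uniform distribution putting a quarter of the mass
  between consecutive quartile knots — this reproduces the printed
  surgery-year quartiles exactly and hence a median administrative
  (potential) follow-up of 6 years. A triangular accrual model is also
  supported (3-tuple `accrual_years`), but no triangular distribution on
  1988–2017 can place the median at 2011, which is why it is not the
  default. Administrative censoring truncates follow-up at the 2017 study
  close; an optional exponential dropout (default 0.01/year, a typical
  low loss-to-follow-up rate for a VA registry) adds non-administrative
  censoring. The source describes no follow-up distribution, so this is a
  plausible reconstruction, not a fit.
* **Demographics.** Cosmetic only (estimation never reads them): age normal
  and PSA log-normal matched to printed medians/quartiles, race 31% black,
  grade group 2 in 77%, stage T1/T2a/T2b/T2c at 66/27/4/3%. Every
  grade-group-1 subject is forced to carry a second intermediate-risk
  feature (PSA folded into 10–20 ng/mL, or stage reassigned to T2b/T2c in
  the printed 33:31 proportion), so all rows satisfy the FIR definition.

One integer seed drives everything through `numpy` `SeedSequence` spawning,
with one sub-stream per component (demographics, censoring, each endpoint in
sorted order), so runs are bit-reproducible and adding an endpoint never
perturbs the others.

What the generator does **not** emulate: correlation between endpoints or
with other-cause death, covariate-dependent hazards, calendar-time trends in
case mix, or the event-count granularity of the real cohort. Passing tests
therefore validate the estimation and scaling machinery under the stated
marginal structure — not the clinical conclusions on real data.

## Problem sizes and tolerances

Calibration round-trips are checked to 1e−12; the estimator is checked
against a brute-force product-limit enumeration to 1e−12 on 500 random
small cohorts (n ≤ 30, heavy ties, censoring) and against lifelines on a
moderate cohort. Monte-Carlo recovery of the 15-year landmark uses 200,000
uncensored draws, for a binomial standard error of ≈0.033% (the check allows
3 SEs); generator marginal checks on n = 920 use 4 binomial SEs. Scenario
grids are exact, so their tests assert string equality of the rounded cells.

## Known limitations

* The hypothetical cohort shares everything with the reference cohort except
  a constant risk multiplier; time-varying multipliers are not modelled.
* NNH here is the reciprocal of a modelled excess, not an empirical contrast
  between observed arms, and carries no uncertainty interval.
* The piecewise-exponential stand-in interpolates landmarks with constant
  hazard between them; any within-interval hazard shape is invisible to it.
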
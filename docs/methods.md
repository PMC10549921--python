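# Methods

## Scope and data model

`thyrobmd` analyses a biomonitoring cohort in which each subject carries a
blood nickel concentration (µg/L), a serum thyroid panel (TSH in µIU/ml,
fT4 and fT3 in pmol/L, T4 and T3 in nmol/L), sex, age and a health-group
label. Any hormone determination may be missing. The analysis treats the
seven endpoints TSH, fT4, fT3, T4, T3, SPINA-GT and SPINA-GD symmetrically
once the two SPINA parameters have been derived.

## SPINA homeostasis parameters

The structure-parameter inference approach summarises the
hypothalamus–pituitary–thyroid feedback loop by two algebraic parameters:

```
GT = beta_T (D_T + [TSH]) (1 + K41 [TBG] + K42 [TBPA]) [fT4] / (alpha_T [TSH])
GD = beta_31 (K_M1 + [fT4]) (1 + K30 [TBG]) [fT3] / (alpha_31 [fT4])
```

Constants (defaults, configurable): alpha_T = 0.1 /L, beta_T = 1.1e-6 /s,
D_T = 2.75 mIU/L, K41 = 2e10 L/mol, K42 = 2e8 L/mol, alpha_31 = 0.026 /L,
beta_31 = 8e-6 /s, K_M1 = 500 nmol/L, K30 = 2e9 L/mol, [TBG] = 300 nmol/L,
[TBPA] = 4.5 µmol/L. A correction coefficient beta = 0.1345 of the
logarithmic model variant is stored for completeness but enters neither
equation.

Unit convention: µIU/ml is treated as numerically identical to mIU/L; all
dissociation-constant products are evaluated in mol/L, making the binding
factors dimensionless (1 + K41·[TBG] + K42·[TBPA] = 6901 and
1 + K30·[TBG] = 601 at defaults); GT is returned in pmol/s and GD in
nmol/s. This convention reproduces the clinical reference ranges
(GT 1.4–8.7 pmol/s, GD 20–60 nmol/s) for central in-range panels — note
that extreme corners of the full in-range hormone box (e.g. TSH at 0.27
with fT4 at 22) can legitimately fall outside the GT range.

GT is undefined for TSH ≤ 0 and GD for fT4 ≤ 0; at the panel level such
inputs propagate as missing rather than raising, because a cohort run must
tolerate incomplete records.

## Quantalization

Each endpoint value is mapped to 0 (inside its reference range) or 1
(outside). Ranges are closed intervals — a value exactly on a bound counts
as in-range, the usual clinical reading of a printed range. Missing values
are dropped per endpoint (not listwise), so endpoint totals differ; the
counts table reports n_in / n_out / n_missing per endpoint and stratum and
always satisfies n_in + n_out + n_missing = stratum size. Values below the
analytical limit of detection are used as reported; no imputation.

## Descriptive statistics and correlation

Quantiles use linear interpolation between order statistics (the "type 7"
convention); the convention used by the original commercial software is
unstated, so small differences at the second decimal are expected.
Exceedance is the percentage of subjects strictly above a threshold.

Spearman correlation is computed on average ranks over pairwise-complete
observations. Two-sided p-values use the t approximation
`t = r sqrt((n−2)/(1−r²))` on n−2 degrees of freedom (an exact permutation
oracle backs this in the tests at small n). The 95% CI applies the Fisher
z-transform with the Fieller-corrected standard error `sqrt(1.06/(n−3))`.
No multiple-testing correction is applied across the endpoint × stratum
grid, matching the screening character of the analysis.

## Quantal benchmark-dose estimation

**Model suite.** Seven classical quantal families (logistic, probit,
log-logistic, log-probit, Weibull, gamma, two-stage), parameterised as in
`families.py`. Background probabilities `a` are bounded in [0, 1−1e−6];
shape-type parameters (Weibull/gamma shape `c`, log-dose spread `sigma`)
have a positive floor of 1e−2 and a cap of 18, because unconstrained shapes
make the low-dose extra-risk inversion ill-posed. Linear-dose slopes
(logistic/probit `beta`, two-stage `b`, `c`) may reach zero so that every
family can collapse exactly to a dose-independent response. Location and
scale bounds are tied to the observed dose range, which makes every fitted
quantity equivariant under a rescaling of the dose axis.

**Fitting.** Individual-level Bernoulli likelihood (each subject its own
dose — appropriate for a biomonitoring design where every subject has a
distinct exposure), maximised by L-BFGS-B with analytic gradients on the
unit-box reparameterisation of the constraint box. Full-data fits use a
data-driven heuristic start plus 10 seeded Latin-hypercube starts;
convergence is flagged honestly and non-converged fits are excluded from
averaging. Datasets with a single outcome class collapse to the analytic
background-only fit and are flagged degenerate.

**Averaging and inversion.** Akaike weights
`w_k = exp(−(AIC_k − min AIC)/2) / Σ exp(−(AIC_j − min AIC)/2)` with
`AIC = 2k − 2 loglik`. The model-averaged curve `P̂(d) = Σ w_k P_k(d)` is
inverted at extra risk `P(BMD) = P0 + BMR (1 − P0)` (BMR = 0.10 by
default; extra risk is the standard convention for quantal data) by
bisection on log-dose to a relative tolerance of 1e−6, inside the window
[min dose × 1e−6, max dose × 1e6]. A curve that never crosses the
benchmark level inside the window is recorded as censored at the
corresponding bound rather than raising — near-flat dose-response curves
are an expected outcome on human data, and absurdly wide intervals must be
visible, not hidden.

**Bootstrap confidence limits.** Parametric bootstrap in the
Wheeler–Bailer style: outcomes are redrawn as Bernoulli(P̂(d_i)) at the
observed doses, the full suite is refitted (warm-started from the
original parameter estimates plus the heuristic start), weights are
recomputed and the refitted averaged curve re-inverted; BMDL and BMDU are
the 5th and 95th percentiles of the 200 bootstrap BMDs, read as one-sided
95% confidence limits. Censored iterations enter the percentile
computation at the window bound and are counted; a result with more than
50% censored or non-converged iterations is flagged unreliable. Every run
is fully determined by its seed. The BMDL–BMDU interval is flagged
*narrow* when BMDU/BMDL < 10, the conventional reliability screen.

**Covariates.** Sex ("covariate gender") is handled by stratified runs —
men, women, entire population — and health status by additional
healthy/unhealthy strata for the SPINA endpoints. Joint
covariate-parameterised fitting is intentionally out of scope; stratified
runs reproduce the reported table layout and keep each fit interpretable.

**Not-estimable cells.** A stratum × endpoint cell with fewer than 10
usable subjects or a single outcome class is reported explicitly as
`not_estimable` and the run continues.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
with defaults fixed at the study conditions:

- 217 men, 218 women, ages 18–94 (rounded normal around 50), healthy
  fraction 136/435;
- blood nickel per sex: log-normal parameterised by the observed median
  and p75/p25 quartile ratio (men median 8.278, quartiles 2.902/14.20;
  women 7.609, 1.771/15.70 µg/L). A two-parameter log-normal cannot honour
  three asymmetric quartiles simultaneously, so the calibration contract
  is the median and the quartile ratio;
- hormones per sex: TSH log-normal (right-skewed), the iodothyronines
  normal truncated at zero, each matched to the observed median and IQR;
- per-endpoint missingness at the rates implied by the observed
  in+out-of-range row totals versus the stratum sizes (e.g. male fT4
  32/217); SPINA missingness then follows mechanically from the hormone
  missingness;
- hormones are drawn independently of nickel and of each other unless a
  dose-response link is configured.

A **link** ties one measured hormone's out-of-range probability to nickel
through a quantal family (log-logistic, log-probit or Weibull) specified by
background rate, true BMD at a given BMR, and log-dose spread; the true
BMD is available in closed form for recovery tests. The subject's
indicator is drawn first from the link, and the continuous hormone value is
then drawn from its marginal truncated to the corresponding region
(inverse-CDF sampling, tails weighted by mass), keeping continuous values
and indicators mutually consistent. Links are restricted to the five
measured hormones; the SPINA endpoints inherit dose dependence indirectly
through fT4/fT3, exactly as they would in real data.

What the generator does **not** emulate: the true joint dependence
structure of nickel and the hormone panel (only marginals are matched),
assay noise and limit-of-detection artefacts, age or health-group effects
on hormone levels, and the heavy lower tail of the real nickel
distribution (the log-normal implied p25 for men is 3.74 µg/L against the
observed 2.902). Passing tests therefore demonstrate correctness of the
estimation machinery under a known truth, not distributional fidelity of
any particular real cohort.

## Simulation study sizes and numerical choices

- Bootstrap: 200 iterations (the analysis setting); BMDL/BMDU as
  5th/95th percentiles with linear interpolation.
- Coverage study: log-logistic link with true BMD10 = 5 µg/L, background
  0.05, log-dose spread 1.0; doses log-normal (median 8 µg/L, log-sd 1.2,
  resembling the male nickel distribution); n = 400 subjects per
  replicate, 100 replicates. Nominal two-sided coverage of the 5th–95th
  percentile interval is 90%; the test accepts 82–96% (binomial error at
  100 replicates).
- Likelihood optimisation: ftol 1e−13 (full fits) / 1e−10 (bootstrap
  refits), gradient tolerance 1e−9, at most 400 iterations per start.
- Probabilities are clipped to [1e−12, 1 − 1e−12] inside the likelihood;
  exponents are clipped at ±700 to avoid overflow in saturating curves.
- Per-cell seeds in the pipeline derive deterministically from the run
  seed and the CRC-32 of the endpoint and stratum labels, so re-running a
  single cell reproduces the full-run numbers bit for bit.

## Known limitations

- Exact numerical agreement with other benchmark-dose packages is not a
  goal: the suite composition, constraint boxes and bootstrap internals of
  commercial/GUI tools are not published at bit level, and near-flat
  dose-response data amplify such differences into orders of magnitude at
  the interval endpoints. Order-of-magnitude agreement is the realistic
  posture for interval limits on human data.
- Stratified fitting discards information relative to a joint model with a
  sex covariate; with ~200 subjects per stratum this is a deliberate
  robustness/simplicity trade-off.
- The Spearman CI convention (Fieller-corrected Fisher z) is one of
  several in circulation; third-party software may differ in the third
  decimal.
- BMDL from percentile bootstrap can be anti-conservative when the
  averaged curve is nearly flat; the censoring counts and the unreliable
  flag are the intended guard rails, and wide intervals should be read as
  "no usable dose-response signal", not as a precise estimate.
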
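# Methods

This note documents the statistical model, the numerical choices, and the
synthetic data that back the `overtreat` package, in enough detail to
judge what its tests do and do not establish.

## Estimand and identification

The study population is all women diagnosed with in situ or invasive
breast cancer at age ≥ 40 in one calendar year in a registry catchment.
Write M for treatment by total mastectomy (simple or modified radical) as
the most extensive first-course surgery, V for the latent event that the
case was overdiagnosed, and X for the recorded case characteristics. The
estimand is Pr(M, V), the fraction of the study population that underwent
mastectomy for an overdiagnosed cancer:

    Pr(M, V) = Σᵢ Pr(M | V, X = xᵢ) · Pr(V | X = xᵢ) · Pr(X = xᵢ).

Three pieces of information partially identify it:

* **(A) Rule-out criteria.** Aggressive/advanced characteristics (≥2
  invaded nodes, ≥4 cm diameter, fascia/muscle/chest-wall invasion, skin
  ulceration or adjacent-skin invasion, distant metastasis) are
  incompatible with overdiagnosis; such cases are excluded from the
  candidate overdiagnosed set, so Pr(V | X) = 0 for them. The criteria are
  deliberately lax in the other direction — one positive node or a
  2.0–3.9 cm tumor does *not* exclude, and an unknown value never
  excludes — because misclassifying an overdiagnosis as a
  non-overdiagnosis would invalidate the bounds, while the converse merely
  widens them. Stage is never tested directly: stage-IV disease is caught
  by its metastasis flag, and stage-NA cases stay eligible.
* **(B) An overdiagnosis proportion q** for the whole study population,
  treated as a scenario parameter. Its ceiling comes from the incidence
  trend: if non-overdiagnosed incidence was constant or rising since the
  pre-screening era and screening drives essentially all overdiagnosis,
  then q ≤ 1 − rate_early/rate_late on age-standardized rates
  (`q_max_from_incidence`). Direct age standardization is the
  weight-normalized mean over a user-supplied standard population
  (`age_standardize`); pre-standardized rates can be supplied directly.
* **(C) Propensities Pr(M | X = xᵢ)** from a regression model (below);
  Pr(X = xᵢ) is the empirical distribution, 1/n per observed case.

The key **exchangeability assumption** is Pr(M | V, X) = Pr(M | ¬V, X):
since no clinician can identify an overdiagnosed case at treatment time,
treatment probability cannot depend on V given X. Under it the estimand
is linear in the unknown weights wᵢ = Pr(V | X = xᵢ) ∈ [0, 1], which must
sum to m = q·n_total over the eligible cases. The extrema of a linear
functional over that simplex slice are attained by "filling up" the
overdiagnosed group with the smallest (lower bound) or largest (upper
bound) propensities.

### Fill-up implementation

`bound_overtreatment` sorts the eligible propensities and takes a prefix
sum of length m; when m is fractional the marginal case enters with
weight frac(m). This is exactly the LP relaxation (verified against
`scipy.optimize.linprog` and against exhaustive subset enumeration in the
tests), makes the curve continuous and 1-Lipschitz in q, and renders
tie-breaking between equal propensities irrelevant to the value; with
n in the thousands the difference from the 0/1 assignment is O(1/n).
Everything is a large-sample plug-in: no sampling CI is attached to the
bounds — identification width dominates sampling error at registry scale,
and uncertainty is explored through the criteria sweep and the sensitivity
analysis instead. Reported headline intervals are rounded **outward** to
whole percents (floor/ceil), the conservative reporting direction.

Rescaling q from the full population to the eligible subset
(`rescale_q = q·n_total/n_eligible`) fails loudly when the implied
eligible-subset fraction exceeds 1 — the assumed amount of overdiagnosis
is then inconsistent with the rule-out criteria.

## Propensity model

Default family: random forest, 2,500 trees, sqrt(#variables) tried per
split, Gini splitting, leaf size 1, untuned — with **out-of-bag**
predictions so no case is scored by trees that trained on it. A cap of 25
random splits for multi-level variables is carried in the model
descriptor for provenance, but the scikit-learn backend splits one-hot
indicators exhaustively, so it is inert here. Non-bagged families
(logistic regression) are **cross-fitted** with K = 5 shuffled folds;
fold membership is drawn independently of outcomes (unstratified), which
is what makes the honesty property exactly testable: permuting a held-out
fold's outcomes cannot change that fold's predictions. Categorical
covariates are one-hot encoded with "NA" as an explicit level — missing
values are never imputed, since missingness can be informative of
surgical choice — and levels unseen at fit time map to "NA" at predict
time. Diagnostics are the Brier score, the c-statistic (ROC AUC, ties
half-counted), and a quantile-binned calibration table. The model is fit
on the full cohort; the bounds consume the eligible subset's estimates.

## Omitted-variable sensitivity

Unrecorded determinants of mastectomy (symptoms, family history,
screening history, post-lumpectomy completion) and informative
missingness could make the true Pr(M | X, omitted) more dispersed than
the fitted Pr(M | X) even if the fit is calibrated. The sensitivity
analysis, a reconstruction of this class of procedure, lets an adversary
replace each eligible propensity pᵢ by any p*ᵢ with
|logit p*ᵢ − logit pᵢ| ≤ log Λ subject to Σp* = Σp, then recomputes the
fill-up bound on p*, maximizing the upper and minimizing the lower bound.
The two constraints encode the two defining properties — predictions are
not systematically biased (calibration in the large, the weakest and
hence most conservative reading of "maintains calibration"), but their
variance may be understated by up to odds ratio Λ per case. Λ = 1
reduces exactly to the main analysis; intervals are nested and monotone
in Λ.

Because a common logit shift preserves the ordering of the per-case
feasible boxes, the optimum has a water-filling form: push the m counted
cases to their caps, funded by pushing uncounted cases down, with at most
one case strictly interior; priorities follow the marginal value of a
unit of mass (1 for fully counted cases, frac for the marginal case, 0
otherwise). The implementation is verified against an exhaustive
support-enumeration + LP oracle on small instances. A structural
consequence: the widening is concave in Λ and saturates at the
mass-transport limit min(m, Σp)/n_total, so equal multiplicative steps in
Λ buy progressively less widening — moderate Λ (≈5) already captures most
of the worst case. Whether the original procedure perturbs probabilities
case-wise or redistributes within strata is not documented; the contract
implemented here is chosen to satisfy the two stated properties and is
flagged as a reconstruction, not asserted as identical.

## Descriptive statistics

Characteristics tables report per-level case counts, mastectomy
percentages, and univariate risk ratios by unconditional maximum
likelihood with log-Wald 95% CIs,
exp(log RR ± 1.96·√(1/a − 1/n₁ + 1/b − 1/n₀)) — the convention that
reproduces published table rows from their printed cells at one decimal.
Trends use the Cochran–Armitage chi-square test (1 df) with consecutive
integer scores (no scores are standard for these tables; integers are the
default convention), "NA" excluded from trends but reported as its own RR
row; with two levels the statistic equals the uncorrected Pearson
chi-square, and the suite also checks it against a permutation oracle.

## Synthetic data: what it emulates and what it does not

`overtreat.simulate` draws registry-like cohorts: age, behavior (≈21% in
situ), histology, tumor size (lognormal by behavior, 12% missing), nodal
status, grade, receptor status, local-invasion and metastasis flags, a
coarse derived AJCC stage, nine catchment regions, race, and a few extra
categorical covariates. Surgery is assigned by a logistic model whose
intercept is re-solved on each generated cohort so the marginal
mastectomy rate is exactly the scenario target (33.8% by default), with
log-odds rising in tumor size, nodes, grade and HER2 positivity and
falling with age — qualitatively matching published margins without
claiming replication. The latent V is drawn from a second logistic model
concentrated on early-stage patterns and masked to zero wherever a
rule-out characteristic is present, so generated overdiagnoses are always
eligible. Two dials matter for validation:

* `exchangeability_violation_delta` adds delta to the mastectomy
  log-odds of overdiagnosed cases; delta = 0 (the default) makes the key
  assumption hold *exactly* by construction.
* `omitted_covariate` injects a latent binary shifter of the mastectomy
  log-odds (independent of X) that is not recorded in the cohort,
  giving a known conditional odds ratio for validating the sensitivity
  analysis; the oracle propensity then reports the X-marginal.

Each covariate draws from its own seeded substream (CRC-keyed off the
global seed), so extending the schema does not perturb existing
covariates and every artifact is reproducible from one integer.

What the generator does **not** emulate: longitudinal screening
histories, multiple primaries per patient (input is one row per patient;
first-primary selection is upstream of the reader), registry coding
quirks, correlated missingness across fields, or calibration of joint
covariate distributions to any real registry. Passing tests therefore
demonstrate the *statistical machinery* — honesty of the propensities,
validity and sharpness of the bounds under the stated assumptions,
robustness claims — on a realistic-shaped cohort; they do not reproduce
any real-registry empirical bound, which requires the actual case
listings.

## Problem sizes and defaults

The shipped scenarios are `small` (n = 1,500; demos and smoke runs),
`default` (n = 6,000; the analysis scenario used for robustness and sweep
checks), and `registry_scale` (n = 26,017). Parameter-recovery checks use
200 replicates of n = 5,000 with cross-fitted logistic propensities —
correctly specified up to binning, hence a sharp test of interval
validity — with forest robustness checked separately by halving/doubling
tree counts (150/300/600 at n = 6,000), where the bounds move by well
under one percentage point. The default q grid spans 0 to the incidence
ceiling (capped at feasibility) in 38 points; the default sensitivity
sweep uses Λ ∈ {1, 5, 25}.

## Numerical conventions and edge cases

* Propensities are clipped to [0, 1] after fitting; fill-up feasibility
  allows a 1e-9 slack before declaring q inconsistent.
* Degenerate propensities 0 and 1 are fixed points of any odds-ratio
  perturbation.
* Outward rounding snaps 1e-9 float fuzz before floor/ceil so an exact
  integer endpoint stays fixed.
* The read path rejects duplicate case ids and malformed fields with the
  row and field named; under-age and unknown-surgery rows are dropped and
  tallied, mirroring standard eligibility cleaning.
* Run reports round floats to 12 digits and serialize with sorted keys,
  making repeat runs byte-identical.

## Known limitations

The bounds carry no information about where inside the interval the truth
lies, apply only to the study population that generated the case listing,
and say nothing about individual patients. The rule-out criteria can
misclassify genuinely overdiagnosed cases with advanced features among
the very elderly, biasing the bounds downward there. The sensitivity
mechanism is a documented reconstruction. The incidence-ceiling argument
assumes negligible pre-screening-era overdiagnosis and non-decreasing
background incidence; if either fails, q_max (and with it the headline
upper bound) is understated.
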
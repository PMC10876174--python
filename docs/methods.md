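# Methods

## Classification rules

All four classifiers are pure functions of a per-case record; every
threshold is configuration (`acnscore.rules.ScoringRules`), shipped with
the published defaults, so variant cutoffs can be explored without
touching code. Cutoffs are strict inequalities as conventionally
printed (> 400 g, > 10.5 cm, > 15/20 HPF, > 5/50 HPF) except the Ki67
cutoff, which is inclusive (≥ 15%).

**Wieneke criteria.** Nine binary criteria counted; < 3 benign, = 3
indeterminate, > 3 malignant. With partially missing inputs the exact
score may be undefined while the *class* is still decidable (e.g. four
satisfied criteria force malignant whatever the missing items resolve
to); `wieneke_class` therefore brackets the attainable score and emits
the class whenever the bracket falls in one band. This maximizes usable
cases under the per-analysis-deletion missing-data policy (below).

**Modified Wieneke score.** The 5-item microscopic score is
well-defined; the published description of the second step is not a
complete rule table. The implemented two-step rule — unfavorable at
score ≥ 3, favorable at ≤ 1, Ki67 ≥ 15% deciding a score of 2 — is a
reconstruction, marked provisional and overridable through the rules
config. Analyses that depend on the mWC should be read with that caveat.

**Reticulin algorithm.** Step 1 is any framework disruption: the
category taxonomy is intact / quantitative (fiber loss over extensive
areas) / qualitative (frayed, irregular fibers with preserved overall
architecture) / both, and every non-intact category satisfies step 1 —
pediatric series report malignant calls among qualitative-only
alterations, so qualitative is not treated as a lesser state. Step 2 is
necrosis OR venous invasion OR mitoses above the variant cutoff. An
intact framework short-circuits to benign regardless of the other
features. The record keeps a single `vascular_invasion` field used both
as the Wieneke "venous invasion" criterion and the RA criterion; the
sources do not distinguish them, and the conflation is deliberate and
documented here rather than hidden.

**Mitotic counts.** Counts are stored per reported denominator (50 HPF
Weiss convention, 20 HPF Wieneke convention) and compared only against
cutoffs over the same denominator. Cross-denominator rescaling is
refused by default — HPF area and counting protocol differ between
conventions, so 10/50 HPF is *not* 4/20 HPF — and available only via an
explicit `allow_mitotic_rescale` flag that warns.

**Missing data.** Any case lacking a field required by a given score is
excluded from that score's analysis (per-analysis deletion), mirroring
the varying Ns of published feature tables. Validation is total and
returns findings rather than raising, so a cohort with problems can be
triaged in one pass.

## Agreement statistics

Cohen's κ = (p₀ − pₑ)/(1 − pₑ) with the simple large-sample standard
error √(p₀(1−p₀)) / ((1−pₑ)√n) and a ±1.96·SE interval. This SE, not
the full Fleiss–Cohen–Everitt variance, reproduces the published
interval for the pRA × aRA table exactly at two decimals, so it is
taken to be what the original analysis computed; tests cross-check the
κ point estimate against statsmodels' independent implementation.
Cramér's V uses the plain Pearson χ² (no Yates continuity correction,
no bias correction), which reproduces the three published values at two
decimals. The three-level Wieneke class is treated as nominal in V.
Printed-precision comparisons round half away from zero; the one
exception is the qualitative/quantitative/both split within altered
cases, whose printed triple (22/73/5) sums to 100 and is evidently
largest-remainder rounded (3/67 = 4.48% prints as 5).

**Nesting reconstruction.** The pRA × aRA joint table was not printed,
but because the pediatric mitotic criterion is strictly stronger,
pRA-malignant ⇒ aRA-malignant, the cell (pRA-malignant, aRA-benign) is
zero and the published marginals (25/34 and 29/30 over n = 59) force
the unique joint table [[25, 4], [0, 30]]. `reconstruct_nested_2x2`
implements exactly this argument and rejects infeasible marginals.

## Outcome models

Survival analyses default to event = died of disease, censoring
complete remission and alive-with-disease at last follow-up; the
logistic outcome defaults to the composite unfavorable = AWD or DOD.
Both are configurable because validation studies rarely state the
coding. Kaplan–Meier and the log-rank test come from lifelines; the Cox
model uses statsmodels `PHReg` with Breslow tie handling (Efron
available), matching the default of the commercial software such
studies typically use. AIC = 2k − 2·log(partial)likelihood with k the
number of estimated coefficients; class predictors are one-hot encoded
against the most benign level, and the indeterminate Wieneke class is
kept as its own level. AUC is the Mann–Whitney statistic of fitted
probabilities with midrank ties. Monotone partial likelihood (all
events in one covariate pattern — common at n ≈ 59 with ~11 deaths) is
reported as a flagged non-converged result with the likelihood value at
the final iterate, which approaches a finite supremum and remains
usable for qualitative AIC comparison; it is never silently dropped.
`compare_scores` evaluates all systems on the identical complete-case
subset so their AICs are comparable.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume;
its defaults are the study conditions, not tuning knobs.

* **Mitotic activity.** One latent per-case rate λ ~ LogNormal(μ, σ)
  with μ = −1.5933, σ = 1.8707, solved by Gauss–Hermite quadrature so
  that P(Poisson(50λ) > 5) = 55/88 and P(Poisson(20λ) > 15) = 22/92,
  the published exceedance fractions. The 20-HPF count is
  Poisson(20λ); the 50-HPF count adds an independent Poisson(30λ)
  increment, so it is marginally Poisson(50λ) while never falling below
  the 20-HPF count — making the two cutoffs coherent case-wise and the
  pRA ⊆ aRA nesting exact in every generated case.
* **Reticulin.** Categorical with probabilities 25:49:15:3 over 92
  (intact : quantitative : qualitative : both).
* **Binary features.** Necrosis, vascular/capsular invasion, atypical
  mitoses, extra-adrenal extension and vena cava invasion follow
  logistic models with log-odds couplings (≈ 1–1.6) to
  quantitative-type alteration and to a high latent mitotic rate
  (λ > 0.75/HPF), so malignant-pattern features co-occur; intercepts
  are solved numerically so each marginal prevalence equals its target
  exactly (43/92 necrosis, 28/92 vascular invasion, 17/87 capsular,
  31/87 atypical). Extra-adrenal extension (0.12) and vena cava
  invasion (0.08) are not tabulated in the source and use
  field-plausible defaults. The coupling magnitudes themselves are
  unconstrained by published tables and are stated in the spec object,
  not hidden in code.
* **Survival.** Exponential in two strata: hazard 0.0095/month for
  cases with the pediatric malignant pattern (altered reticulin plus at
  least one criterion at the > 15/20 cutoff) vs 0.0008/month otherwise
  (true log HR 2.474). Administrative censoring is uniform on
  (0, 110] months; the horizon exceeds twice the 48-month target
  because being censored conditions on surviving past the censor time,
  which skews observed censored follow-up downward — at 110 the
  observed median follow-up is ≈ 48 months. Censored cases are labelled
  AWD with probability 0.42 (malignant pattern) or 0.04, CR otherwise,
  giving an outcome mix near 39 CR : 9 AWD : 11 DOD per 59
  outcome-known cases. A coarser two-stratum hazard (rather than a full
  reticulin × criteria grid) suffices because the published
  outcome-by-system tables put every death in the pRA-malignant column.
* **The rest.** Weight/size are correlated bivariate lognormal (medians
  60 g / 6 cm, ρ = 0.8 on logs); Ki67 lognormal (median 6%, σ solved so
  P(Ki67 > 15%) = 15/77, clipped at 100); age lognormal with median 60
  months clipped to [1, 216]; P(male) = 0.375; stage probabilities
  0.50/0.295/0.09/0.115. Per-field missingness matches the published
  missing-data columns (weight 47/92, outcome 33/92, mitoses/50 HPF
  4/92, ...); outcomes are generated from *pre-missingness* features,
  so missingness is non-informative by construction.

What the generator does **not** emulate: observer disagreement,
within-tumor heterogeneity, correlation of weight/size/Ki67 with
malignancy (Ki67 and tumor bulk are drawn independently of the hazard
stratum), the bimodal pediatric age distribution, stage–outcome
dependence, and real missingness mechanisms (all missingness is
completely at random). Passing tests on synthetic data therefore
demonstrate the correctness and calibration of the pipeline, not
clinical performance on real cohorts.

## Reference cohort reconstruction

`build_reference_cohort` deterministically rebuilds a 59-case cohort
from the published classification cross-tabulations. The published
two-way tables (system × system, system × reticulin, × outcome,
× stage, × sex) admit a consistent three-way assignment, which the
builder realizes with minimal feature combinations forcing each
intended class (e.g. an aRA-only malignant case gets 10/50 and 4/20 HPF
from one latent rate of 0.2/HPF). Scoring the reconstruction reproduces
every one of those published tables exactly — this is checked
per-table in the test suite. Not matched, because the published tables
do not constrain them: per-feature row counts (e.g. ">5 mitosis/50 HPF"
by mWC class), median ages/weights/sizes, and follow-up times, which
are nominal placeholders (48/36/24 months by outcome); no survival
statistic is computed from them.

## Numerical choices and problem sizes

Intercept and quadrature solves use scipy (`brentq` to 1e-12;
degree-200 Gauss–Hermite). All stochastic draws flow from one
`numpy.random.default_rng` per cohort; study-level replicate seeds are
drawn from a single seeded generator, so every result is reproducible
end-to-end from one integer. The replicated studies use 100 replicates
at n = 500 (hazard-ratio recovery; non-converged replicates count as
coverage failures) and 100 replicates at n = 92 (AIC ordering; ties for
the minimum AIC count as attaining it), and the large-n calibration
checks use cohorts of 20 000–50 000 — sizes at which the binomial
tolerance bands are decisive while the full suite stays fast.

## Known limitations

* The mWC second step is a reconstruction (above); published mWC
  agreement values cannot be verified without the original rule table.
* The κ confidence interval uses the simple SE; for tables far from
  the nested-2×2 structure the Fleiss–Cohen–Everitt variance can
  differ noticeably.
* Separation-flagged Cox/logistic fits report the boundary likelihood;
  coefficient values and CIs from flagged fits should not be
  interpreted.
* Cross-denominator mitotic rescaling, even when explicitly enabled,
  assumes equal field area, which is generally false between the Weiss
  and Wieneke conventions.
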
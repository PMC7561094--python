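# Methods

This note records the models implemented, the defaults chosen where the
design was genuinely open, and what the synthetic experiments can and
cannot establish.

## Risk-score engines

The scoring engine evaluates a generic logistic specification: an
intercept, a dictionary of *derived variables* (category recodes, numeric
bands, flag tests, additive integer scores) and a list of coefficient
terms. The three shipped specifications are transcriptions of the original
publications, carried as JSON with provenance strings, so a band edit or a
re-transcription never touches code:

* **SORT** (`sort_v1`): six variable groups — ASA-PS (III/IV/V vs I–II),
  NCEPOD urgency (expedited/urgent/immediate vs elective), high-risk
  specialty flag (gastrointestinal, thoracic/cardiac, vascular), Xmajor/
  complex severity, any active malignancy, and age band (65–79, ≥80 vs
  <65); intercept −7.366.
* **P-POSSUM** (`ppossum_v1`): `logit = −9.065 + 0.1692·PS + 0.1550·OS`,
  where PS sums twelve physiology items and OS six operative items, each
  scoring 1/2/4/8. Band boundaries live in the JSON. Two items are not
  directly observed and are derived from comorbidity flags: cardiac signs
  (cardiac failure → 4, coronary artery disease → 2, else 1) and
  respiratory signs (COPD → 2, else 1). The banding uses contiguous
  half-open intervals so every real value scores.
* **SRS** (`srs_v1`): `SRS = CEPOD grade + severity grade + ASA-PS`
  (range 3–14), converted to probability by `logit p = 0.84·SRS − 9.81`.

**Expedited urgency** post-dates two of the models. It maps to SORT
natively; to the non-emergency mode-of-surgery band (1 point) in P-POSSUM;
and to the "scheduled" CEPOD grade 2 in SRS. The mappings are declared in
the JSON and overridable.

**Normal-value imputation.** Missing physiology/labs are filled with the
centre of each item's minimum-score band (Na 140 mmol/L, K 4.0 mmol/L,
urea 5.0 mmol/L, Hb 14.0 g/dL, WBC 8.0×10⁹/L, pulse 75 bpm, SBP 120 mmHg,
GCS 15, ECG normal) before scoring — the assumption a clinician makes when
a test was not indicated. By construction imputation can never raise a
POSSUM sub-score above the fully observed normal record; a per-field flag
frame is returned for audit. Complete-case filtering applies *after*
imputation and only to the non-imputable variables.

## The subjective scale and the combined model

The six risk intervals are stored in percent so the printed midpoints
(0.5, 1.75, 3.8, 7.55, 30.05) are float-exact. The open-ended top interval
(">50%") has no defined midpoint; the default is 75% (the arithmetic
midpoint of 50–100), configurable, and is used only where a probability is
needed for the subjective predictor (calibration plotting, NRI, decision
curves) — never inside the combined model, which represents categories as
dummies against the "<1%" reference.

The combined model is unpenalized maximum-likelihood logistic regression
with seven parameters; the SORT term enters in **percent** (the published
slope is per 1% of predicted risk — passing a proportion is the likeliest
unit bug and is pinned by tests at the published coefficients). Separation
or non-convergence raises an error rather than silently regularizing,
because the published coefficient set is the reference surface. A fit
normally requires all six categories to be populated; subgroup analyses
may relax this, building dummies from the observed categories only.

## Validation statistics

* **Calibration / Hosmer–Lemeshow:** deciles of predicted risk (ties kept
  together, so heavily tied predictors yield fewer bins), Wilson 95%
  intervals per bin, lowess-smoothed curve for continuous predictors.
  `HL = Σ (O−E)²/(E(1−E/n))`, referred to χ² with `bins − 2` degrees of
  freedom; the df is reported so the `bins` convention can be re-derived.
  A single-valued predictor returns a flagged degenerate single-bin result.
* **AUROC:** Mann–Whitney with half credit for ties, which equals the
  trapezoidal area under the operating points; for ordinal predictors the
  ROC is the polygon with one vertex per category threshold and the same
  equality holds (asserted internally). Variance by DeLong's structural
  components (midrank formulation), CI by normal approximation.
* **DeLong comparison:** two-sided z-test on the AUROC difference with the
  structural-components covariance; identical predictors report z = 0,
  p = 1. With a single case or control the variance contribution is zero.
* **Continuous NRI:** events component P(up|event) − P(down|event) plus
  non-events component P(down|nonevent) − P(up|nonevent); exact ties count
  in neither direction. SE from the asymptotic multinomial formula.
* **Decision curves:** net benefit `TP/n − (FP/n)·t/(1−t)` with high risk
  defined as `pred ≥ t`; default grid 0.1%–50% in 0.1% steps. Treat-none
  is identically zero; treat-all crosses zero at the event prevalence.
* **Bootstrap optimism:** resample episodes with replacement, refit,
  optimism = mean(metric on bootstrap sample − metric on original cohort);
  corrected = apparent − mean optimism. Failed replicate fits are dropped
  and counted (more than 10% aborts); fewer than 100 successful replicates
  flags the report as low precision. No cluster bootstrap — episodes are
  treated as independent.

## Synthetic cohort generator

The generator emulates a multi-centre adult inpatient surgical cohort:

* **Marginals.** Categorical covariates follow the published cohort mix
  (e.g. elective 53.3%, ASA I 19.7% … ASA V 0.3%, severity and specialty
  shares, comorbidity rates); age follows a piecewise-linear quantile
  function anchored at the published median/IQR (62 [46–73]).
* **Dependence.** Age, ASA-PS, urgency and severity are drawn through a
  Gaussian copula (inverse-CDF transforms keep every marginal exact) with
  a fixed 4×4 correlation matrix (age–ASA 0.45, ASA–urgency 0.25,
  urgency–severity 0.20, remaining pairs 0.10). Independent draws would
  understate how risk concentrates in elderly, sick, emergency,
  major-surgery patients: they yield a true-risk AUROC of ≈0.84, well
  below the externally validated ≈0.90 of the scores being studied. The
  matrix was calibrated once against those published anchors (SORT AUROC
  ≈0.90; SORT median risk 0.4 [0.2–1.6]%) and frozen; `dependence=None`
  restores independent draws. Other covariates are independent apart from
  small clinically motivated conditionals (blood loss rises with severity,
  peritoneal soiling with urgency, labs drift mildly with ASA-PS).
* **Outcome.** True risk is the SORT specification applied to the drawn
  covariates, with the intercept shifted by bisection so the cohort mean
  hits the configured mortality target (default 1.4%). Because the engine
  scores with the *published* intercept while outcomes follow the tuned
  one, the scored models overpredict — reproducing the overprediction/
  HL < 0.001 pattern of real external validations. Setting
  `mortality_target=None` disables tuning, making predictions exactly
  calibrated (used to verify the nominal Hosmer–Lemeshow rejection rate).
* **Clinicians.** The subjective category is `logit(true risk)` perturbed
  by slope 1.0, bias +0.7 logits and Gaussian noise (SD 1.0 logits), then
  binned by the scale intervals. The positive bias makes every category's
  observed mortality fall below its midpoint (overprediction) while
  discrimination stays high (ordinal AUROC ≈0.84–0.87).
* **Assessment methods / missingness.** 21.1% of episodes are flagged as
  assisted by one objective tool (shares per the published usage table);
  blood tests go missing as a block with probability decreasing in ASA-PS
  (relative weights 1.6/1.1/0.55/0.25/0.10), scaled to a 19% cohort rate.
* **Raw mode.** `include_ineligible=True` adds obstetric episodes (13.8%
  of raw, no deaths) and a 1.08% core-variable missingness stream so the
  exclusion cascade has realistic work to do.

Everything is drawn from one `numpy` Generator seeded by the config, so a
fixed config is bit-reproducible.

**What passing tests do and do not show.** The generator reproduces
published *marginals*, the outcome's link to one score (SORT), and
stylized clinician behaviour. It does not model hospital clustering,
country effects, time-varying calibration drift, or the real joint
distribution of comorbidities and physiology — P-POSSUM's physiology
channel in particular carries less signal here than in real data, so its
synthetic AUROC (≈0.79) underestimates its published performance (0.89).
Results on synthetic cohorts validate the *statistical machinery*, not the
clinical ranking of the tools.

## Pipeline conventions

* Exclusion order is frozen (it changes the counts): eligibility flags →
  complete-case → objective-tool carve-out; every count is logged and the
  log's arithmetic is asserted.
* The DeLong comparison involving the combined model uses its apparent
  (in-sample) predictions; the headline AUROC reported for the combined
  model is the optimism-corrected one. Both are in the report.
* The subjective predictor enters NRI and decision curves as its interval
  midpoint probability, and ROC analysis as raw categories (polygon).
* Subgroup runs require at least 20 events (configurable) and relax the
  all-categories requirement of the combined fit.
* Problem sizes in the shipped experiments — 26,502-episode studies,
  200,000-record parameter recovery, B = 200–1,000 bootstrap replicates,
  20-seed calibration repeats at n = 20,000 — were chosen so each check
  has comfortable statistical resolution (3-SE sampling bounds) at
  single-CPU scale.

## Known limitations

* SORT/P-POSSUM/SRS coefficients are transcribed from the original
  publications; fidelity rests on those sources.
* The Hosmer–Lemeshow df convention (`bins − 2`) is the development-style
  one; external-validation practice sometimes uses `bins`.
* The continuous NRI's asymptotic SE ignores the estimation error of a
  *fitted* new model (standard practice, slightly anticonservative).
* The top-category midpoint (75%) is a convention; subjective-predictor
  calibration and NRI values involving category 6 move with it.
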
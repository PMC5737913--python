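# Methods

`medassoc` infers, at the level of an institution's outpatient population,
which medications are used to treat an index condition, and which
comorbidities tilt the choice among the drug classes used to treat it. Its
input is deliberately minimal: a long-format mention table with one row per
(patient, visit, concept), where each concept is a normalized condition or
medication identifier. Producing such a table — NLP over clinical notes,
negation/temporality handling, vocabulary normalization — is upstream and out
of scope here.

## The four-step association procedure

**1. Cohort.** Cases are patients who have ever had the index condition;
controls are everyone else. Each case contributes one uniformly random visit
at which the index condition was recorded; each control one uniformly random
visit. The binary feature vector is the set of concepts (conditions and
medications) mentioned at the selected visit, excluding the index condition
itself. A `feature_window: history` switch instead takes the union over all
visits; the per-visit window is the default because per-visit concept counts
are the natural per-patient quantities in this design, and one visit per
patient avoids weighting patients by their visit counts.

**2. Screen.** Each binary column is tested by its point-biserial (Pearson)
correlation r with the labels; the two-sided p-value comes from
t = r·sqrt((n−2)/(1−r²)) on n−2 df. Columns with p < `alpha_screen`
(default 0.05, deliberately not multiplicity-adjusted — this step only prunes
the feature space) are retained. Zero-variance columns are dropped, and among
columns with identical 0/1 patterns (vocabulary synonyms produce these) one
representative is kept and the group recorded.

**3. Select.** L1-penalized logistic regression over a 100-point log-spaced
penalty grid running from the data-derived null penalty (smallest λ with an
all-zero solution) down to a ratio of 1e−4. Five-fold cross-validation,
stratified by label and seeded, scores each penalty by mean out-of-fold
per-observation binomial deviance with the standard error taken across fold
means. The chosen penalty λ\* is the largest whose mean deviance is within
one standard error of the minimum — the usual 1-SE rule, which trades a
little fit for a sparser, more stable model. (A published description of this
rule that we follow is garbled in its source; we implement the standard
form: within one SE *of the minimum mean CV deviance*.) Covariates are binary
indicators on a common scale, so no standardization is applied by default
(`standardize: true` is available). The intercept is never penalized.

**4. Refit and rank.** The concepts with nonzero coefficients at λ\* are
refit by unpenalized maximum likelihood. Each coefficient is the log adjusted
odds ratio for that concept given all the others; we report exp(β̂), the
two-sided Wald p-value, and the Benjamini–Hochberg adjusted p-value, sorted
by p ascending with ties broken by odds ratio descending (ties occur when p
underflows to 0). Wald rather than likelihood-ratio p-values keep one number
per coefficient. Selection and inference use the same data, so these
p-values inherit post-selection optimism; they are ranking devices, not
calibrated error rates, and no correction is attempted.

Columns whose 2×2 table against the labels has a zero cell are flagged as
(quasi-)separated rather than dropped: their point estimates are unstable and
their Wald p-values near 1. The MLE is attempted with Newton's method and
falls back to L-BFGS under separation; a hard error is raised only if even
the fallback cannot produce finite estimates.

## Tabulation baseline

The naive comparator tests each medication's 2×2 table against case/control
status with Fisher's exact test (two-sided by the "probability mass ≤
observed" rule, the most common convention) and the sample cross-product odds
ratio a·d/(b·c); zero-cell odds ratios are reported as 0/∞ with a flag rather
than continuity-corrected. Because this adjusts for nothing, a medication
treating a comorbidity of the index condition shows a spurious association —
the contrast with the regression pipeline is the package's central claim.

## Drug-class preference

For the class analysis the population is restricted to patients with at
least one visit co-mentioning the index condition and a medication of one of
the configured classes; the visit is drawn uniformly among such visits and
the outcome uniformly among the distinct classes mentioned there (patients
frequently mention several classes, and the upstream data keeps all of them —
deduplication happens only at the draw). Features are condition indicators
only.

Comorbidities are screened by a K×2 chi-square test (no Yates correction),
then fitted by L1-penalized multinomial logistic regression along a penalty
path with the same CV/1-SE machinery as the binary pipeline. Per-class
coefficients of a softmax are only identified up to a per-feature constant;
we report the symmetric parameterization (zero mean across classes per
feature) and interpret only pairwise differences: exp(β_a,j − β_ref,j) is the
factor by which comorbidity j multiplies the odds of class a over the
reference class. No p-values are computed for this model (they are expensive
and unnecessary for ranking); comorbidities are ranked instead by their
drop-out penalty — the largest path penalty at which they still carry a
nonzero coefficient for any class. The number of rows shown (`top_n`,
default 13) is a display parameter, not a selection rule.

Two solver details matter. scikit-learn's saga can stop after a single epoch
when a penalty sits exactly at a coefficient's entry threshold; a fit that
hits its iteration cap is accepted if it satisfies the L1 first-order (KKT)
conditions within 5% relative slack, and rejected with an error otherwise.
And because saga's stopping rule can leave the (unpenalized) intercepts
unconverged at strong penalties, intercepts are re-solved exactly at each
path point with coefficients held fixed — a small convex problem — so the CV
deviance curve is trustworthy along the whole path. With two classes
scikit-learn fits the binary parameterization; it is converted to ±w/2, which
carries the same L1 cost for any pairwise difference, so path and CV choices
are unaffected.

## Synthetic EHR generator

No real mention data ships with the package, so every downstream stage is
exercised against a generator whose ground truth is known exactly:

- **Conditions** are drawn per patient in configuration order from their
  marginal prevalences; a comorbidity link (A, B, m) multiplies B's
  prevalence odds by m when A is present (links only act forward in the
  sampling order, keeping marginals interpretable).
- **Treatments** (med, condition, q) prescribe the medication with
  probability q to patients with the condition. Medications mapped to drug
  classes are prescribed through a class choice: the patient is treated with
  probability 1 − Π(1−q) over the class-mapped medications, the class is
  drawn from a multinomial logit whose base weights are the summed q per
  class and whose log-odds are shifted by the patient's comorbidity
  preference effects, and the medication within the class is drawn
  proportional to q.
- **Background mentions** give any medication a condition-independent
  mention probability. In the standard study configuration the treatment
  medications also carry a small background probability (0.02): outpatient
  notes list home medications taken for any reason, so even an
  index-condition drug appears occasionally in control notes. Without this,
  every treatment column would be perfectly separated — something real
  mention data never shows.
- **Visits** are 1 + negative-binomial with configurable mean and dispersion
  (real outpatient visit counts are overdispersed, sd ≳ mean; a Poisson is
  deliberately not used).
- **Recording noise**: each latent concept is mentioned at each visit
  independently with probability `recording_prob`. A patient none of whose
  latent concepts is ever recorded does not appear in the table at all, as in
  a real EHR extract.

Each patient owns an RNG stream derived from (seed, patient index), and each
treatment link consumes exactly one uniform regardless of outcome, so output
is reproducible and medication frequencies are monotone in the prescribing
probabilities under a shared seed.

The generator emulates the *statistical* structure the method must
disentangle — treatment links, confounding through comorbidity co-occurrence,
class preference, recording noise — and nothing else: no free text, no
negation or temporality, no demographics, no dates, no coding-system
idiosyncrasies. Passing tests therefore demonstrate that the statistics
recover the structure they target under this model, not that any particular
institution's data satisfies the model.

### Standard study conditions

The end-to-end recovery checks use a fixed configuration: 20,000 patients;
index condition at prevalence 0.35 with three comorbidities linked at odds
multipliers 2–4; five true treatments with prescribing probabilities
0.6–0.8; three confounder-only medications treating the linked comorbidities
(0.5–0.7); fifty background medications at 0.03; visit mean 4; recording
probability 0.7. The class-preference checks use 10,000 patients, two
equally-weighted classes, and a single comorbidity at prevalence 0.4 — the
prevalence mirrors the dominant comorbidity in published class-preference
tables (diabetes, ~46%) — shifting one class's log-odds by +1.0. Problem
sizes for the unit-level simulations (e.g. n = 2,000 for selection behavior,
n = 5,000 for Wald coverage) are the smallest at which the binomial noise
floor is well below the effects being measured.

## Evaluation

Ranked medication lists are scored against an indication reference (a
two-column medication–condition table standing in for a high-precision
medication-indication knowledge base) by precision@k (k defaults to 30), and
by the number and in-reference proportion of discoveries at a
Benjamini–Hochberg FDR of 5%. Discovery counting is restricted to medication
rows — the protocol counts drugs, while the regression table may also retain
conditions. A run with zero discoveries reports its proportion as
not-applicable, never as zero. Against simulator ground truth the harness
additionally reports recall of true treatments in the top k and the number of
confounder-only medications there.

## Numerical choices and edge cases

- Penalty parameterization: per-observation objective (1/n)·deviance/2 +
  λ‖β‖₁; scikit-learn's C = 1/(nλ). liblinear (binary path) regularizes its
  intercept; `intercept_scaling=100` makes that penalty negligible.
- "Nonzero" coefficient means |β| > 1e−8.
- p-values below double precision are reported as 0; ranking then relies on
  the documented odds-ratio tie-break.
- Fisher two-sided ties use scipy's 1+1e−7 relative tolerance on
  hypergeometric probabilities.
- Degenerate designs error early: no cases, no controls, no qualifying
  class-choice patient, an empty screen, an all-zero contingency table.
- BH adjusted p-values are min over j ≥ rank of m·p₍ⱼ₎/j, capped at 1, so
  `adjusted p ≤ q` reproduces the step-up rejection set exactly.

## Known limitations

- No case/control matching, no interaction terms, no elastic-net variants,
  no confidence intervals for the selection stage, no mid-p or stratified
  (CMH) tabulation — all deliberately out of scope.
- Post-selection p-values are optimistic (see step 4); residual confounding
  through unrecorded comorbidity mentions is attenuated, not eliminated, by
  the per-visit recording model.
- Whether a case's features should exclude visits before condition onset is
  not modelled; visit selection is uniform.
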
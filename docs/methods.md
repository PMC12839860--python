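# Methods

## Scores

**ISS.** Each patient carries a map from the six ISS body regions
(head/neck, face, chest, abdomen, extremities, external) to the maximum AIS
severity (0–6) sustained there. ISS is the sum of squares of the three
highest region severities, with the conventional override that any AIS 6
injury scores the maximum of 75. Regions are interchangeable: ties are
broken by value sort only. Severities outside 0–6 are rejected.

**SRR / scaled ICISS.** On a derivation cohort the survival risk ratio of
code *c* is SRR(*c*) = survivors(*c*) / carriers(*c*), where a patient
counts once per distinct code regardless of repeats within their record.
A patient's ICISS is the product of SRRs over their distinct codes
(`iciss_variant="product"`, the conventional rule); a worst-single-SRR
variant (`"worst"`) is provided because the combination rule is not uniquely
standardized in the literature. The score is reported as
(1 − ICISS) × 100 so that all three metrics share a 0–100,
higher-is-worse scale.

**CCRR / ICASS.** The critical-care risk ratio of code *c* is
CCRR(*c*) = 100 · episodes(*c*) / carriers(*c*), where "episode" is a
patient-level 0/1 indicator (not an event count — this keeps CCRR ≤ 100).
The episode rule is configurable (`CritCareRule`); the default is *ICU
admission from the ED or any ICU stay ≥ 1 day, or mechanical ventilation,
or in-hospital death*. This is deliberately a generic critical-care-services
definition, distinct from the trauma-center resource (NFPTCR) criteria the
scores are later evaluated against, so the score and its reference standard
are not the same rule. A patient's ICASS is the maximum CCRR over their
distinct codes.

**Unseen codes.** Codes in an application cohort that never entered the
derivation table are handled by policy: `neutral` (default — the code
contributes SRR 1 and CCRR 0, i.e. no severity), `cohort_mean` (table-mean
ratios), or `strict` (unseen codes are dropped; a record with no resolvable
code raises an error). `min_count` (default 1) drops codes with fewer
derivation carriers, since ratios from a handful of patients are noisy.
The fitted table reports Wilson score intervals for each code's SRR and
CCRR via `DiagnosisRiskResults.conf_int()`.

## NFPTCR classification

A record is NFPTCR+ if any of five criteria fires: transfusion within 4 h
of arrival; a qualifying procedure (tube thoracostomy, pericardiocentesis,
ICP monitoring, craniotomy, laparotomy, hemorrhage control, invasive
angiography, solid-organ/hollow-viscus repair) within 72 h; general
anesthesia or mechanical ventilation at age ≤ 5; ICU admission from the ED
or any ICU stay ≥ 3 days; or a physical child-abuse investigation. All
time/age boundaries are **inclusive** ("within 4 h", "5 years old or
younger", "≥ 3 days"). Death is not itself a criterion. ICU days are
whole days with any partial day counting as 1, and the ≥ 3-day rule is read
as cumulative days across stays. Mapping clinical events to the controlled
procedure vocabulary is the registry record's responsibility, not the
classifier's.

## Evaluation

AUC is the Mann–Whitney pair statistic (ties credited ½), computed from
DeLong placement values; its variance, the 95% CI (logit-transformed and
back-transformed so it stays inside [0, 1]) and the paired comparison of
two correlated AUCs all come from the same placement-value machinery. The
paired test refers (AUC₁ − AUC₂)² / var(diff) to χ²(1), equivalent to a
two-sided z-test; when var(diff) is exactly zero the statistic is reported
as undefined with p = 1 if the AUCs are equal. The implementation is
cross-checked in the test suite against R's `pROC` (`roc.test`,
`method="delong"`), exhaustive pair counting, and a paired stratified
bootstrap.

Threshold operating characteristics default to the `strict_greater`
convention (predicted positive iff score > t, matching "score > 5"-style
table rows); `geq` is available because published threshold tables are not
always explicit about the boundary. Sensitivity/specificity are reported
in percent. Descriptive group comparisons use Pearson chi-square without
continuity correction for categoricals and tie-corrected Kruskal–Wallis for
continuous variables (for two groups this is the Wilcoxon rank-sum test on
the χ²(1) scale); medians are shown with interquartile ranges. A score
that enters a univariate logistic regression yields the same ROC curve as
the raw score (AUC is invariant under strictly increasing transforms), so
regression is documented rather than separately implemented.

## Synthetic registry generator

The generator emulates the structure the analysis assumes, not any real
coding system. Each of `n_codes` ICD-like codes gets a body region
(uniform), an AIS severity (1–6, weighted 0.30/0.28/0.20/0.12/0.07/0.03
toward minor injuries), and latent propensities drawn from Beta
distributions (pseudo-count 8) whose means rise with severity:
mean p_critcare = 0.20·(ais/6) and mean (1 − p_survive) = 0.04·(ais/6)²
(lethality concentrates in the worst codes). Sharing the AIS severity
couples p_critcare and lethality positively, as in real vocabularies.

Patients draw 1–6 distinct codes (truncated geometric, p = 0.55 — real
injury records list few distinct codes; the distribution is configurable
because registry code-count distributions vary), an integer age uniform on
0–15, sex 63% female, and a mechanism mix (abuse 1.3%, penetrating 1.9%,
transport 31.6%, other blunt 65.2%) matching the descriptive margins of a
large US pediatric registry cohort. Death occurs with probability
1 − ∏ p_survive and a critical-care episode with probability
1 − ∏ (1 − p_critcare) over the patient's codes (the multiplicative
independence structure the risk-ratio estimands assume). Death is *nested*
within the episode whenever the marginals permit: given the episode, death
occurs with probability min(1, q_death/q_episode), and otherwise only with
the leak probability max(0, q_death − q_episode)/(1 − q_episode). Both
marginals are preserved exactly, and because an episode always plants an
ICU stay ≥ 1 day, the default CCRR rule (ICU ≥ 1 day / ventilation /
death) fires if and only if the episode indicator is true up to the
(negligible at defaults) leak — making the derived CCRR an unbiased
estimator of p_critcare. Clinically the nesting says fatal trauma courses
pass through critical care, which is closer to reality than independence.

An episode additionally realizes one NFPTCR-qualifying event drawn from a
categorical mix (transfusion 15%, urgent procedure 20%, anesthesia/
ventilation 15% — only offered at age ≤ 5, ICU admission-from-ED or ≥ 3-day
stay 45%, abuse 5%), with timestamps uniform inside the qualifying window.
Episode-free patients receive a qualifying event at a 2% background rate
and, independently at a 5% rate, an event with a deliberately
*disqualifying* timestamp (transfusion in (4.5, 24) h, procedures in
(72.5, 168) h) to exercise the timeframe filters. The default scales were
fixed once so that a default cohort reproduces the study conditions the
generator emulates — ≈ 16% NFPTCR prevalence and ≈ 1–2% in-hospital
mortality. All randomness flows from the single integer seed in
`CohortSpec` through one numpy generator stream, so identical specs give
byte-identical cohorts.

**What the generator does not emulate:** real ICD-9/10 code semantics,
coding variability between hospitals, interfacility-transfer dynamics,
correlation between mechanism and outcome (mechanism is descriptive only),
or within-patient clinical coherence beyond the region-max AIS profile.
Passing tests therefore demonstrate that the estimators and the pipeline
are correct under the assumed multiplicative structure — not that the
scores would achieve any particular AUC on real registry data.

## Pipeline

Inclusion keeps patients aged ≤ 15 with a computable ISS (non-empty AIS
profile) when `require_iss` is set; exclusions are logged per patient with
a reason (`age`, `missing_iss`). The derive/apply split is temporal by the
record's calendar year (derivation years vs one held-out application year,
validated to be disjoint), mirroring a registry derive-then-apply design
rather than a random split. `run_study` writes every artifact plus a
manifest (config hash, seed, package version, counts, AUCs); rerunning an
identical config reproduces all CSV/JSON outputs byte for byte.

## Problem sizes and numerical choices

The test suite exercises oracle equivalence on small fixtures (ROC vs pair
counting at n ≤ 50; score tables vs naive recounts at n ≤ 100), parameter
recovery at ~10,000 single-code carriers per code (tolerance ±0.02,
comfortably above the ~0.005 binomial standard error), and the directional
AUC comparison on a 50,000-patient cohort with the default generator
settings — sizes chosen to make the statistical checks decisive while the
whole suite runs in well under a minute of compute per test. Floating-point
equality is asserted only where arithmetic is exact (counts and ratios);
everything else uses absolute or relative tolerances stated in the tests.
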
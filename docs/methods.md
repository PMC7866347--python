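# Methods

## Data model and units

A cohort is a list of validated patient records. Each record pairs a series
of 12-region lung-ultrasound (LUS) exams with clinical observations
one-to-one by timepoint (`admission`, `h24`, `h48`, `event`), with an
auxiliary hour offset so that event exams can fall anywhere in the stay;
the admission exam must occur within 6 h of admission. Units are fixed:
mm for IVC diameters, mL for fluid balance, °C for temperature, L/min for
oxygen flow, per mm³ for white cells; no converters are provided. Optional
quantities (labs, fluid balance, IVC, temperature) are explicit nulls —
never sentinel zeros — because the pneumonia rule's "if available" clause
must distinguish a missing white-cell count from a low one. The 12 regions
use a fixed canonical naming (side `L`/`R` × `ventral/lateral/
posterolateral` × `superior/inferior`); auscultation findings are carried
as free text and used by no rule.

## Aeration scoring

The global LUS score is the sum of per-region aeration scores (0–3) over
examinable regions (range 0–36 for a complete exam). Unexaminable regions
(dressings, positioning) are excluded without imputation, and
`examined_regions` is reported so callers can flag incomplete exams. An
exam is "normally aerated" only if all 12 regions are examinable and score
0 — an incomplete exam cannot be certified normal, a deliberate
conservative choice since the alternative cannot be distinguished on the
data. Bilateral interstitial syndrome requires ≥ 2 B-pattern regions
(score 1 or 2) per hemithorax; bilateral consolidation ≥ 2 score-3 regions
per hemithorax; both count examinable regions only. IVC plethora is a
strict inequality (maximal diameter > 23 mm) and is `unknown` (None) when
the IVC was not measured.

## Physiology

FiO₂ = 0.21 + 0.03 × O₂ flow (L/min), capped at 1.0 because the linear
formula exceeds the physical bound above ~26.3 L/min. The S/F ratio is
compared against thresholds unrounded, avoiding display-rounding artifacts
at the 315 boundary. Respiratory distress = RR ≥ 30 /min OR S/F ≤ 315 OR
use of accessory muscles OR nasal flaring; only those two signs of
difficult breathing are coded.

The OEWS engine is chart-agnostic: a chart is a set of contiguous,
non-overlapping half-open bands per vital sign plus AVPU weights, validated
at load time. The shipped default chart is a best-effort reconstruction of
a standard obstetric early-warning banding (weights 0–3 per parameter) and
is explicitly replaceable via a YAML file with the same schema; no claim is
made that it reproduces any particular hospital's chart. A missing vital
contributes 0 with a warning rather than failing the score.

Sample size for a proportion uses n₀ = z²p(1−p)/d² with z = Φ⁻¹(0.975) ≈
1.959964 for 95% confidence, the finite-population correction
n = n₀ / (1 + (n₀−1)/N), and ceiling rounding.

## Case definitions and evaluation order

Per exam, flags are computed in the order: effusion → fluid overload →
ARDS → pneumonia → atelectasis.

1. **Effusion**: any region with a pleural-effusion finding. Independent of
   all other calls (non-exclusive category).
2. **Fluid overload**: (bilateral interstitial syndrome OR effusion) AND
   (fluid balance > 1000 mL/24 h OR IVC plethora). Missing balance or IVC
   contributes false to its disjunct. Strict inequalities.
3. **ARDS**: S/F ≤ 315 AND bilateral opacities AND no history of cardiac
   failure AND not fluid-overloaded at this exam. "Bilateral opacities not
   attributable solely to effusion" is operationalized as: the bilateral
   interstitial/consolidation pattern holds, and each hemithorax has ≥ 1
   examinable region scored ≥ 1 without an effusion flag. Nodule
   adjudication is not computable from the data model and is not attempted.
   The one-week acuity window of the Berlin-style definition is satisfied
   by construction: all HDU exams fall within the acute admission episode.
4. **Pneumonia**: any examinable region scored ≥ 1 (focal or multifocal
   interstitial syndrome and/or consolidation) AND (temperature > 38.3 °C
   OR white cells > 12,000/mm³ when a count is available). With both
   unavailable the call is false, not unknown, reflecting non-systematic
   laboratory sampling.
5. **Atelectasis**: any region scored 3, not falling in the ARDS, pneumonia
   or fluid-overload definitions (residual clause).

The order encodes the exclusion clauses: ARDS and fluid overload are never
both called at one exam, and atelectasis excludes the other three. These
invariants are enforced by the `ExamCall` validator and property-tested on
random exams. Because S/F ≤ 315 is both an ARDS requirement and a distress
criterion, an ARDS call implies respiratory distress at the paired
observation.

Stay-level aggregation takes the union of types over exams; `first_onset`
is the category of the earliest positive exam (exams ordered by hour
offset, ties toward the earlier category): the admission exam →
`admission`; any later exam within 24 h → `first_24h`; beyond →
`thereafter`. An event exam is categorized by its hour offset. Distress
stratification uses "distress at any observation during the stay". Poor
outcome = transfer for escalation of care or death. All thresholds
(RR 30, S/F 315, IVC 23 mm, 1000 mL, 38.3 °C, 12,000/mm³) are overridable
through a `Thresholds` object and CLI flags for sensitivity analyses.

## Statistics

Binomial proportions default to exact Clopper–Pearson intervals
(beta-quantile based; Wilson available): for 35/166 the exact interval
rounds to [15, 28] whereas Wilson's lower bound rounds to 16, and the exact
method matches study-style reporting. 2×2 chi-square tests apply the Yates
continuity correction by default (for the 21/36 vs 14/109 stratum contrast
the corrected p ≈ 0.00068 rounds to 0.001; the uncorrected does not).
Mann–Whitney uses exact enumeration for n₁+n₂ ≤ 12 without ties, otherwise
the tie-corrected normal approximation with continuity correction; complete
ties return p = 1. Kruskal–Wallis applies tie correction and returns
(0, 1) for fully degenerate input. Fleiss' kappa is computed from the
items × categories count matrix with the convention that perfect agreement
— including the degenerate all-one-category case where chance agreement is
1 — returns exactly 1.0.

The outcome model is a logistic regression (Newton/IRLS maximum likelihood,
score tolerance 1e-10, ≤ 50 iterations) of poor outcome on any-complication
with the admission OEWS entered as a continuous integer covariate (banding
is an equally defensible alternative; continuous was chosen as the simpler
model given no evidence either way). Odds-ratio CIs are Wald, which match
the closed-form 2×2 estimator exactly in the unadjusted case. Complete or
quasi-complete separation and non-convergence are detected and reported
(`converged=False` with a diagnostic) — never a silent estimate. Tests are
two-sided; rendered tables display whole-number percentages and p-values to
three decimals with a "<0.001" floor, while machine output keeps full
precision.

These primitives delegate to scipy.stats and statsmodels; the test suite
checks them against independent from-scratch oracles (beta-tail bisection,
exhaustive rank enumeration, direct kappa arithmetic, closed-form 2×2
odds ratio).

## The deterministic fixture

`build_paper_fixture()` emits 166 granular records — region scores and
artifact flags, vitals, balances, IVC diameters, histories, outcomes — and
**no complication labels**, so every downstream count exercises the full
rule engine rather than echoing stored answers. The construction targets
the published group structure: strata 21/36/14/95 (distress × complication),
distress-stratum type counts ARDS 6 / fluid overload 6 / effusion 8 /
pneumonia 2 / atelectasis 6, no-distress counts effusion 3 / pneumonia 1 /
atelectasis 11, outcomes per group (poor 6/5/3/4; deaths 0/5/1/2; transfers
6/0/2/2), onset timing 14/5/2 and 8/5/1, and the exam schedule 166
admission + 121 at 24 h + 86 at 48 h + 10 event exams (attached to
deteriorating complication patients at hour 30).

Effusion overlaps are arranged to respect the exclusion rules: in the
distress stratum 7 of 8 effusions coexist with another type (2 ARDS, 2
fluid overload, 1 pneumonia, 2 atelectasis) and 1 stands alone (21
patients, 28 type counts); in the no-distress stratum 1 effusion coexists
with atelectasis (14 patients, 15 type counts). Any assignment meeting the
marginals would do; this one is fixed and documented here.

Exam-level global scores are drawn from fixed per-type multisets chosen so
the 96 complication-positive exams have median 4 (IQR 3–9) and the 287
negative exams median 0 (IQR 0–1) under linear-interpolation percentiles:
ARDS exams 8–24 (bilateral B-patterns), fluid overload 6–12, pneumonia 2–4
(focal), atelectasis 3–5 (focal consolidation), effusion-only 0–2,
negatives 0–2. Region patterns guarantee each rule's premises: bilateral
patterns anchor ≥ 2 effusion-free B regions per side; focal patterns stay
unilateral so they can never satisfy a bilateral rule.

The builder self-verifies: after construction it classifies the cohort and
asserts every count above (`FIXTURE_EXPECTED`), raising on any mismatch,
and it is byte-deterministic across builds. Demographics (admission
reasons, delivery mode, anesthesia, malaria status) follow the published
marginal frequencies via a fixed interleaving; they are realism, not
assertions. The published per-patient exam-count median (2, IQR 2–3) is
not asserted: it is not exactly reconcilable with the 166/121/86/10
schedule without extra assumptions about early discharge.

## The stochastic simulator

`simulate_cohort(SimulationConfig(seed=...))` draws granular cohorts from
a generative model whose defaults are the study conditions: distress
prevalence 0.34; complication probability 21/57 in the distress stratum
and 14/109 outside it (overall ≈ 0.21); type mixes and coexisting-effusion
probabilities equal to the fixture's observed frequencies; onset
probabilities 22/35, 10/35, 3/35; exam schedule probabilities 121/166 and
86/121; vitals from truncated normals located at the published medians with
scale IQR/1.349 (truncation bounds keep each patient consistent with its
assigned class, e.g. assigned-ARDS patients draw SpO₂ ≤ 96 on 5 L/min so
S/F ≤ 315 always holds). Event exams are not simulated — the fixture covers
them. Poor outcome is drawn from a logistic model, intercept −3.2,
log-odds-ratio ln 5.0 for any complication, 0.15 per OEWS point; the
intercept was set so the simulated poor-outcome rate sits near the observed
11%. By construction the classifier recovers the generative labels
(self-consistency is asserted ≥ 99% in tests; in practice it is exact),
and the seed fully determines the cohort.

`simulate_outcome_frame` is a vectorized label-level draw from the same
model (distress, OEWS, complication, outcome only), used for
parameter-recovery studies — 200 replicates at n = 2000 fit in seconds,
where materializing 400,000 fully granular records would add nothing to
the question being asked of the outcome model. Recovery of the configured
odds ratio with ~95% Wald coverage is asserted in the acceptance tests at
exactly that scale.

What the synthetic data does **not** emulate: measurement error and
inter-rater disagreement in region scoring (the real study quantified this
as kappa 0.77 on saved images — not reproducible without them, so the
kappa statistic is validated on constructed matrices instead); missing-ness
mechanisms beyond "labs sometimes absent"; correlation between vitals
within a patient over time; the enrollment funnel upstream of the 166
enrolled patients; survival after transfer (unknown in the source setting).
Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline under the stated generative assumptions, not
clinical validity on real records.

## Numerical conventions and edge cases

Percentile summaries use numpy's linear interpolation. Exams are ordered by
hour offset with admission < h24 < event < h48 on ties. Validation errors
name the offending patient/field; duplicate (patient, timepoint) exams are
rejected. The CLI exits 0 on success, 2 on input/validation failure, 3 on
computation failure, and logs each run as JSON lines. All randomness flows
through a single numpy Generator seeded from the mandatory config seed.

## Known limitations

The default OEWS chart is a reconstruction, not the original instrument;
OEWS-adjusted estimates on real data should supply the site's chart. The
pneumonia rule accepts any qualifying region ("focal or multifocal") and
relies on the fever/leukocytosis arm for specificity, since the boundary
between focal and bilateral patterns is already consumed by the ARDS rule.
Pulmonary embolism and peripartum cardiomyopathy are out of scope (no
compression ultrasonography or echocardiography in the data model), as is
any image-level processing.
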
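# Methods

## Scope and model

The package analyses one presentation-level triage question: how well does
a three-component disposition score (mental status, mobility, respiratory
abnormality; 0–3 points) discriminate 24-hour mortality and hospital
admission, and how does its implied acuity compare with the South African
Triage Scale (SATS) presentation urgency ranking?

The score is deterministic given its components. Thresholds are strict
inequalities: SpO2 < 94% and respiratory rate > 23/min score the
respiratory point; the boundary values 94 and 23 do not. Subjective mental
status is normal only if the patient is alert, attentive, calm **and**
coherent; the objective alternative is the months-backwards test
(December back to July), where inability to attempt the test is recorded
as a fail, not as missing — a deliberate choice, since the patients who
cannot attempt it are exactly those an objective mental-status screen
should flag. Mobility collapses a 5-level gait category to binary at
scoring time so richer source data survives I/O.

Eligibility is non-pregnant, age ≥ 12. Analysis sets are per-variant
complete-case: a record missing a required component is excluded from that
variant only. This mirrors real deployments where assessments are
introduced at different times, and it is why a fair comparison of two
variants recomputes the reference score *on the comparison variant's
subset* (see Discrimination below).

## SATS taxonomy

The taxonomy carries the 21 presentations observed in the study setting:
3 emergent, 12 very urgent (the combined haemoptysis/uncontrolled-bleeding
row is split into its two constituent presentations, both very urgent —
pure bookkeeping, no ranking changes), 6 urgent; reduced level of
consciousness is narrowed to coma. A patient's rank is the maximum over
their presentations; no presentations means non-urgent. Codes outside the
taxonomy raise rather than defaulting to non-urgent, so malformed fixture
data cannot silently deflate urgency. An explicit `non_urgent` pseudo-code
lets generators distinguish "ranked non-urgent" from "never ranked"
(empty list); concordance operations exclude never-ranked records and
report the exclusion count.

## Statistics

* **c statistic**: midrank (Mann–Whitney) estimator; tied pairs count ½.
  With a 4-level score ties dominate, so the tie convention is
  load-bearing; the test suite pins the estimator to a brute-force
  all-pairs oracle and to an independent ROC-AUC implementation.
* **Standard error**: the Hanley–McNeil closed form in A, n_pos, n_neg
  (exactly 0 at A ∈ {0, 1}; strictly decreasing in both counts —
  property-tested).
* **Comparison of two c statistics**: normal z on the difference with
  variance SE₁² + SE₂² − 2·r·SE₁·SE₂. The default is the independent test
  (r = 0) with a *one-tailed* p = P(Z ≥ |z|), the convention that
  reproduces the published comparison p-values from their printed AUC/SE
  pairs; it is conservative for same-patient comparisons, which are
  positively correlated, and a paired option with user-supplied r is
  provided. Back-computing from SEs printed to 3 decimals leaves
  rounded-input noise of order 10⁻³ in small p-values; agreement beyond
  one significant figure is not forced.
* **Association**: 2×2 tables use the Yates-corrected chi-squared with the
  correction clamped at zero; wider tables (score 0–3 × outcome) use the
  uncorrected Pearson statistic. Numeric comparisons use the
  pooled-variance two-sample t.

## Concordance and discordance

The cross-tab counts patients by (score points 0–3) × (urgency). Acuity
discordance uses a high-score cut of ≥ 2 points: *higher* discordants are
non-urgent-ranked patients at or above the cut (as a share of the
non-urgent total), *lower* discordants are below-cut patients among
urgent + very urgent ranks (share of that group). The cut and the
lower-denominator levels are configurable; on the packaged published
cross-tab, adding emergent to the denominator changes nothing because no
emergent patient scored below 2. The ≥ 2 cut is the mapping consistent
with the published table's own arithmetic (689 + 79 = 768 of 6,926 =
11.1%), and is the package default for that reason.

Percentages in all reports are rounded half-up to one decimal and always
recomputed from their integer numerator/denominator at render time.
Quantiles (median, IQR) use the q·(n+1) plotting position (type-6 /
"exclusive" convention); SD is the sample SD, defined as 0 for n = 1.

## Discrimination table

For each outcome (24-h death, admission): the reference variant's
c statistic on its full complete-case set, then per comparison variant its
c statistic on its own subset **and the reference recomputed on that same
subset**, with the one-tailed independent-z p. The SATS row treats the
urgency rank 0–3 as an ordinal score over the ranked sub-cohort. Rows
whose subset lacks an outcome class are flagged non-computable rather than
raising.

## Synthetic cohort generator

No patient-level data of this kind is publicly deposited, so the pipeline
is exercised on simulated cohorts. Generation is **score-class-first**:
the published marginals are score-level prevalences and score-conditional
outcome rates, so the score class is drawn first and everything else is
made consistent with it; component correlation is implied by the class,
not modelled separately.

Default calibration (all overridable via `GeneratorConfig`):

| parameter | default | source/choice |
|---|---|---|
| n | 14,585 | published cohort size |
| score-class probabilities | (0.7293, 0.1022, 0.1238, 0.0448) | published counts (10,637 / 1,490 / 1,805 / 653) |
| p(24-h death \| score) | (0, 0, 2/1805, 37/653) | published death breakdown |
| p(admit \| score 3) | 0.95 | free parameter (the 2-vs-3 split is not identifiable) |
| p(admit \| score 2) | solved ≈ 0.603 | so expected admissions at ≥ 2 points = 1,708 |
| p(admit \| score 0, 1) | 96/12,127 each | 96 published low-score admissions, spread evenly |
| p(late death \| admitted) | 134/1,804, all scores | per-score split not identifiable |
| score × urgency joint | published 7,500-patient cross-tab / 7,500 | urgency drawn conditional on points |
| months-test disagreement | 0.05 | makes the objective variant differ from the subjective one without degrading it |
| sub-cohort availability | RR 4,368/14,585; months 11,481/14,585; SATS 7,500/14,585 | staggered-introduction sub-cohort sizes, drawn independently per patient |
| SpO2 ranges | low 88–93, normal 94–99 (uniform integers) | range-faithful, no physiology |
| RR ranges | normal 12–23, high 24–40 | likewise |
| age | truncated normal, floor 12, *parent* parameters solved so the truncated law has mean 44.0, SD 19.9 | naive truncation would realize ≈ 46/18 |
| sex | P(male) = 0.392 | published |
| arrival | 6-h block weights (297, 6658, 6658, 972)/14,585 over a 342-day window | published day/night load; the 06–18 split is assumed even |
| late-death day | geometric, p = 0.21 | puts ≈ 69% of late deaths within 5 days, matching the published share |

Component patterns are uniform over subsets of the drawn size, with one
exception: 24-h deaths at 2 points are confined to the
{mental, mobility} pattern with the rate rescaled ×3 to preserve the
marginal, so that **no simulated decedent has a stable gait or a normal
mental status** — the structural zero the calibration data exhibits. The
toggle `deaths_require_mental_and_mobility` disables this.

Deaths force admission; this adds ≈ 2.6 expected admissions (0.02% of the
cohort) over the 1,804 target, far inside sampling noise at this n.
SpO2 and respiratory rate are drawn on the same side of their thresholds,
so the saturation- and rate-based variants agree wherever both are
measured; their table rows still differ through their different subsets.

RNG: one root seed spawns eight per-stage child streams (scores,
components, vitals, months test, SATS, outcomes, demographics, arrival),
so a given seed yields a byte-identical cohort and adding a stage never
reshuffles earlier draws.

### What the generator does and does not show

Passing marginal-recovery and discrimination checks on simulated cohorts
demonstrates that the *pipeline arithmetic* is correct and that the
calibrated regime (c statistics > 0.9 for both outcomes) is reproduced.
It does **not** validate the score on real patients: vital-sign
physiology, repeat attendance, time-of-day acuity structure, and any
component correlation beyond what the score class induces are absent, and
the exact published cohort-level c statistics are not identifiable from
printed marginals alone — simulated values land near, not on, them.

## Numerical choices and degenerate inputs

* One-tailed p from the normal survival function; equal c statistics give
  z = 0, p = 0.5; both SEs zero raises a degenerate-comparison error.
* All-positive or all-negative outcome vectors make the c statistic
  undefined and raise; in the discrimination table they flag the row
  instead.
* Yates correction clamps at zero when |ad − bc| ≤ n/2; zero margins
  raise.
* Zero pooled variance makes the t statistic undefined and raises.
* Empty cohorts raise in summaries; empty denominator groups raise in
  discordance percentages; a discordant group with no admissions reports
  its in-hospital death percentage as missing rather than 0.
* CSV I/O is strict: unknown enum tokens, out-of-range vitals and
  inconsistent outcome fields are reported with row numbers; the
  round-trip write→read is lossless.

## Known limitations

* The admission split across scores 2/3, the per-score late-death split,
  and the even 06–18 arrival split are free choices within the published
  marginals; conclusions sensitive to them should vary the config.
* The generator's SATS draw is conditional on the score, so simulated
  urgency-discordance percentages track the published ones only in
  expectation through the joint matrix.
* Paired c-statistic comparison requires a user-supplied correlation; no
  resampling estimator of r is provided (DeLong/bootstrap are out of
  scope).
* Paediatric (< 12 y) and obstetric scoring, vital-sign early-warning
  composites (TEWS), and respiratory-rate capture devices are out of
  scope; respiratory rate is accepted as a number.
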
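# Methods

## Scope and data model

`dentage` consumes per-tooth developmental-stage records — FDI two-digit
tooth codes, one of three staging schemes per assessment (Nolla integer
1–10 with a between-stage qualifier, Demirjian letters A–H plus a "0"
absent-crypt token, or an atlas ordinal index), subject sex, and
chronological age at one-month resolution — and produces per-method age
estimates with full provenance (which teeth and tables were used, which
contralateral substitutions fired, whether a lookup clamped). Radiograph
reading is out of scope; the package starts where the examiner's stage
calls end.

Cohorts emulating the reference study design are soft-validated to ages
4–21 (a warning outside, not an error), and at most one assessment per
(tooth, scheme) is allowed per subject.

## Estimation engines

### Lookup and interpolation

All age lookups share one rule (`lookup_age`): exact knot hits return the
tabulated age exactly (asserted to 1e-12 in the tests); values strictly
between knots are linearly interpolated; values outside the tabulated
range return the boundary age with a `clamped` flag rather than an error.
Linear interpolation was chosen because it subsumes the only reading rule
the classical descriptions state — a value exactly between two entries
receives the mean of the two ages — and is the simplest rule consistent
with it. Clamping (rather than refusing) mirrors how these methods are
used in practice on subjects older than the tables' ceilings, and is what
produces the well-known saturation/underestimation pattern at the top of
the age range.

### Nolla

One value per left/right tooth pair (the left member preferred, the right
substituted and recorded when the left is unassessable), summed over a
configurable jaw scope (mandible by default; maxilla or both supported
because the published tables exist for all three). Third-molar pairs are
included exactly when every pair in scope is assessable
(`include_third_molars=None`, the default, resolves this per subject), and
the matching sex-specific table variant is selected. A pair with neither
member assessable is an `IncompleteDentitionError` naming the pair.

### Demirjian + Olze

The maturity score S is the sum of sex-specific self-weighted scores of
the seven left mandibular positions (right-side mirrors substitute, with a
record). S maps to age through sex-specific knots. The method's
calibration ceiling is 16 years; the table type carries that ceiling as
metadata (`usable_max_age`) while its knots may extend slightly beyond it,
because the third-molar supplement is defined to fire when the estimate is
*strictly greater than* 16 — a table hard-capped at 16.0 could never
trigger it. When it fires and a third molar (38, else 48) is stageable and
mapped in Olze's table, the Olze age *replaces* the estimate (both are
kept in the result detail); an unmapped or missing third molar falls back
to the base estimate, recorded as an attempted-but-unavailable supplement.
Replacement rather than averaging is a deliberate choice, exposed through
the trigger-age parameter.

### London-atlas matching

The observed pattern is assembled over the charted (right-side) teeth,
substituting the left mirror where the right was not assessed. Chart
similarity is the mean absolute ordinal stage discrepancy over shared
teeth — zero iff identical on shared teeth — and the estimate is the age
of the minimal-mismatch chart, with exact ties (tolerance 1e-9) resolved
by averaging all tied chart ages, the natural extension of the stated
two-chart rule. The result is independent of chart order. Sex is ignored
by design: the atlas makes no male/female distinction.

## Evaluation

Δ = estimated − real age, so positive values are overestimation. Age
categories are the floor of decimal age; margin rates use the inclusive
rule |Δ| ≤ m (the conventional reading; a margin is a tolerance, not an
open bound). Overall rows are computed over all subjects and are asserted
(at every call) to equal the count-weighted mean of the per-category
values; all aggregation is full precision, with 2-decimal rounding applied
only when tables are written.

Paired comparisons use the classical Student's t statistic on the paired
differences with n−1 degrees of freedom and a two-sided p-value
(cross-checked against explicit-sum arithmetic to 1e-10 in the tests).
Applicability is checked, not enforced: for n < 30 a Shapiro–Wilk test on
the differences at α = 0.05 is reported in the result's note; for n ≥ 30
normality is waived on central-limit grounds. Zero-variance differences
raise a degenerate-test error instead of returning a meaningless
statistic. No multiple-testing correction is applied.

## Synthetic cohorts

### Maturation model

Each tooth type (jaw × position; left and right share a trajectory)
carries, per sex, strictly increasing mean stage-entry ages for each
scheme grid — 10 Nolla stages, 8 Demirjian letters, a 10-point atlas
ordinal — generated from per-position development windows (first
calcification to apex closure). The default windows are plausible for
permanent teeth: incisors and first molars earliest (≈0.7 y), second
molars latest of the ordinary teeth (≈2.8–15.5 y), third molars ≈9–21.5 y;
the maxilla runs 0.3 y behind the mandible and females 0.3 y ahead of
males. Demirjian self-weighted scores give each position a weight (8, 8,
10, 12, 14, 22, 26 — molar-heavy, summing to 100) scaled linearly along
the stage index, so S saturates at 100.

A subject of age *a* draws one tempo shift z ~ Normal(0,
`individual_effect_sd`); the latent maturation age *a − z* drives the
stages of **all** teeth under **all three** schemes, so methods are
correlated across schemes as they are in real dentitions. The latent
position within an inter-stage interval also yields the Nolla qualifier
(quartiles: exact / +0.2 / +0.5 / +0.7). Observation noise mis-stages each
emitted assessment independently by ±1 stage with probability
`observation_noise`, truncated at scheme boundaries — the simplest
reader-error model; nothing in the reference study constrains it, as no
repeatability statistics were reported. Third molars are absent (no
assessment) before crypt formation; all other teeth are always assessable,
with pre-calcification Nolla calls scored as stage 1 (crypt) and
Demirjian as the "0" token.

Defaults: `individual_effect_sd` = 0.8 y (biological tempo variation of
roughly the size needed for realistic 1-year margin rates),
`observation_noise` = 0.08. The default cohort composition is the
reference study's: 324 subjects in categories 4–20 with fixed per-age
counts, 156 males/168 females allocated per category by largest-remainder
rounding, ages uniform on the one-month grid within each category. All
randomness flows through one explicitly passed seeded generator.

### Derived tables

`derive_tables` evaluates the model's zero-shift trajectory on a fine age
grid (1/24 y) and collapses each monotone step function into knots (one
knot per run of equal ordinate, at the run's mean age), yielding Nolla
sum-to-age tables for every (sex, scope, third-molar flag) combination,
Demirjian score/age tables, Olze stage-to-age entries (stages D–H; stage
ages are inter-stage midpoints, terminal stage entry + 0.75 y), and
sex-pooled atlas charts at 0.5-y steps over ages 4–23. Demirjian age knots
run to 17 y (`usable_max_age` stays 16) so that saturated scores produce
estimates above the trigger threshold; without-third-molar Nolla tables
end at 17 y and with-third-molar variants at 22 y, mirroring the reach of
the published tables. A `max_age` argument truncates every table for
ceiling-effect experiments.

Because tables and cohort come from the same process, a zero-variation
cohort estimated against its own tables must recover age within the table
resolution; the measured round-trip MAEs at n = 324 are ≈0.06 y (Nolla,
whose sub-stage qualifiers give the finest grid), ≈0.23 y
(Demirjian+Olze, dominated by the coarse third-molar letters above 16 y)
and ≈0.21 y (atlas, bounded by the 0.5-y chart step plus the 0.15-y
sex-pooling offset) — all within the 0.5-y resolution bound the design
targets. Halving the atlas chart resolution roughly doubles its
worst-case error, as expected from the step size.

`bias_scenario` shifts every entry age earlier by a chosen amount, so a
cohort generated from the shifted model but estimated against the
unshifted tables overestimates by that amount by construction; at +0.5 y
and n = 324 the recovered mean error is within ±0.1 y of +0.5 for all
three engines and the estimated-vs-real paired test is significant —
reproducing, at a known effect size, the systematic-overestimation
phenomenon the evaluation layer is built to detect. Truncating all tables
at 16 y reproduces the qualitative ceiling effect: mean error magnitudes
for categories ≥ 18 far exceed those for categories ≤ 14.

### What the simulator does and does not show

The generator emulates the *structure* of real staging data — monotone
maturation, between-subject tempo variation, left/right symmetry, scheme
correlation, third-molar late onset, reader error — but not real
populations: windows are not fitted to any demographic group, noise is
symmetric and memoryless, and tables derived from the model are exactly
consistent with it, which real published tables (calibrated on other
populations) are not. Passing round-trip and bias checks therefore
validates the *pipeline arithmetic and plumbing*, not the field accuracy
of any method on real subjects; the published per-age summaries in
`dentage.study_reference` are the package's only contact with real data,
and only their aggregation arithmetic (count-weighted totals) is
reproduced. The published per-age rates at categories 10 and 16 imply
denominators inconsistent with the printed counts (19 and 21 vs 20 and
20), so rate totals reproduce to ~0.1 percentage point rather than
exactly; this is a property of the source and is left as is.

## Numerical choices

- Knot tables require ≥ 2 knots, strict monotonicity in the abscissa and
  non-decreasing ages; violations are reported with table, field and rule.
- Atlas ties use an absolute tolerance of 1e-9 on the mismatch score;
  mismatch values are small rationals, so this only guards float noise.
- Problem sizes: tests and the acceptance script run cohorts of 324
  (the study composition); the full suite and script each finish in
  seconds.
- Errors are values, not silence: incomplete dentitions, unmapped stages,
  empty chart intersections, zero-variance paired differences and
  zero-count totals all raise typed exceptions; the pipeline logs and
  skips per-subject engine failures so one unreadable dentition does not
  abort a cohort run.

## Known limitations

- Shipped/generated reference tables are synthetic; results on them
  characterise the engines, not the published methods' field accuracy.
- The Olze supplement substitutes a point age per stage; no confidence
  intervals are produced anywhere (the reference analysis reports none).
- Willems-table and Cameriere-index variants, Bayesian calibration, and
  sex-stratified inference beyond the descriptive split are out of scope.
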
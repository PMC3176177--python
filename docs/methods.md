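# Methods

## The two indices

`carescore` grades one woman's antenatal care trajectory — her ordered
visits, each visit's gestational week (completed weeks) and which of three
tracked interventions occurred there, plus her gestational age at delivery
— on two rule-based four-level ordinal scales.

### CTP (Content and Timing of care in Pregnancy)

CTP uses the timing of initiation, the counts of three basic content
indicators over the whole pregnancy — ultrasound scans (US), blood-pressure
measurements (BP), blood screenings (BS) — and whether those counts were
delivered in the recommended trimesters. The decision sequence, applied in
order so that every trajectory receives exactly one label:

1. **Inadequate** if the first visit falls after the timely-initiation
   cutoff (default 14 completed weeks; week 14 itself is timely, reading
   "after fourteen completed weeks" strictly).
2. **Inadequate** if some intervention total is below its lower range and
   no intervention total is above its upper range.
3. **Intermediate** if some intervention total is below its lower range
   while another is above its upper range (under-provision co-occurring
   with over-provision).
4. Otherwise (all lower ranges met): **Appropriate** if every per-trimester
   timing minimum is met, else **Sufficient**.

Defaults:

| parameter | default | note |
|---|---|---|
| initiation cutoff | 14 completed weeks | international consensus on the start of care |
| lower ranges | US 2, BP 6, BS 2 | guideline minima over the whole pregnancy |
| upper ranges | US 7, BP 10, BS 10 | implementation defaults near observed 75th percentiles; *not* guideline values — override for replication |
| trimester minima | T1: 1 US, 1 BP, 1 BS; T2: 1 US, 2 BP; T3: 3 BP, 1 BS | sums per intervention equal the lower ranges |
| trimester boundaries | T1 ≤ 14, T2 15–28, T3 ≥ 29 weeks | T1's end aligned with the initiation cutoff; configurable |

Deliberate conventions where the rule description is open to reading:

- A count exactly **equal** to an upper range is not exceedance
  ("above the range" is strict).
- **Appropriate** requires *all* trimester minima; a single timing failure
  yields Sufficient. This matches the definition of Appropriate as "the
  minimum package delivered at the recommended times".
- Exceeding an upper range while all lower ranges are met has no effect:
  the scale carries no over-use penalty.
- Timely initiation with zero recorded content falls through to step 2 and
  is Inadequate.
- Interventions count with multiplicity: two ultrasounds at one visit count
  as two. Consequently the CTP label is invariant to how a fixed
  (week, intervention) multiset is split across visit rows — CTP never
  counts visits (property-tested).
- Zero-visit trajectories are rejected with a distinct error rather than
  classified: women with no care at all belong in a separate no-care group
  that neither index defines.

### APNCU (Adequacy of Prenatal Care Utilization, Kotelchuck)

APNCU uses quantity only: the month care began and the ratio of observed
visits to the visits a guideline schedule recommends between initiation and
delivery. Late initiation (after the 4th month) is Inadequate outright;
otherwise the ratio bands are `<0.50` Inadequate, `[0.50, 0.80)`
Intermediate, `[0.80, 1.10)` Adequate, `>=1.10` Adequate plus. Two
conventions are fixed here:

- **Month→week mapping.** Months are not defined in week units by the
  index; we take month *m* to end at `floor(m × 4.345)` completed weeks, so
  "by the end of the 4th month" means initiation week ≤ 17. Both the
  cutoff month and the weeks-per-month factor are configurable.
- **The 110% boundary.** The band descriptions "80–109%" and "more than
  110%" leave exactly 110% unassigned; the standard convention (≥110% →
  Adequate plus) is used.

Expected visits are the schedule's template weeks falling in the inclusive
window `[initiation week, delivery week]`, floored at 1 (the initiation
visit itself is always expected, which also avoids division by zero for
very early deliveries). A config switch (`expected_basis="month"`) starts
the window at the first week of the initiation month instead — the original
registry convention — since it is not knowable from the index description
alone which of the two a given study used; week-based is the default.
Ratios are held as exact `Fraction`s so band boundaries (exactly 0.50,
0.80, 1.10) are classified without floating-point blur.

Two schedules ship built-in: the ACOG low-risk template (16 visit weeks:
monthly to 28, fortnightly to 36, weekly to 42) and a `belgian` template of
10 visits to week 40 (`8, 12, 16, 20, 24, 28, 31, 34, 37, 40`). The
authoritative Belgian guideline week list is not published alongside the
index; the shipped template reproduces the guideline's *count* of 10
recommended visits, which is what the index arithmetic consumes. Users
replicating against Belgian data should supply the authoritative list as a
YAML schedule.

## Comparison machinery

The two gradings of a cohort are compared on a 4×4 contingency table
(APNCU rows × CTP columns) with:

- marginal percentages, rounded **half-up** to one decimal (the convention
  of printed epidemiological tables; `Decimal`-based, not banker's
  rounding);
- per-APNCU-row agreement shares: the fraction of each row that CTP places
  in {Sufficient, Appropriate} versus {Inadequate, Intermediate};
- Pearson's chi-square test of independence, no continuity correction,
  after pruning all-zero rows/columns (dof = (r−1)(c−1) on the pruned
  table), with a `small_expected_flag` raised when any expected cell is
  below 5 — such tables (which realistic comparison tables are, given
  near-empty Inadequate rows) make the asymptotic p-value approximate.

## The synthetic cohort generator

No individual-level diary dataset of this kind is publicly deposited, so
the simulator emulates the reported care characteristics of such a cohort.
Calibration anchors (medians with quartiles in parentheses): initiation 7
(6–10) weeks, 11 (10–14) visits, delivery 40 (38–40) weeks. Only the
medians are treated as hard targets (±1 week/visit, Monte-Carlo tested at
n = 2000); the quartiles are matched approximately.

Generation per woman: delivery ~ discretised normal(39.6, 1.7²) truncated
to [22, 43]; initiation ~ discretised log-normal(median 7, σ = 0.38)
capped at 28 weeks (observed initiation in such cohorts spans roughly 0–28
weeks); visit weeks follow a guideline-like lattice from initiation (every
4 weeks, every 2 weeks from week 36) with ±1 week jitter plus
Poisson(2) extra visits; each intervention occurs at each visit as an
independent Bernoulli with per-trimester probabilities (defaults chosen so
whole-pregnancy intervention totals land near the reported medians of ~5
ultrasounds and ~8 blood-pressure readings; the reported blood-screening
mean and median disagree with each other in the source table — 4.6 vs
8 — and the defaults follow the general magnitude of the medians).

The distribution *families* are simulator choices: the emulated study
reports only summary statistics, so any family matching them is equally
defensible. The simulator does not model provider switching,
sociodemographic covariates, risk status, or missing-diary behaviour, and
the per-visit Bernoulli content model has no within-woman correlation —
real cohorts cluster content by provider. Passing calibration tests
therefore shows the classifiers behave correctly on cohorts with the right
marginal structure, not that the simulator reproduces any real cohort's
joint distribution; in particular the CTP/APNCU category proportions of
the `study_like` preset are in the broad neighbourhood of, but not equal
to, those a real cohort would produce.

Presets: `study_like` (the calibrated defaults), `all_appropriate`
(deterministic template meeting every minimum — 100% CTP Appropriate by
construction), `late_initiators` (initiation fixed at week 20 — Inadequate
under both tools), and `high_visits_low_content` (14 visits, intervention
probability 0.02 — graded Adequate/Adequate plus by APNCU but
Inadequate/Intermediate by CTP, the discordance pattern that motivates a
content-and-timing tool). All randomness flows from one integer seed
through one `numpy` generator; identical parameters and seed give an
identical cohort on any platform.

## Numerical and degenerate-input choices

- Gestational age is integer completed weeks throughout; calendar-date
  arithmetic is out of scope (diary dates are assumed pre-converted).
- Visit weeks are validated to [0, 45] and to not exceed the woman's
  delivery week; week-0 visits are accepted.
- Ties (two visits in the same week) are allowed and ordering among them is
  stable.
- Batch classification offers strict (first invalid woman aborts) and
  lenient (errors collected per woman) modes; CSV reading likewise.
- Problem sizes in the test suite — oracle grids of ~10⁵ (CTP) and ~10⁴
  (APNCU) cases, calibration at n = 2000 — were chosen as the smallest
  sizes at which the checks are decisive.

## Known limitations

- The CTP upper ranges and the Belgian visit-week template are
  implementation defaults, not published guideline values; replication
  studies must supply their own.
- The chi-square p-value on sparse 4×4 tables is asymptotic only (flagged).
- No kappa-style chance-corrected agreement, no risk adjustment, no
  no-care category, no association with birth outcomes — all deliberately
  out of scope for this iteration of the tool.
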
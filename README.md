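# carescore

Rule-based adequacy classification of antenatal care trajectories.

Health-services researchers grade how adequately a pregnant woman used
antenatal care from visit-level records. The long-standing standard, the
**APNCU index** (Kotelchuck), sees only *quantity*: the month care began
and the ratio of observed visits to the guideline-recommended number
adjusted for gestational age at delivery, banded into
Inadequate / Intermediate / Adequate / Adequate plus
(`<50%`, `50–79%`, `80–109%`, `≥110%` of recommended visits, with late
initiation — after the 4th month — Inadequate outright). A woman can
attend many visits yet never receive the basic clinical content of care,
and APNCU cannot see that.

The **CTP tool** (Content and Timing of care in Pregnancy) grades the same
trajectory from its *content and timing*: counts of ultrasound scans (US),
blood-pressure measurements (BP) and blood screenings (BS) against
guideline ranges (at least 2 US, 6 BP, 2 BS over the pregnancy), and
whether those minima were delivered in the recommended trimesters, giving
Inadequate / Intermediate / Sufficient / Appropriate:

1. care initiated after 14 completed weeks → **Inadequate**;
2. some intervention below its lower range, none above its upper range →
   **Inadequate**;
3. some intervention below its lower range while another exceeds its upper
   range → **Intermediate**;
4. all lower ranges met → **Appropriate** when every per-trimester timing
   minimum (T1: 1 US, 1 BP, 1 BS; T2: 1 US, 2 BP; T3: 3 BP, 1 BS) is also
   met, otherwise **Sufficient**.

`carescore` implements both classifiers over a validated visit-level CSV
model, a calibrated synthetic-cohort simulator (median initiation 7 weeks,
11 visits, delivery at 40 weeks), and the comparison machinery — 4×4
cross-tabulation, marginal percentages, per-row agreement shares, Pearson
chi-square — used to contrast the two gradings on one cohort. See
`docs/methods.md` for the full rule conventions and simulator model.

## Worked example

```python
from carescore import (
    Visit, CareTrajectory, Intervention as I,
    classify_ctp, classify_apncu, BELGIAN_SCHEDULE, visit_ratio,
)

woman = CareTrajectory(
    "w001",
    (
        Visit(8,  {I.US: 1, I.BP: 1, I.BS: 1}),   # booking: scan + bloods
        Visit(20, {I.US: 1, I.BP: 1}),            # anomaly scan
        Visit(30, {I.BP: 1, I.BS: 1}),
        Visit(34, {I.BP: 1}),
        Visit(36, {I.BP: 1}),
        Visit(38, {I.BP: 1}),
    ),
    ga_at_delivery=40,
)

ctp = classify_ctp(woman)
apncu = classify_apncu(woman, BELGIAN_SCHEDULE)
ratio = visit_ratio(woman, BELGIAN_SCHEDULE)
print(ctp.category.label, apncu.category.label,
      f"{ratio.observed}/{ratio.expected}")
print(ctp.rule_trace[-3:])
```

prints

```
Sufficient Intermediate 6/10
('timing:T3:BP:ok(4>=3)', 'timing:T3:BS:ok(1>=1)', 'decision:sufficient')
```

Content meets every whole-pregnancy minimum (2 US, 6 BP, 2 BS) but the
second-trimester minimum of 2 BP readings is missed, so CTP stops at
*Sufficient*; APNCU, seeing only 6 visits against 10 recommended between
week 8 and delivery (ratio 0.60), says *Intermediate*. The `rule_trace`
records every decision node so each label is auditable.

The same pipeline from the shell:

```sh
carescore simulate --preset study_like --n 333 --seed 42 --out cohort.csv
carescore classify --cohort cohort.csv --schedule belgian --out results.csv
carescore compare  --cohort cohort.csv --schedule belgian --out report.json
carescore dump-config ctp        # editable default CTP configuration
```

`report.json` contains the 4×4 APNCU×CTP table, both sets of marginal
percentages, the per-APNCU-row agreement split, and the chi-square block.

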
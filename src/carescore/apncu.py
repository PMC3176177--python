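"""Adequacy of Prenatal Care Utilization (APNCU / Kotelchuck) index.

The APNCU index grades a care trajectory on a four-level ordinal scale —
Inadequate < Intermediate < Adequate < Adequate plus — from *quantity* of
care only: the month care began and the ratio of observed visits to the
number of visits a guideline schedule recommends between initiation and
delivery.  Content of the visits is deliberately ignored.

Given timely initiation (by the end of the 4th month), the ratio bands are

=================  ==============
observed/expected  category
=================  ==============
< 0.50             Inadequate
0.50 – <0.80       Intermediate
0.80 – <1.10       Adequate
>= 1.10            Adequate plus
=================  ==============

Late initiation is Inadequate regardless of the ratio.  The expected count
is the number of recommended visit weeks falling in the inclusive window
[initiation week, delivery week], floored at 1 so that the initiation visit
itself is always expected.  Ratios are compared as exact fractions, so band
boundaries are never blurred by floating-point rounding.

Two schedules ship as defaults: the ACOG low-risk template (monthly to 28
weeks, fortnightly to 36, weekly to term) and a 10-visit template standing
in for the Belgian guideline.
"""

from __future__ import annotations

import enum
import math
from fractions import Fraction
from typing import List, Literal, Optional

from pydantic import BaseModel, model_validator

from .trajectory import (
    CareTrajectory,
    Cohort,
    UndefinedInitiationError,
    initiation_week,
)
from .ctp import BatchResult, ClassificationResult

__all__ = [
    "APNCUCategory",
    "APNCUSchedule",
    "VisitRatio",
    "ACOG_SCHEDULE",
    "BELGIAN_SCHEDULE",
    "builtin_schedule",
    "expected_visits",
    "visit_ratio",
    "classify_apncu",
    "classify_cohort_apncu",
]


class APNCUCategory(enum.IntEnum):
    """Ordinal APNCU categories, ordered worst to best."""

    INADEQUATE = 0
    INTERMEDIATE = 1
    ADEQUATE = 2
    ADEQUATE_PLUS = 3

    @property
    def label(self) -> str:
        return "Adequate plus" if self is APNCUCategory.ADEQUATE_PLUS \
            else self.name.capitalize()


class APNCUSchedule(BaseModel):
    """A recommended-visit schedule and initiation cutoff.

    ``visit_weeks`` is the guideline's template of recommended visit weeks;
    the expected count for a woman is the number of template weeks between
    her initiation and delivery.  ``initiation_month_cutoff`` is the latest
    month of pregnancy in which initiation still counts as timely;
    ``weeks_per_month`` converts it to a completed-week cutoff
    (floor(cutoff * weeks_per_month), 17 weeks under the defaults).

    ``expected_basis`` selects whether the expected-visit window starts at
    the exact initiation week ("week", default) or at the first week of the
    month of initiation ("month", the original registry convention).
    """

    name: str = "custom"
    visit_weeks: List[int]
    initiation_month_cutoff: int = 4
    weeks_per_month: float = 4.345
    expected_basis: Literal["week", "month"] = "week"

    @model_validator(mode="after")
    def _check_weeks(self) -> "APNCUSchedule":
        if not self.visit_weeks:
            raise ValueError("visit_weeks must be non-empty")
        if any(b <= a for a, b in zip(self.visit_weeks, self.visit_weeks[1:])):
            raise ValueError("visit_weeks must be strictly increasing")
        if self.visit_weeks[0] < 0 or self.visit_weeks[-1] > 45:
            raise ValueError("visit_weeks must lie within [0, 45]")
        return self

    @property
    def timely_week_cutoff(self) -> int:
        """Latest initiation week (completed) that still counts as timely."""
        return math.floor(self.initiation_month_cutoff * self.weeks_per_month)

    def month_of(self, week: int) -> int:
        """1-based month of pregnancy containing a completed week.

        Month m ends at floor(m * weeks_per_month) completed weeks, so the
        4th month ends at week 17 under the defaults — consistent with the
        timely-initiation cutoff.
        """
        return max(1, math.ceil(week / self.weeks_per_month))


#: ACOG low-risk schedule: monthly to 28 weeks, fortnightly to 36, weekly
#: thereafter.
ACOG_SCHEDULE = APNCUSchedule(
    name="acog",
    visit_weeks=[8, 12, 16, 20, 24, 28, 30, 32, 34, 36, 37, 38, 39, 40, 41, 42],
)

#: Ten-visit template standing in for the Belgian guideline schedule; the
#: authoritative week list is not published with the index, so replications
#: against Belgian data should supply their own template.
BELGIAN_SCHEDULE = APNCUSchedule(
    name="belgian",
    visit_weeks=[8, 12, 16, 20, 24, 28, 31, 34, 37, 40],
)


def builtin_schedule(name: str) -> APNCUSchedule:
    schedules = {"acog": ACOG_SCHEDULE, "belgian": BELGIAN_SCHEDULE}
    try:
        return schedules[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown schedule {name!r}; built-ins are {sorted(schedules)}"
        ) from None


class VisitRatio(BaseModel):
    """Observed and expected visit counts with their exact ratio."""

    observed: int
    expected: int
    ratio: Fraction

    model_config = {"arbitrary_types_allowed": True, "frozen": True}


def expected_visits(
    schedule: APNCUSchedule, initiation_week_: int, ga_at_delivery: int
) -> int:
    """Expected number of visits between initiation and delivery, >= 1."""
    if initiation_week_ > ga_at_delivery:
        raise ValueError(
            f"initiation week {initiation_week_} after delivery at "
            f"{ga_at_delivery}"
        )
    if schedule.expected_basis == "month":
        month = schedule.month_of(initiation_week_)
        low = 0 if month == 1 else (
            math.floor((month - 1) * schedule.weeks_per_month) + 1
        )
    else:
        low = initiation_week_
    n = sum(1 for w in schedule.visit_weeks if low <= w <= ga_at_delivery)
    return max(1, n)


_RATIO_BANDS = (
    (Fraction(1, 2), APNCUCategory.INADEQUATE),
    (Fraction(4, 5), APNCUCategory.INTERMEDIATE),
    (Fraction(11, 10), APNCUCategory.ADEQUATE),
)


def classify_apncu(
    trajectory: CareTrajectory, schedule: Optional[APNCUSchedule] = None
) -> ClassificationResult:
    """Assign one APNCU category to a care trajectory.

    Raises :class:`UndefinedInitiationError` for a zero-visit trajectory.
    """
    sched = schedule or ACOG_SCHEDULE
    trace: list[str] = []

    start = initiation_week(trajectory)
    observed = trajectory.n_visits
    expected = expected_visits(sched, start, trajectory.ga_at_delivery)
    ratio = Fraction(observed, expected)
    trace.append(f"observed:{observed}")
    trace.append(f"expected:{expected}(schedule={sched.name})")
    trace.append(f"ratio:{float(ratio):.3f}")

    if start > sched.timely_week_cutoff:
        trace.append(
            f"initiation:late(week {start} > {sched.timely_week_cutoff})"
        )
        trace.append("decision:inadequate")
        return ClassificationResult(
            trajectory.woman_id, APNCUCategory.INADEQUATE, tuple(trace)
        )
    trace.append(
        f"initiation:timely(week {start} <= {sched.timely_week_cutoff})"
    )

    category = APNCUCategory.ADEQUATE_PLUS
    for bound, cat in _RATIO_BANDS:
        if ratio < bound:
            category = cat
            break
    trace.append(f"decision:{category.label.lower().replace(' ', '_')}")
    return ClassificationResult(trajectory.woman_id, category, tuple(trace))


def visit_ratio(
    trajectory: CareTrajectory, schedule: Optional[APNCUSchedule] = None
) -> VisitRatio:
    """The observed/expected visit ratio underlying the APNCU label."""
    sched = schedule or ACOG_SCHEDULE
    start = initiation_week(trajectory)
    expected = expected_visits(sched, start, trajectory.ga_at_delivery)
    observed = trajectory.n_visits
    return VisitRatio(
        observed=observed, expected=expected,
        ratio=Fraction(observed, expected),
    )


def classify_cohort_apncu(
    cohort: Cohort, schedule: Optional[APNCUSchedule] = None,
    *, strict: bool = True,
) -> BatchResult:
    """Classify every trajectory in a cohort (see classify_cohort_ctp)."""
    out = BatchResult()
    for trajectory in cohort:
        try:
            out.results[trajectory.woman_id] = classify_apncu(
                trajectory, schedule
            )
        except UndefinedInitiationError as exc:
            if strict:
                raise
            out.errors[trajectory.woman_id] = str(exc)
    return out
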
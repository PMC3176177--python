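"""Shared fixtures and independent rule-table oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pytest

from carescore import (
    CareTrajectory,
    Cohort,
    CrossTab,
    Intervention,
    Visit,
)

I = Intervention

#: The published-style 4x4 comparison pattern used throughout the
#: comparison tests: APNCU rows (Inadequate, Intermediate, Adequate,
#: Adequate plus) by CTP columns (Inadequate, Intermediate, Sufficient,
#: Appropriate), n = 333.
TABLE2_COUNTS = np.array(
    [
        [8, 0, 0, 0],
        [9, 5, 3, 6],
        [9, 12, 51, 35],
        [8, 11, 66, 110],
    ]
)


@pytest.fixture
def table2() -> CrossTab:
    return CrossTab(TABLE2_COUNTS.copy(), int(TABLE2_COUNTS.sum()))


def make_trajectory(
    visits: Sequence[Tuple[int, Mapping[Intervention, int]]],
    ga_at_delivery: int = 40,
    woman_id: str = "w",
) -> CareTrajectory:
    """Build a trajectory from (week, {code: count}) pairs."""
    return CareTrajectory(
        woman_id,
        tuple(Visit(week, dict(counts)) for week, counts in visits),
        ga_at_delivery,
    )


def make_cohort(*trajectories: CareTrajectory) -> Cohort:
    return Cohort.from_trajectories(trajectories)


# ---------------------------------------------------------------------------
# Independent oracles: plain rule tables, written without reusing any of the
# package's decision code, against which the classifiers are checked.
# ---------------------------------------------------------------------------

CTP_LOWER = {I.US: 2, I.BP: 6, I.BS: 2}
CTP_UPPER = {I.US: 7, I.BP: 10, I.BS: 10}
# (trimester low, trimester high, code, minimum); T3 runs to delivery
CTP_TIMING = [
    (0, 14, I.US, 1), (0, 14, I.BP, 1), (0, 14, I.BS, 1),
    (15, 28, I.US, 1), (15, 28, I.BP, 2),
    (29, 99, I.BP, 3), (29, 99, I.BS, 1),
]


def ctp_oracle(trajectory: CareTrajectory) -> str:
    """Brute-force re-evaluation of the default CTP rule table."""
    weeks = [v.gestational_week for v in trajectory.visits]
    if min(weeks) > 14:
        return "Inadequate"
    totals = {code: 0 for code in I}
    for v in trajectory.visits:
        for code, n in v.interventions:
            totals[code] += n
    any_below = False
    any_above = False
    for code in I:
        if totals[code] < CTP_LOWER[code]:
            any_below = True
        if totals[code] > CTP_UPPER[code]:
            any_above = True
    if any_below and any_above:
        return "Intermediate"
    if any_below:
        return "Inadequate"
    for low, high, code, minimum in CTP_TIMING:
        got = 0
        for v in trajectory.visits:
            if low <= v.gestational_week <= high:
                got += v.count(code)
        if got < minimum:
            return "Sufficient"
    return "Appropriate"


def apncu_oracle(
    observed: int,
    initiation: int,
    delivery: int,
    visit_weeks: Sequence[int],
) -> str:
    """Table-driven re-evaluation of the APNCU bands (default cutoffs)."""
    expected = len([w for w in visit_weeks if initiation <= w <= delivery])
    expected = max(1, expected)
    ratio = Fraction(observed, expected)
    if initiation > 17 or ratio < Fraction(1, 2):
        return "Inadequate"
    if ratio < Fraction(4, 5):
        return "Intermediate"
    if ratio < Fraction(11, 10):
        return "Adequate"
    return "Adequate plus"
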
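"""Content and Timing of care in Pregnancy (CTP) classifier.

CTP grades an antenatal care trajectory on a four-level ordinal scale —
Inadequate < Intermediate < Sufficient < Appropriate — from three pieces of
information: when care started, how often each of three basic interventions
(ultrasound, blood pressure, blood screening) was received over the whole
pregnancy, and whether the per-trimester timing minima were met.

Decision sequence (each woman receives exactly one label):

1. Care initiated after the timely-initiation cutoff (default 14 completed
   weeks) -> **Inadequate**, regardless of content.
2. Some intervention total below its lower range and *no* intervention
   total above its upper range -> **Inadequate**.
3. Some intervention total below its lower range and some *other*
   intervention total above its upper range -> **Intermediate**
   (over-provision of one aspect alongside under-provision of another).
4. All intervention totals at or above their lower ranges -> **Appropriate**
   when every per-trimester timing minimum is also met, otherwise
   **Sufficient**.

Exceeding an upper range while all lower ranges are met has no effect: the
scale does not penalise over-use on its own.  "Above the upper range" is
read strictly (a count exactly equal to the upper bound is not exceedance).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from pydantic import BaseModel, Field, model_validator

from .trajectory import (
    CareTrajectory,
    Cohort,
    Intervention,
    Trimester,
    TrimesterBoundaries,
    UndefinedInitiationError,
    count_interventions,
    initiation_week,
)

__all__ = [
    "CTPCategory",
    "CTPConfig",
    "ClassificationResult",
    "BatchResult",
    "classify_ctp",
    "classify_cohort_ctp",
]


class CTPCategory(enum.IntEnum):
    """Ordinal CTP categories, ordered worst to best."""

    INADEQUATE = 0
    INTERMEDIATE = 1
    SUFFICIENT = 2
    APPROPRIATE = 3

    @property
    def label(self) -> str:
        return self.name.capitalize()


#: Lower ranges: the minimum recommended counts over the whole pregnancy
#: (at least 2 ultrasounds, 6 blood-pressure readings, 2 blood screenings).
DEFAULT_LOWER_RANGE: Dict[Intervention, int] = {
    Intervention.US: 2,
    Intervention.BP: 6,
    Intervention.BS: 2,
}

#: Upper ranges: counts above these flag over-provision in step 3.  These
#: are implementation defaults (chosen near observed 75th percentiles of
#: typical utilisation), not guideline values; override via CTPConfig.
DEFAULT_UPPER_RANGE: Dict[Intervention, int] = {
    Intervention.US: 7,
    Intervention.BP: 10,
    Intervention.BS: 10,
}

#: Per-trimester timing minima.  Their per-intervention sums equal the
#: lower ranges (US 1+1+0=2, BP 1+2+3=6, BS 1+0+1=2), so "Appropriate" is
#: exactly "the minimum package, delivered at the recommended times".
DEFAULT_TRIMESTER_MINIMA: Dict[Trimester, Dict[Intervention, int]] = {
    Trimester.T1: {Intervention.US: 1, Intervention.BP: 1, Intervention.BS: 1},
    Trimester.T2: {Intervention.US: 1, Intervention.BP: 2},
    Trimester.T3: {Intervention.BP: 3, Intervention.BS: 1},
}


class CTPConfig(BaseModel):
    """Tunable parameters of the CTP decision rule."""

    initiation_cutoff_weeks: int = 14
    lower_range: Dict[Intervention, int] = Field(
        default_factory=lambda: dict(DEFAULT_LOWER_RANGE)
    )
    upper_range: Dict[Intervention, int] = Field(
        default_factory=lambda: dict(DEFAULT_UPPER_RANGE)
    )
    trimester_minima: Dict[Trimester, Dict[Intervention, int]] = Field(
        default_factory=lambda: {
            t: dict(m) for t, m in DEFAULT_TRIMESTER_MINIMA.items()
        }
    )
    boundaries: TrimesterBoundaries = Field(default_factory=TrimesterBoundaries)

    @model_validator(mode="after")
    def _check_ranges(self) -> "CTPConfig":
        for code in Intervention:
            lo = self.lower_range.get(code, 0)
            hi = self.upper_range.get(code)
            if hi is not None and lo > hi:
                raise ValueError(
                    f"lower_range[{code.value}]={lo} exceeds "
                    f"upper_range[{code.value}]={hi}"
                )
            minima_sum = sum(
                m.get(code, 0) for m in self.trimester_minima.values()
            )
            if minima_sum != lo:
                raise ValueError(
                    f"trimester minima for {code.value} sum to {minima_sum}, "
                    f"but lower_range is {lo}"
                )
        return self


@dataclass(frozen=True)
class ClassificationResult:
    """A category label plus the ordered trace of decision nodes that fired."""

    woman_id: str
    category: enum.IntEnum
    rule_trace: Tuple[str, ...] = ()


@dataclass
class BatchResult:
    """Per-woman results of a cohort classification, with per-woman errors."""

    results: Dict[str, ClassificationResult] = field(default_factory=dict)
    errors: Dict[str, str] = field(default_factory=dict)


def classify_ctp(
    trajectory: CareTrajectory, config: Optional[CTPConfig] = None
) -> ClassificationResult:
    """Assign one CTP category to a care trajectory.

    Raises :class:`UndefinedInitiationError` for a zero-visit trajectory.
    """
    cfg = config or CTPConfig()
    trace: list[str] = []

    start = initiation_week(trajectory)
    if start > cfg.initiation_cutoff_weeks:
        trace.append(
            f"initiation:late(week {start} > {cfg.initiation_cutoff_weeks})"
        )
        trace.append("decision:inadequate")
        return ClassificationResult(
            trajectory.woman_id, CTPCategory.INADEQUATE, tuple(trace)
        )
    trace.append(
        f"initiation:timely(week {start} <= {cfg.initiation_cutoff_weeks})"
    )

    totals = {
        code: count_interventions(trajectory, code) for code in Intervention
    }
    below = [c for c in Intervention if totals[c] < cfg.lower_range.get(c, 0)]
    above = [
        c
        for c in Intervention
        if c in cfg.upper_range and totals[c] > cfg.upper_range[c]
    ]
    trace.append(
        "totals:" + ",".join(f"{c.value}={totals[c]}" for c in Intervention)
    )
    if below:
        trace.append("lower_range:below(" + ",".join(c.value for c in below) + ")")
        if above:
            trace.append(
                "upper_range:exceeded(" + ",".join(c.value for c in above) + ")"
            )
            trace.append("decision:intermediate")
            return ClassificationResult(
                trajectory.woman_id, CTPCategory.INTERMEDIATE, tuple(trace)
            )
        trace.append("upper_range:none_exceeded")
        trace.append("decision:inadequate")
        return ClassificationResult(
            trajectory.woman_id, CTPCategory.INADEQUATE, tuple(trace)
        )

    trace.append("lower_range:all_met")
    timing_ok = True
    for trimester, minima in cfg.trimester_minima.items():
        window = cfg.boundaries.window(trimester)
        for code, minimum in minima.items():
            got = count_interventions(trajectory, code, window)
            if got < minimum:
                timing_ok = False
                trace.append(
                    f"timing:{trimester.value}:{code.value}:fail({got}<{minimum})"
                )
            else:
                trace.append(
                    f"timing:{trimester.value}:{code.value}:ok({got}>={minimum})"
                )
    if timing_ok:
        trace.append("decision:appropriate")
        category = CTPCategory.APPROPRIATE
    else:
        trace.append("decision:sufficient")
        category = CTPCategory.SUFFICIENT
    return ClassificationResult(trajectory.woman_id, category, tuple(trace))


def classify_cohort_ctp(
    cohort: Cohort, config: Optional[CTPConfig] = None, *, strict: bool = True
) -> BatchResult:
    """Classify every trajectory in a cohort.

    In strict mode a per-woman error (e.g. a zero-visit trajectory) aborts
    the batch; in lenient mode it is recorded under ``errors`` and the rest
    of the cohort is still classified.  Results are deterministic and
    independent of iteration order.
    """
    out = BatchResult()
    for trajectory in cohort:
        try:
            out.results[trajectory.woman_id] = classify_ctp(trajectory, config)
        except UndefinedInitiationError as exc:
            if strict:
                raise
            out.errors[trajectory.woman_id] = str(exc)
    return out
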
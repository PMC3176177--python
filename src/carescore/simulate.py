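"""Synthetic antenatal-care cohort generator.

No individual-level antenatal diary data are publicly deposited for this
kind of study, so the package ships a simulator that emulates the care
characteristics such cohorts report: median initiation of care at 7
completed weeks (IQR 6-10), a median of 11 antenatal visits (IQR 10-14),
and median delivery at 40 completed weeks (IQR 38-40).

A woman is generated in three steps:

1. draw gestational age at delivery (discretised truncated normal on
   [22, 43] weeks by default);
2. draw the initiation week (discretised log-normal, capped at 28 weeks —
   observed initiation in such cohorts spans roughly 0 to 28 weeks);
3. lay out visit weeks from a guideline-like schedule (every 4 weeks, then
   every 2 weeks near term) with +/-1 week of jitter plus a Poisson number
   of extra unscheduled visits, and at each visit draw each intervention
   (ultrasound, blood pressure, blood screening) as an independent
   Bernoulli with a per-trimester probability.

Only the location/spread targets above are calibrated; the distribution
families, the jitter and the intervention probabilities are simulator
choices.  Named presets cover the study-like cohort and three boundary
scenarios (all-appropriate care, uniformly late initiation, and the
discordant many-visits-but-little-content pattern that separates a
quantity-only index from a content-and-timing tool).
"""

from __future__ import annotations

import math
from typing import Dict, List, Literal, Optional, Union

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .trajectory import (
    CareScoreError,
    CareTrajectory,
    Cohort,
    Intervention,
    Trimester,
    TrimesterBoundaries,
    Visit,
    trimester_of,
)

__all__ = [
    "ParameterError",
    "FixedWeeks",
    "LogNormalWeeks",
    "TruncNormalWeeks",
    "GuidelineJitterVisits",
    "FixedTemplateVisits",
    "CohortSimParams",
    "simulate_cohort",
    "preset_scenarios",
]


class ParameterError(CareScoreError):
    """Simulator parameters are invalid or infeasible."""


class FixedWeeks(BaseModel):
    """Degenerate distribution: every draw is ``value`` weeks."""

    family: Literal["fixed"] = "fixed"
    value: int

    def sample(self, rng: np.random.Generator) -> int:
        return self.value

    @property
    def min_possible(self) -> int:
        return self.value


class LogNormalWeeks(BaseModel):
    """Discretised log-normal over completed weeks, clipped to a range."""

    family: Literal["lognormal"] = "lognormal"
    median: float = 7.0
    sigma: float = 0.38
    min_week: int = 0
    max_week: int = 28

    def sample(self, rng: np.random.Generator) -> int:
        x = rng.lognormal(mean=math.log(self.median), sigma=self.sigma)
        return int(np.clip(round(x), self.min_week, self.max_week))

    @property
    def min_possible(self) -> int:
        return self.min_week


class TruncNormalWeeks(BaseModel):
    """Discretised normal over completed weeks, truncated by rejection."""

    family: Literal["truncnorm"] = "truncnorm"
    mean: float = 39.6
    sd: float = 1.7
    low: int = 22
    high: int = 43

    def sample(self, rng: np.random.Generator) -> int:
        for _ in range(10_000):
            w = round(rng.normal(self.mean, self.sd))
            if self.low <= w <= self.high:
                return int(w)
        raise ParameterError(
            f"truncation [{self.low}, {self.high}] rejects essentially all "
            f"draws from N({self.mean}, {self.sd}^2)"
        )

    @property
    def min_possible(self) -> int:
        return self.low


WeekDistribution = Union[FixedWeeks, LogNormalWeeks, TruncNormalWeeks]


class GuidelineJitterVisits(BaseModel):
    """Schedule-with-jitter visit process.

    Visits run from initiation every ``interval_early`` weeks, switching to
    ``interval_late`` from ``switch_week``; each scheduled week is jittered
    by up to ``jitter`` weeks and a Poisson(``extra_mean``) number of extra
    visits is scattered uniformly over the care window.
    """

    kind: Literal["guideline_jitter"] = "guideline_jitter"
    interval_early: int = 4
    interval_late: int = 2
    switch_week: int = 36
    jitter: int = 1
    extra_mean: float = 2.0

    def weeks(
        self, initiation: int, delivery: int, rng: np.random.Generator
    ) -> List[int]:
        weeks = [initiation]
        w = initiation
        while True:
            step = (
                self.interval_late if w >= self.switch_week
                else self.interval_early
            )
            w += step
            if w > delivery:
                break
            jittered = w + int(rng.integers(-self.jitter, self.jitter + 1))
            weeks.append(int(np.clip(jittered, initiation, delivery)))
        n_extra = int(rng.poisson(self.extra_mean))
        for _ in range(n_extra):
            weeks.append(int(rng.integers(initiation, delivery + 1)))
        return sorted(weeks)


class FixedTemplateVisits(BaseModel):
    """Deterministic visit process: the template weeks, clipped to care window."""

    kind: Literal["fixed_template"] = "fixed_template"
    template: List[int]

    def weeks(
        self, initiation: int, delivery: int, rng: np.random.Generator
    ) -> List[int]:
        weeks = [initiation] + [
            w for w in self.template if initiation < w <= delivery
        ]
        return sorted(weeks)


VisitProcess = Union[GuidelineJitterVisits, FixedTemplateVisits]

#: Per-trimester per-visit intervention probabilities for the study-like
#: cohort: booking bloods and a dating scan cluster early, blood pressure
#: is near-routine at every visit throughout.
DEFAULT_INTERVENTION_PROBS: Dict[Trimester, Dict[Intervention, float]] = {
    Trimester.T1: {
        Intervention.US: 0.80, Intervention.BP: 0.85, Intervention.BS: 0.90,
    },
    Trimester.T2: {
        Intervention.US: 0.50, Intervention.BP: 0.80, Intervention.BS: 0.60,
    },
    Trimester.T3: {
        Intervention.US: 0.35, Intervention.BP: 0.85, Intervention.BS: 0.60,
    },
}


class CohortSimParams(BaseModel):
    """Full parameterisation of one simulated cohort."""

    n_women: int = 333
    seed: int = 0
    initiation_dist: WeekDistribution = Field(
        default_factory=LogNormalWeeks, discriminator="family"
    )
    delivery_dist: WeekDistribution = Field(
        default_factory=TruncNormalWeeks, discriminator="family"
    )
    visit_process: VisitProcess = Field(
        default_factory=GuidelineJitterVisits, discriminator="kind"
    )
    intervention_probs: Dict[Trimester, Dict[Intervention, float]] = Field(
        default_factory=lambda: {
            t: dict(p) for t, p in DEFAULT_INTERVENTION_PROBS.items()
        }
    )
    boundaries: TrimesterBoundaries = Field(default_factory=TrimesterBoundaries)

    @model_validator(mode="after")
    def _check(self) -> "CohortSimParams":
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        for t, probs in self.intervention_probs.items():
            for code, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"intervention_probs[{t.value}][{code.value}]={p} "
                        "outside [0, 1]"
                    )
        return self


def _feasible(params: CohortSimParams) -> None:
    init_min = params.initiation_dist.min_possible
    if isinstance(params.delivery_dist, FixedWeeks):
        delivery_max = params.delivery_dist.value
    elif isinstance(params.delivery_dist, TruncNormalWeeks):
        delivery_max = params.delivery_dist.high
    else:
        delivery_max = params.delivery_dist.max_week
    if init_min > delivery_max:
        raise ParameterError(
            f"initiation distribution starts at week {init_min}, after the "
            f"latest possible delivery (week {delivery_max})"
        )


def simulate_cohort(
    params: CohortSimParams,
    *,
    n_women: Optional[int] = None,
    seed: Optional[int] = None,
) -> Cohort:
    """Generate a validated synthetic cohort.

    ``n_women`` and ``seed`` override the corresponding fields in
    ``params``.  Identical parameters and seed yield an identical cohort.
    """
    _feasible(params)
    n = n_women if n_women is not None else params.n_women
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    trajectories: dict[str, CareTrajectory] = {}
    for i in range(n):
        delivery = params.delivery_dist.sample(rng)
        for _ in range(1000):
            initiation = params.initiation_dist.sample(rng)
            if initiation <= delivery:
                break
        else:
            raise ParameterError(
                "could not draw an initiation week at or before delivery "
                f"(delivery at week {delivery})"
            )
        visits = []
        for week in params.visit_process.weeks(initiation, delivery, rng):
            trimester = trimester_of(week, params.boundaries)
            probs = params.intervention_probs.get(trimester, {})
            counts = {
                code: int(rng.random() < probs.get(code, 0.0))
                for code in Intervention
            }
            visits.append(Visit(week, counts, scheduled=None))
        woman_id = f"w{i:05d}"
        trajectories[woman_id] = CareTrajectory(
            woman_id, tuple(visits), delivery
        )
    return Cohort(trajectories)


def preset_scenarios() -> Dict[str, CohortSimParams]:
    """Named parameter sets for common scenarios.

    - ``study_like``: the calibrated defaults (initiation ~7 weeks, ~11
      visits, delivery ~40 weeks).
    - ``all_appropriate``: timely initiation with a deterministic visit
      template that satisfies every content and timing minimum.
    - ``late_initiators``: first visit fixed at week 20 — late under both
      tools.
    - ``high_visits_low_content``: many visits (high observed/expected
      ratio) but almost no tracked interventions, the pattern on which a
      quantity-only index and a content-and-timing tool disagree.
    """
    full = {
        t: {Intervention.US: 1.0, Intervention.BP: 1.0, Intervention.BS: 1.0}
        for t in Trimester
    }
    sparse = {
        t: {Intervention.US: 0.02, Intervention.BP: 0.02, Intervention.BS: 0.02}
        for t in Trimester
    }
    return {
        "study_like": CohortSimParams(),
        "all_appropriate": CohortSimParams(
            initiation_dist=FixedWeeks(value=8),
            delivery_dist=FixedWeeks(value=40),
            visit_process=FixedTemplateVisits(
                template=[8, 16, 20, 30, 33, 36, 39]
            ),
            intervention_probs=full,
        ),
        "late_initiators": CohortSimParams(
            initiation_dist=FixedWeeks(value=20),
        ),
        "high_visits_low_content": CohortSimParams(
            initiation_dist=FixedWeeks(value=7),
            delivery_dist=FixedWeeks(value=40),
            visit_process=FixedTemplateVisits(
                template=[7, 10, 13, 16, 19, 22, 25, 28, 30, 32, 34, 36, 38, 40]
            ),
            intervention_probs=sparse,
        ),
    }
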
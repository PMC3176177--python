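"""Domain model for antenatal care trajectories and validated CSV I/O.

The unit of analysis is one woman's *care trajectory*: the ordered sequence
of antenatal visits she attended, the gestational week of each visit, which
of three tracked interventions (ultrasound scan, blood-pressure measurement,
blood screening) were performed at each visit, and her gestational age at
delivery.  Gestational age is always expressed in completed weeks.

Trajectories are exchanged as a flat CSV with one row per visit::

    woman_id,gestational_week,us,bp,bs,ga_at_delivery,scheduled

where ``us``/``bp``/``bs`` are non-negative integer counts of each
intervention at that visit, ``ga_at_delivery`` is repeated (and must be
consistent) across a woman's rows, and ``scheduled`` is ``0``, ``1`` or
``NA``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple

import pandas as pd
from pydantic import BaseModel, model_validator

__all__ = [
    "Intervention",
    "Trimester",
    "TrimesterBoundaries",
    "Visit",
    "CareTrajectory",
    "Cohort",
    "ParseReport",
    "CareScoreError",
    "CohortFormatError",
    "TrajectoryValidationError",
    "UndefinedInitiationError",
    "CSV_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "initiation_week",
    "count_interventions",
    "trimester_of",
]

MAX_GESTATIONAL_WEEK = 45

CSV_COLUMNS = (
    "woman_id",
    "gestational_week",
    "us",
    "bp",
    "bs",
    "ga_at_delivery",
    "scheduled",
)


class CareScoreError(Exception):
    """Base class for all errors raised by this package."""


class CohortFormatError(CareScoreError):
    """The input file does not match the documented CSV schema."""


class TrajectoryValidationError(CareScoreError):
    """A record violates a trajectory invariant (names the offender)."""


class UndefinedInitiationError(CareScoreError):
    """A trajectory with zero visits has no initiation week.

    Women with no recorded antenatal care are deliberately *not* classified:
    they belong in a separate no-care group, which neither classifier
    defines.  Callers must handle this error explicitly.
    """


class Intervention(str, enum.Enum):
    """The three tracked content-of-care indicators."""

    US = "US"  #: ultrasound scan
    BP = "BP"  #: blood-pressure measurement
    BS = "BS"  #: blood screening

    @classmethod
    def parse(cls, code: str) -> "Intervention":
        try:
            return cls(code.upper())
        except ValueError:
            raise TrajectoryValidationError(
                f"unknown intervention code {code!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


class Trimester(str, enum.Enum):
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"


class TrimesterBoundaries(BaseModel):
    """Trimester windows in completed weeks (inclusive upper ends).

    T1 = [0, t1_end], T2 = [t1_end+1, t2_end], T3 = [t2_end+1, delivery].
    The default first-trimester end of 14 completed weeks is aligned with
    the timely-initiation cutoff used by the content-and-timing classifier.
    """

    t1_end: int = 14
    t2_end: int = 28

    @model_validator(mode="after")
    def _check_order(self) -> "TrimesterBoundaries":
        if not 0 < self.t1_end < self.t2_end:
            raise ValueError("boundaries must satisfy 0 < t1_end < t2_end")
        return self

    def window(self, trimester: Trimester) -> Tuple[int, Optional[int]]:
        """Inclusive (low, high) week window; T3's high is open (None)."""
        if trimester is Trimester.T1:
            return (0, self.t1_end)
        if trimester is Trimester.T2:
            return (self.t1_end + 1, self.t2_end)
        return (self.t2_end + 1, None)


def trimester_of(
    gestational_week: int, boundaries: Optional[TrimesterBoundaries] = None
) -> Trimester:
    """Map a completed gestational week to exactly one trimester."""
    if gestational_week < 0:
        raise ValueError("gestational_week must be non-negative")
    b = boundaries or TrimesterBoundaries()
    if gestational_week <= b.t1_end:
        return Trimester.T1
    if gestational_week <= b.t2_end:
        return Trimester.T2
    return Trimester.T3


def _freeze_counts(
    interventions: Mapping[Intervention, int] | Iterable[Intervention] | None,
) -> Tuple[Tuple[Intervention, int], ...]:
    """Normalise an intervention multiset to a sorted tuple of (code, n)."""
    counts: dict[Intervention, int] = {}
    if interventions is None:
        pass
    elif isinstance(interventions, Mapping):
        for code, n in interventions.items():
            code = Intervention(code)
            n = int(n)
            if n < 0:
                raise TrajectoryValidationError(
                    f"negative count {n} for intervention {code.value}"
                )
            if n:
                counts[code] = counts.get(code, 0) + n
    else:
        for code in interventions:
            code = Intervention(code)
            counts[code] = counts.get(code, 0) + 1
    return tuple(sorted(counts.items(), key=lambda kv: kv[0].value))


@dataclass(frozen=True)
class Visit:
    """One antenatal visit: its week and the interventions performed.

    A visit with an empty intervention multiset is still a visit — it counts
    toward the visit-based APNCU index even though it contributes nothing to
    the content-based CTP counts.
    """

    gestational_week: int
    interventions: Tuple[Tuple[Intervention, int], ...] = ()
    scheduled: Optional[bool] = None

    def __post_init__(self) -> None:
        if not 0 <= self.gestational_week <= MAX_GESTATIONAL_WEEK:
            raise TrajectoryValidationError(
                f"gestational_week {self.gestational_week} outside "
                f"[0, {MAX_GESTATIONAL_WEEK}]"
            )
        object.__setattr__(
            self, "interventions", _freeze_counts(self.interventions)
        )

    def count(self, code: Intervention) -> int:
        for c, n in self.interventions:
            if c is code:
                return n
        return 0


@dataclass(frozen=True)
class CareTrajectory:
    """One woman's ordered antenatal visits plus gestational age at delivery."""

    woman_id: str
    visits: Tuple[Visit, ...]
    ga_at_delivery: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "visits",
            tuple(sorted(self.visits, key=lambda v: v.gestational_week)),
        )
        if not 0 <= self.ga_at_delivery <= MAX_GESTATIONAL_WEEK:
            raise TrajectoryValidationError(
                f"woman {self.woman_id!r}: ga_at_delivery "
                f"{self.ga_at_delivery} outside [0, {MAX_GESTATIONAL_WEEK}]"
            )
        for v in self.visits:
            if v.gestational_week > self.ga_at_delivery:
                raise TrajectoryValidationError(
                    f"woman {self.woman_id!r}: visit at week "
                    f"{v.gestational_week} after delivery at week "
                    f"{self.ga_at_delivery}"
                )

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def initiation_week(self) -> int:
        return initiation_week(self)


def initiation_week(trajectory: CareTrajectory) -> int:
    """Gestational week of the first antenatal visit.

    Raises :class:`UndefinedInitiationError` for a zero-visit trajectory.
    """
    if not trajectory.visits:
        raise UndefinedInitiationError(
            f"woman {trajectory.woman_id!r} has no recorded visits; "
            "initiation of care is undefined (no-care group)"
        )
    return min(v.gestational_week for v in trajectory.visits)


def count_interventions(
    trajectory: CareTrajectory,
    code: Intervention,
    window: Optional[Tuple[int, Optional[int]]] = None,
) -> int:
    """Count occurrences of one intervention, optionally within a week window.

    ``window`` is an inclusive ``(low, high)`` pair of completed weeks; a
    ``high`` of ``None`` means "to the end of pregnancy".  ``window=None``
    counts over the whole pregnancy.  A visit contributes the multiplicity
    recorded for the code.
    """
    if window is None:
        low, high = 0, None
    else:
        low, high = window
        if low < 0 or (high is not None and high < low):
            raise ValueError(f"invalid window {window!r}")
    total = 0
    for v in trajectory.visits:
        if v.gestational_week < low:
            continue
        if high is not None and v.gestational_week > high:
            continue
        total += v.count(code)
    return total


@dataclass
class ParseReport:
    """Rows or women skipped while reading a cohort file, with reasons."""

    skipped: list[str] = field(default_factory=list)

    def add(self, reason: str) -> None:
        self.skipped.append(reason)


@dataclass
class Cohort:
    """A collection of care trajectories keyed by unique woman_id."""

    trajectories: dict[str, CareTrajectory] = field(default_factory=dict)
    parse_report: Optional[ParseReport] = field(default=None, compare=False)

    @classmethod
    def from_trajectories(cls, trajectories: Iterable[CareTrajectory]) -> "Cohort":
        out: dict[str, CareTrajectory] = {}
        for t in trajectories:
            if t.woman_id in out:
                raise TrajectoryValidationError(
                    f"duplicate woman_id {t.woman_id!r}"
                )
            out[t.woman_id] = t
        return cls(out)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[CareTrajectory]:
        return iter(self.trajectories.values())

    def __getitem__(self, woman_id: str) -> CareTrajectory:
        return self.trajectories[woman_id]


def _parse_count(value: object, column: str, rowno: int) -> int:
    try:
        n = int(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise TrajectoryValidationError(
            f"row {rowno}: {column} value {value!r} is not a non-negative "
            f"integer intervention count"
        ) from None
    if n < 0:
        raise TrajectoryValidationError(
            f"row {rowno}: {column} count {n} is negative"
        )
    return n


def read_cohort_csv(
    path, *, strict: bool = True, dialect: Optional[dict] = None
) -> Cohort:
    """Read a visit-level cohort CSV into a validated :class:`Cohort`.

    In strict mode (default) the first invalid record raises.  In lenient
    mode invalid women are dropped and listed in ``cohort.parse_report``.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False,
                            **(dialect or {}))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise CohortFormatError(f"cannot parse {path}: {exc}") from exc

    missing = [c for c in CSV_COLUMNS if c not in frame.columns and c != "scheduled"]
    if missing:
        raise CohortFormatError(
            f"{path}: missing required column(s) {missing}"
        )
    has_scheduled = "scheduled" in frame.columns

    report = ParseReport()
    per_woman: dict[str, list[Visit]] = {}
    per_woman_ga: dict[str, int] = {}
    bad_women: set[str] = set()

    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        woman = str(getattr(row, "woman_id"))
        try:
            week = _parse_count(getattr(row, "gestational_week"),
                                "gestational_week", idx)
            ga_raw = getattr(row, "ga_at_delivery")
            if ga_raw in ("", "NA"):
                raise TrajectoryValidationError(
                    f"woman {woman!r}: ga_at_delivery missing on row {idx}"
                )
            ga = _parse_count(ga_raw, "ga_at_delivery", idx)
            counts = {
                Intervention.US: _parse_count(getattr(row, "us"), "us", idx),
                Intervention.BP: _parse_count(getattr(row, "bp"), "bp", idx),
                Intervention.BS: _parse_count(getattr(row, "bs"), "bs", idx),
            }
            scheduled: Optional[bool] = None
            if has_scheduled:
                s = str(getattr(row, "scheduled")).strip()
                if s in ("", "NA", "nan"):
                    scheduled = None
                elif s in ("0", "1"):
                    scheduled = bool(int(s))
                else:
                    raise TrajectoryValidationError(
                        f"row {idx}: scheduled value {s!r} not in {{0,1,NA}}"
                    )
            if woman in per_woman_ga and per_woman_ga[woman] != ga:
                raise TrajectoryValidationError(
                    f"woman {woman!r}: inconsistent ga_at_delivery "
                    f"({per_woman_ga[woman]} vs {ga} on row {idx})"
                )
            visit = Visit(week, counts, scheduled)
        except TrajectoryValidationError as exc:
            if strict:
                raise
            bad_women.add(woman)
            report.add(str(exc))
            continue
        per_woman_ga[woman] = ga
        per_woman.setdefault(woman, []).append(visit)

    trajectories: dict[str, CareTrajectory] = {}
    for woman in sorted(per_woman):
        if woman in bad_women:
            continue
        try:
            trajectories[woman] = CareTrajectory(
                woman, tuple(per_woman[woman]), per_woman_ga[woman]
            )
        except TrajectoryValidationError as exc:
            if strict:
                raise
            report.add(str(exc))
    return Cohort(trajectories, parse_report=report)


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort as one CSV row per visit, deterministically ordered."""
    rows = []
    for woman_id in sorted(cohort.trajectories):
        t = cohort.trajectories[woman_id]
        for v in t.visits:
            rows.append(
                {
                    "woman_id": woman_id,
                    "gestational_week": v.gestational_week,
                    "us": v.count(Intervention.US),
                    "bp": v.count(Intervention.BP),
                    "bs": v.count(Intervention.BS),
                    "ga_at_delivery": t.ga_at_delivery,
                    "scheduled": (
                        "NA" if v.scheduled is None else int(v.scheduled)
                    ),
                }
            )
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    frame.to_csv(path, index=False)
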
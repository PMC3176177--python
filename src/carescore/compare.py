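"""Cross-tabulation and agreement analysis of the two classifications.

The two tools grade the same cohort on different four-level scales, so the
natural comparison is a 4x4 contingency table with APNCU categories as rows
and CTP categories as columns, together with

* marginal percentages per category on either axis (rounded half-up, as
  epidemiological tables conventionally print them),
* per-APNCU-row agreement shares — the fraction of each APNCU row that CTP
  places in its upper half (Sufficient or Appropriate) versus its lower
  half (Inadequate or Intermediate), and
* Pearson's chi-square test of independence (no continuity correction),
  with a warning flag when any expected cell is below 5, since sparse
  cells make the asymptotic p-value approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .apncu import APNCUCategory
from .ctp import CTPCategory
from .trajectory import CareScoreError

__all__ = [
    "CrossTab",
    "ChiSquareResult",
    "AgreementRow",
    "DegenerateTableError",
    "cross_tabulate",
    "marginal_proportions",
    "agreement_summary",
    "chi_square",
]

APNCU_ORDER: Tuple[APNCUCategory, ...] = tuple(APNCUCategory)
CTP_ORDER: Tuple[CTPCategory, ...] = tuple(CTPCategory)


class DegenerateTableError(CareScoreError):
    """The table collapses to a single row or column; no test is defined."""


@dataclass(frozen=True)
class CrossTab:
    """4x4 contingency table: APNCU categories (rows) x CTP (columns)."""

    counts: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(APNCU_ORDER), len(CTP_ORDER)):
            raise ValueError(f"expected a 4x4 table, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("cell counts must be non-negative")
        if counts.sum() != self.n_total:
            raise ValueError(
                f"cells sum to {counts.sum()} but n_total={self.n_total}"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrossTab):
            return NotImplemented
        return self.n_total == other.n_total and bool(
            (self.counts == other.counts).all()
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float
    expected_counts: np.ndarray
    small_expected_flag: bool


@dataclass(frozen=True)
class AgreementRow:
    """How one APNCU row splits across the upper/lower halves of CTP."""

    row_total: int
    sufficient_or_appropriate: int
    inadequate_or_intermediate: int

    @property
    def share_upper(self) -> Optional[float]:
        if self.row_total == 0:
            return None
        return self.sufficient_or_appropriate / self.row_total

    @property
    def share_lower(self) -> Optional[float]:
        if self.row_total == 0:
            return None
        return self.inadequate_or_intermediate / self.row_total


def cross_tabulate(
    apncu_labels: Mapping[str, APNCUCategory],
    ctp_labels: Mapping[str, CTPCategory],
) -> CrossTab:
    """Joint frequency table of the two label assignments.

    Both mappings must cover exactly the same women.
    """
    a_keys, c_keys = set(apncu_labels), set(ctp_labels)
    if a_keys != c_keys:
        diff = sorted(a_keys.symmetric_difference(c_keys))
        raise CareScoreError(
            f"label mappings cover different women: {diff[:10]}"
            + ("..." if len(diff) > 10 else "")
        )
    counts = np.zeros((len(APNCU_ORDER), len(CTP_ORDER)), dtype=int)
    for woman_id, apncu in apncu_labels.items():
        counts[int(apncu), int(ctp_labels[woman_id])] += 1
    return CrossTab(counts, len(apncu_labels))


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def marginal_proportions(
    tab: CrossTab, axis: str = "columns", decimals: int = 1
) -> Dict[str, float]:
    """Marginal percentages per category along one axis.

    ``axis`` is ``"rows"`` (APNCU) or ``"columns"`` (CTP).  Percentages are
    rounded half-up to ``decimals`` places.
    """
    if tab.n_total == 0:
        raise CareScoreError("proportions undefined for an empty table")
    if axis == "rows":
        totals: Sequence[int] = tab.row_totals
        labels = [c.label for c in APNCU_ORDER]
    elif axis == "columns":
        totals = tab.col_totals
        labels = [c.label for c in CTP_ORDER]
    else:
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    return {
        label: _round_half_up(100.0 * n / tab.n_total, decimals)
        for label, n in zip(labels, totals)
    }


def agreement_summary(tab: CrossTab) -> Dict[str, AgreementRow]:
    """Per-APNCU-row split across the upper/lower halves of the CTP scale.

    Rows with zero total are still reported; their shares are ``None``.
    """
    upper = [int(CTPCategory.SUFFICIENT), int(CTPCategory.APPROPRIATE)]
    lower = [int(CTPCategory.INADEQUATE), int(CTPCategory.INTERMEDIATE)]
    out: Dict[str, AgreementRow] = {}
    for cat in APNCU_ORDER:
        row = tab.counts[int(cat)]
        out[cat.label] = AgreementRow(
            row_total=int(row.sum()),
            sufficient_or_appropriate=int(row[upper].sum()),
            inadequate_or_intermediate=int(row[lower].sum()),
        )
    return out


def chi_square(tab: CrossTab) -> ChiSquareResult:
    """Pearson chi-square test of independence on the cross-tabulation.

    All-zero rows and columns are dropped before testing (they carry no
    information and would produce zero expected counts).  No continuity
    correction is applied.
    """
    if tab.n_total == 0:
        raise DegenerateTableError("empty table")
    keep_rows = tab.row_totals > 0
    keep_cols = tab.col_totals > 0
    pruned = tab.counts[np.ix_(keep_rows, keep_cols)]
    if pruned.shape[0] < 2 or pruned.shape[1] < 2:
        raise DegenerateTableError(
            "chi-square needs at least two non-empty rows and columns "
            f"(got {pruned.shape[0]}x{pruned.shape[1]})"
        )
    statistic, p_value, dof, expected = stats.chi2_contingency(
        pruned, correction=False
    )
    return ChiSquareResult(
        statistic=float(statistic),
        dof=int(dof),
        p_value=float(p_value),
        expected_counts=np.asarray(expected),
        small_expected_flag=bool((np.asarray(expected) < 5).any()),
    )
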
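"""Cohort summaries: matching grades per probability category, search
times, and the prospective-DPB1 worked example.

Counts are exact integers; means and percentages are rounded half-up to
the stated precision (percentages and per-category means to the number
of decimals requested by the caller, one by default).  Summaries accept
either per-search records or pre-aggregated margins, because published
cohort data often comes as margins only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GRADE_LABELS",
    "OutcomeRecord",
    "CategoryRow",
    "CohortSummary",
    "TimeRow",
    "round_half_up",
    "summarize_matching",
    "summarize_times",
    "dpb1_prospective_summary",
]

GRADE_LABELS = ("10/10", "9/10", "<=8/10 or nonevaluable")
CATEGORY_ORDER = ("high", "intermediate", "low")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OutcomeRecord:
    """Minimal per-search row: probability category, grade label, number
    of donors tested, and optional day counts."""

    category: str
    grade: str
    donors_tested: int
    days_to_identification: int | None = None
    days_to_transplant: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_ORDER:
            raise ValueError(f"unknown category {self.category!r} in {self}")
        if self.grade not in GRADE_LABELS:
            raise ValueError(f"unknown grade {self.grade!r} in {self}")


@dataclass(frozen=True)
class CategoryRow:
    category: str
    n_patients: int
    donors_tested: int
    mean_donors_per_patient: float
    grade_counts: tuple[int, int, int]  # 10/10, 9/10, <=8/10-or-nonevaluable
    grade_pct: tuple[float, float, float]


@dataclass(frozen=True)
class CohortSummary:
    rows: tuple[CategoryRow, ...]
    total: CategoryRow

    def row(self, category: str) -> CategoryRow:
        for r in self.rows:
            if r.category == category:
                return r
        raise KeyError(category)


def _make_row(
    category: str,
    n_patients: int,
    donors_tested: int,
    counts: tuple[int, int, int],
    mean_digits: int,
    pct_digits: int,
) -> CategoryRow:
    if sum(counts) != n_patients:
        raise ValueError(
            f"{category}: grade counts {counts} do not sum to {n_patients} patients"
        )
    mean = (
        round_half_up(donors_tested / n_patients, mean_digits) if n_patients else 0.0
    )
    pct = tuple(
        round_half_up(100.0 * c / n_patients, pct_digits) if n_patients else 0.0
        for c in counts
    )
    return CategoryRow(category, n_patients, donors_tested, mean, counts, pct)


def summarize_matching(
    records: Iterable[OutcomeRecord] | None = None,
    margins: Sequence[Mapping[str, object]] | None = None,
    mean_digits: int = 2,
    pct_digits: int = 1,
) -> CohortSummary:
    """Per-category and total matching-grade summary.

    ``margins`` rows need keys ``category``, ``n_patients``,
    ``donors_tested``, ``n_10of10``, ``n_9of10``, ``n_8orless``.
    """
    agg: dict[str, dict[str, int]] = {}
    if records is not None:
        for rec in records:
            a = agg.setdefault(
                rec.category,
                {"n": 0, "donors": 0, "10/10": 0, "9/10": 0, GRADE_LABELS[2]: 0},
            )
            a["n"] += 1
            a["donors"] += rec.donors_tested
            a[rec.grade] += 1
    elif margins is not None:
        for m in margins:
            cat = str(m["category"])
            if cat not in CATEGORY_ORDER:
                raise ValueError(f"unknown category {cat!r} in margins row {m}")
            agg[cat] = {
                "n": int(m["n_patients"]),
                "donors": int(m["donors_tested"]),
                "10/10": int(m["n_10of10"]),
                "9/10": int(m["n_9of10"]),
                GRADE_LABELS[2]: int(m["n_8orless"]),
            }
    else:
        raise ValueError("either records or margins must be given")

    rows = []
    tot = {"n": 0, "donors": 0, "10/10": 0, "9/10": 0, GRADE_LABELS[2]: 0}
    for cat in CATEGORY_ORDER:
        a = agg.get(cat, {"n": 0, "donors": 0, "10/10": 0, "9/10": 0, GRADE_LABELS[2]: 0})
        counts = (a["10/10"], a["9/10"], a[GRADE_LABELS[2]])
        rows.append(_make_row(cat, a["n"], a["donors"], counts, mean_digits, pct_digits))
        for k in tot:
            tot[k] += a[k]
    total = _make_row(
        "total",
        tot["n"],
        tot["donors"],
        (tot["10/10"], tot["9/10"], tot[GRADE_LABELS[2]]),
        mean_digits,
        pct_digits,
    )
    return CohortSummary(tuple(rows), total)


@dataclass(frozen=True)
class TimeRow:
    category: str
    n: int
    mean_days: int
    min_days: int
    max_days: int


def summarize_times(records: Iterable[OutcomeRecord]) -> tuple[TimeRow, ...]:
    """Per-category mean (rounded to integer days) and min-max range of
    days to donor identification."""
    by_cat: dict[str, list[int]] = {}
    for rec in records:
        if rec.days_to_identification is None:
            raise ValueError(f"record without day count: {rec}")
        by_cat.setdefault(rec.category, []).append(rec.days_to_identification)
    rows = []
    for cat in CATEGORY_ORDER:
        days = by_cat.get(cat)
        if not days:
            continue
        rows.append(
            TimeRow(
                cat,
                len(days),
                int(round_half_up(sum(days) / len(days), 0)),
                min(days),
                max(days),
            )
        )
    return tuple(rows)


def dpb1_prospective_summary(
    margins: Mapping[str, object], mean_digits: int = 1, pct_digits: int = 1
) -> dict[str, float]:
    """Worked example for a prospective DPB1-typing cohort.

    From margins (``n_searches``, ``donors_tested``, ``n_dpb1_matched``
    where the matched count may include rejection-direction-only pairs)
    computes the mean number of donors tested per patient and the DPB1
    match rate.
    """
    n = int(margins["n_searches"])
    donors = int(margins["donors_tested"])
    matched = int(margins["n_dpb1_matched"])
    return {
        "n_searches": float(n),
        "donors_tested": float(donors),
        "mean_donors_per_patient": round_half_up(donors / n, mean_digits),
        "dpb1_match_rate_pct": round_half_up(100.0 * matched / n, pct_digits),
    }
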
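"""Cohort description of the neurological-adverse-event reports.

Produces the classic pharmacovigilance "Table 1": sex, age, reporting year,
reporter occupation, reporting country, seriousness, outcome codes,
indications, and time to onset.  The unit of analysis is the deduplicated
report; percentages use the report-level cohort size as denominator and are
rounded half-up to two decimals, applied only at presentation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .faers_io import DatePrecision, PartialDate, parse_partial_date

#: Conversion of (value, unit) to years.  DEC = decades; WK/HR divisors follow
#: the FAERS convention of mean weeks/hours per year.
AGE_UNIT_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.143,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

MAX_PLAUSIBLE_AGE = 120.0

OCCUPATION_LABELS = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "OT": "Other health-professional",
    "CN": "Consumer",
    "LW": "Lawyer",
    "": "Not Specified",
}

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "HO": "Hospitalization - Initial or Prolonged",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention to Prevent Permanent Impairment/Damage",
    "OT": "Other",
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (printed-table convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int) -> float:
    """100·n/d rounded half-up to 2 decimals; exact rational arithmetic."""
    if denominator <= 0:
        raise ValueError("percent() requires a positive denominator")
    value = (Decimal(100) * Decimal(numerator)) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def age_in_years(value: float | None, unit: str | None) -> float | None:
    """Convert a FAERS (AGE, AGE_COD) pair to years; implausible (>120) -> None."""
    if value is None or unit is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if value < 0:
        return None
    factor = AGE_UNIT_FACTORS.get(str(unit).upper())
    if factor is None:
        return None
    years = float(value) * factor
    if years > MAX_PLAUSIBLE_AGE:
        return None
    return years


def time_to_onset(event_dt: PartialDate | None,
                  start_dts: Sequence[PartialDate | None]) -> int | None:
    """Days from the earliest DAY-precise therapy start to the DAY-precise event date.

    Partial or missing dates on either side yield None; a negative interval
    (event before any recorded start) is treated as unusable, enforcing a
    nonnegative onset.
    """
    if event_dt is None or event_dt.precision is not DatePrecision.DAY:
        return None
    starts = [d.to_date() for d in start_dts
              if d is not None and d.precision is DatePrecision.DAY]
    if not starts:
        return None
    days = (event_dt.to_date() - min(starts)).days
    if days < 0:
        return None
    return days


def classify_seriousness(outcome_codes: Iterable[str]) -> str:
    """SERIOUS iff the report carries at least one outcome record."""
    return "SERIOUS" if any(True for _ in outcome_codes) else "NON_SERIOUS"


def tukey_quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) by median-of-halves, excluding the median when n is odd."""
    xs = sorted(values)
    n = len(xs)
    if n == 0:
        raise ValueError("quartiles of empty sequence")

    def _median(v: Sequence[float]) -> float:
        m = len(v)
        mid = m // 2
        return float(v[mid]) if m % 2 else (v[mid - 1] + v[mid]) / 2.0

    med = _median(xs)
    if n == 1:
        return med, med, med
    lower = xs[: n // 2]
    upper = xs[n // 2 + 1:] if n % 2 else xs[n // 2:]
    return _median(lower), med, _median(upper)


def _numeric_block(values: Sequence[float], n_total: int) -> dict[str, float | int]:
    """n / missing / mean / sd / median / Q1 / Q3 / min / max for one variable."""
    xs = [float(v) for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    n = len(xs)
    block: dict[str, float | int] = {"n": n, "missing": n_total - n}
    if n == 0:
        block.update(mean=math.nan, sd=math.nan, median=math.nan,
                     q1=math.nan, q3=math.nan, min=math.nan, max=math.nan)
        return block
    arr = np.asarray(xs)
    q1, med, q3 = tukey_quartiles(xs)
    block.update(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if n > 1 else 0.0,
        median=med, q1=q1, q3=q3,
        min=float(arr.min()), max=float(arr.max()),
    )
    return block


def _count_block(series: pd.Series, denominator: int,
                 rank: bool = False, top: int | None = None) -> dict[str, tuple[int, float]]:
    counts = series.value_counts()
    if rank:
        items = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    else:
        items = sorted(counts.items(), key=lambda kv: str(kv[0]))
    if top is not None:
        items = items[:top]
    return {str(k): (int(v), percent(int(v), denominator)) for k, v in items}


@dataclass
class CohortSummary:
    """All Table-1 blocks for one cohort of deduplicated reports."""

    n_reports: int
    sex_counts: dict[str, tuple[int, float]]
    age_stats: dict[str, float | int]
    year_counts: dict[str, tuple[int, float]]
    reporter_counts: dict[str, tuple[int, float]]
    country_counts: dict[str, tuple[int, float]]
    serious: tuple[int, float]
    non_serious: tuple[int, float]
    outcome_counts: dict[str, tuple[int, float]]
    indication_counts: dict[str, tuple[int, float]]
    tto_stats: dict[str, float | int]

    def to_table(self) -> pd.DataFrame:
        """Long-format frame mirroring the printed table's blocks."""
        rows: list[tuple[str, str, object, object]] = []

        def add_counts(block: str, counts: Mapping[str, tuple[int, float]]) -> None:
            for label, (n, pct) in counts.items():
                rows.append((block, label, n, f"{pct:.2f}"))

        def add_numeric(block: str, stats: Mapping[str, float | int]) -> None:
            rows.append((block, "N (Missing)", stats["n"], stats["missing"]))
            rows.append((block, "Mean (SD)",
                         f"{round_half_up(stats['mean']):.2f}",
                         f"{round_half_up(stats['sd']):.2f}"))
            rows.append((block, "Median (Q1, Q3)",
                         f"{round_half_up(stats['median']):.2f}",
                         f"{round_half_up(stats['q1']):.2f}, {round_half_up(stats['q3']):.2f}"))
            rows.append((block, "Min, Max",
                         f"{round_half_up(stats['min']):.2f}",
                         f"{round_half_up(stats['max']):.2f}"))

        add_counts("Gender", self.sex_counts)
        add_numeric("Age (years)", self.age_stats)
        add_counts("Reporting year", self.year_counts)
        add_counts("Reporter", self.reporter_counts)
        add_counts("Reported countries", self.country_counts)
        add_counts("Seriousness", {"Serious": self.serious, "Non-Serious": self.non_serious})
        add_counts("Outcome", self.outcome_counts)
        add_counts("Indication", self.indication_counts)
        add_numeric("Time to onset (day)", self.tto_stats)
        return pd.DataFrame(rows, columns=["block", "label", "value", "value2"])


def summarize_cohort(cohort: pd.DataFrame,
                     outcomes: pd.DataFrame,
                     indications: pd.Series,
                     tto_days: pd.Series,
                     top_countries: int = 10,
                     top_indications: int = 10) -> CohortSummary:
    """Build the full cohort summary.

    ``cohort`` must carry one row per deduplicated report with columns
    ``primaryid, sex, age_years, year, occupation_label, country``;
    ``outcomes`` is a long frame (primaryid, outc_cod) restricted to the
    cohort; ``indications`` and ``tto_days`` are per-report series (NaN for
    missing).  Countries and indications are ranked by count descending, ties
    alphabetical.
    """
    if cohort.empty:
        raise ValueError("summarize_cohort requires a nonempty cohort")
    n = len(cohort)

    sex_counts = {}
    for code in ("F", "M", "UNK"):
        c = int((cohort["sex"] == code).sum())
        sex_counts[code] = (c, percent(c, n))

    age_stats = _numeric_block(list(cohort["age_years"].dropna()), n)
    year_counts = _count_block(cohort["year"].astype(str), n)
    reporter_counts = _count_block(cohort["occupation_label"], n)
    country_counts = _count_block(cohort["country"][cohort["country"] != ""], n,
                                  rank=True, top=top_countries)

    serious_ids = set(outcomes["primaryid"])
    n_serious = int(cohort["primaryid"].isin(serious_ids).sum())
    serious = (n_serious, percent(n_serious, n))
    non_serious = (n - n_serious, percent(n - n_serious, n))

    outcome_counts: dict[str, tuple[int, float]] = {}
    per_code = outcomes.drop_duplicates(["primaryid", "outc_cod"])["outc_cod"].value_counts()
    for code, label in OUTCOME_LABELS.items():
        c = int(per_code.get(code, 0))
        if c:
            outcome_counts[label] = (c, percent(c, n))

    indication_counts = _count_block(indications.dropna(), n,
                                     rank=True, top=top_indications)
    tto_stats = _numeric_block(list(tto_days.dropna()), n)

    return CohortSummary(
        n_reports=n, sex_counts=sex_counts, age_stats=age_stats,
        year_counts=year_counts, reporter_counts=reporter_counts,
        country_counts=country_counts, serious=serious, non_serious=non_serious,
        outcome_counts=outcome_counts, indication_counts=indication_counts,
        tto_stats=tto_stats,
    )
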
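"""Reporting-odds-ratio (ROR) disproportionality signal detection.

For an exposure E and event Y over a universe of deduplicated reports, the
2x2 table is

    a = reports with E and Y        b = reports with E, without Y
    c = reports with Y, without E   d = reports with neither

and ROR = (a/c)/(b/d) = ad/bc, with SE(ln ROR) = sqrt(1/a+1/b+1/c+1/d) and
95% CI = exp(ln ROR +/- 1.96*SE).  A pair is flagged as a signal when a >= 3
and the CI lower bound (ROR_025) exceeds 1 (strict).  No continuity
correction is applied: a zero cell yields an "undefined" result rather than
an invented estimate.

The module offers a scalar API (build_table / compute_ror) mirroring the
formulas one-to-one, and a vectorized screen over exposure x event boolean
matrices used by the pipeline; the two paths agree exactly and are tested
against each other.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

Z_95 = 1.96  # normal quantile used for the 95% interval

MIN_CASES = 3  # signal criterion: a >= 3

SIGNAL_COLUMNS = ["exposure", "partner", "level", "stratum", "event",
                  "a", "b", "c", "d", "ror", "se_log_ror",
                  "ci_low", "ci_high", "is_signal", "status"]

#: Default age bands for stratification: young < 45, middle 45-64, elderly >= 65.
DEFAULT_AGE_BANDS = (45.0, 65.0)
AGE_BAND_LABELS = ("young", "middle", "elderly")


@dataclass(frozen=True)
class TwoByTwo:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RorResult:
    table: TwoByTwo
    ror: float
    se_log_ror: float
    ci_low: float
    ci_high: float
    is_signal: bool
    status: str  # "ok" or "undefined"


def build_table(universe: Iterable[str], exposed: set[str], event: set[str]) -> TwoByTwo:
    """Count each report of ``universe`` into exactly one cell."""
    a = b = c = d = 0
    for pid in universe:
        e = pid in exposed
        y = pid in event
        if e and y:
            a += 1
        elif e:
            b += 1
        elif y:
            c += 1
        else:
            d += 1
    return TwoByTwo(a, b, c, d)


def build_table_fast(n_universe: int, exposed: set[str], event: set[str]) -> TwoByTwo:
    """build_table when exposed/event are known subsets of the universe."""
    a = len(exposed & event)
    b = len(exposed) - a
    c = len(event) - a
    d = n_universe - len(exposed) - len(event) + a
    return TwoByTwo(a, b, c, d)


def compute_ror(t: TwoByTwo) -> RorResult:
    """ROR point estimate, Wald CI on the log scale, and signal flag.

    Any zero cell makes the estimate undefined (no continuity correction);
    the signal flag is then False.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return RorResult(t, math.nan, math.nan, math.nan, math.nan, False, "undefined")
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_ror = math.log(ror)
    ci_low = math.exp(log_ror - Z_95 * se)
    ci_high = math.exp(log_ror + Z_95 * se)
    result = RorResult(t, ror, se, ci_low, ci_high, False, "ok")
    return RorResult(t, ror, se, ci_low, ci_high, apply_signal_criterion(result), "ok")


def apply_signal_criterion(r: RorResult) -> bool:
    """a >= 3 AND ROR_025 > 1 (strict on both)."""
    if r.status != "ok" or math.isnan(r.ci_low):
        return False
    return r.table.a >= MIN_CASES and r.ci_low > 1.0


# ---------------------------------------------------------------------------
# Vectorized screen
# ---------------------------------------------------------------------------

def _result_frame(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray,
                  exposure: Sequence[str], event: Sequence[str],
                  level: str, stratum: str, partner: Sequence[str] | str = "") -> pd.DataFrame:
    a = a.astype(np.int64); b = b.astype(np.int64)
    c = c.astype(np.int64); d = d.astype(np.int64)
    defined = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = np.where(defined, (a * d) / np.maximum(b * c, 1), np.nan)
        se = np.where(defined,
                      np.sqrt(1 / np.maximum(a, 1) + 1 / np.maximum(b, 1)
                              + 1 / np.maximum(c, 1) + 1 / np.maximum(d, 1)),
                      np.nan)
        log_ror = np.log(np.where(defined, ror, 1.0))
        ci_low = np.where(defined, np.exp(log_ror - Z_95 * se), np.nan)
        ci_high = np.where(defined, np.exp(log_ror + Z_95 * se), np.nan)
    is_signal = defined & (a >= MIN_CASES) & (ci_low > 1.0)
    if isinstance(partner, str):
        partner = [partner] * len(a)
    return pd.DataFrame({
        "exposure": exposure, "partner": partner, "level": level,
        "stratum": stratum, "event": event,
        "a": a, "b": b, "c": c, "d": d,
        "ror": ror, "se_log_ror": se, "ci_low": ci_low, "ci_high": ci_high,
        "is_signal": is_signal,
        "status": np.where(defined, "ok", "undefined"),
    })[SIGNAL_COLUMNS]


def screen(universe: Sequence[str],
           exposure_sets: Mapping[str, set[str]],
           event_sets: Mapping[str, set[str]],
           level: str = "PT",
           stratum: str = "all",
           partner_of: Mapping[str, str] | None = None) -> pd.DataFrame:
    """ROR screen of every (exposure, event) pair over one universe.

    Returns a SignalTable frame; non-signal rows are retained and flagged.
    """
    n = len(universe)
    uni = set(universe)
    rows_exp, rows_evt, aa, bb, cc, dd = [], [], [], [], [], []
    for ename in sorted(exposure_sets):
        exp_ids = exposure_sets[ename] & uni
        for yname in sorted(event_sets):
            evt_ids = event_sets[yname] & uni
            t = build_table_fast(n, exp_ids, evt_ids)
            rows_exp.append(ename); rows_evt.append(yname)
            aa.append(t.a); bb.append(t.b); cc.append(t.c); dd.append(t.d)
    partners = ([partner_of.get(e, "") for e in rows_exp] if partner_of else "")
    return _result_frame(np.array(aa), np.array(bb), np.array(cc), np.array(dd),
                         rows_exp, rows_evt, level, stratum, partners)


def rank_and_select(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k signal rows by ROR_025 descending; ties by a descending, then event name."""
    if k < 1:
        raise ValueError("k must be >= 1")
    signals = table[table["is_signal"]].copy()
    signals = signals.sort_values(["ci_low", "a", "event"],
                                  ascending=[False, False, True],
                                  kind="mergesort")
    return signals.head(k).reset_index(drop=True)


def age_band(age_years: float | None,
             bands: tuple[float, float] = DEFAULT_AGE_BANDS) -> str | None:
    """young / middle / elderly band for an age in years; None when missing."""
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return None
    lo, hi = bands
    if not lo < hi:
        raise ValueError("age bands must be strictly increasing")
    if age_years < lo:
        return AGE_BAND_LABELS[0]
    if age_years < hi:
        return AGE_BAND_LABELS[1]
    return AGE_BAND_LABELS[2]


def stratified_analysis(universe: Sequence[str],
                        exposure_sets: Mapping[str, set[str]],
                        event_sets: Mapping[str, set[str]],
                        strata: Mapping[str, str | None],
                        level: str = "PT",
                        dimension: str = "SEX") -> pd.DataFrame:
    """Screen within each stratum's sub-universe.

    ``strata`` maps primaryid -> stratum label (None = missing, excluded).
    Stratified cells over the labelled sub-universes sum to the cells of the
    same screen restricted to labelled reports (partition identity).
    """
    frames = []
    labels = sorted({v for v in strata.values() if v is not None})
    for label in labels:
        sub = [pid for pid in universe if strata.get(pid) == label]
        if not sub:
            continue
        frames.append(screen(sub, exposure_sets, event_sets, level=level,
                             stratum=f"{dimension}:{label}"))
    if not frames:
        return pd.DataFrame(columns=SIGNAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def sensitivity_monotherapy(universe: Sequence[str],
                            drug: str,
                            monotherapy_ids: set[str],
                            event_sets: Mapping[str, set[str]],
                            level: str = "PT") -> pd.DataFrame:
    """Monotherapy sensitivity analysis for one drug.

    Exposure is restricted to reports where the drug is the sole target ICI
    with no other suspect drug; the comparator is every other report in the
    universe (combination reports of the same drug included).
    """
    return screen(universe, {drug: set(monotherapy_ids)}, event_sets,
                  level=level, stratum="monotherapy")


def combination_analysis(universe: Sequence[str],
                         ici: str,
                         partner: str,
                         exposed_ids: set[str],
                         event_sets: Mapping[str, set[str]],
                         level: str = "PT") -> pd.DataFrame:
    """Screen for one ICI+partner combination.

    ``exposed_ids`` are reports carrying the ICI as suspect AND the partner
    among partner-role ingredients; the comparator is all other reports.
    """
    out = screen(universe, {ici: set(exposed_ids)}, event_sets,
                 level=level, stratum="combination",
                 partner_of={ici: partner})
    return out
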
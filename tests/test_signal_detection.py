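"""ROR engine: closed-form oracle agreement, symmetry, criteria, analyses."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from neurovigil.signal_detection import (RorResult, TwoByTwo, age_band,
                                         apply_signal_criterion, build_table,
                                         build_table_fast,
                                         combination_analysis, compute_ror,
                                         rank_and_select, screen,
                                         sensitivity_monotherapy,
                                         stratified_analysis)


def oracle_ror(a, b, c, d):
    """Independent arithmetic path: log-odds difference, CI by multiplication."""
    log_ror = (math.log(a) + math.log(d)) - (math.log(b) + math.log(c))
    se = (1 / a + 1 / b + 1 / c + 1 / d) ** 0.5
    point = math.exp(log_ror)
    return point, point * math.exp(-1.96 * se), point * math.exp(1.96 * se)


def test_build_table_hand_enumerated():
    universe = [str(i) for i in range(10)]
    exposed = {"0", "1", "2"}
    event = {"0", "1", "3"}
    t = build_table(universe, exposed, event)
    assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 6)
    assert t == build_table_fast(10, exposed, event)


def test_build_table_degenerate_margins():
    universe = [str(i) for i in range(5)]
    t = build_table(universe, {"0", "1"}, set())
    assert t.a == 0 and t.c == 0
    t = build_table(universe, set(universe), {"0"})
    assert t.c == 0 and t.d == 0


def test_compute_ror_point_and_ci():
    r = compute_ror(TwoByTwo(10, 90, 100, 9900))
    assert r.ror == pytest.approx(11.0)
    assert r.ci_low == pytest.approx(5.5594, abs=2e-3)
    assert r.is_signal
    r = compute_ror(TwoByTwo(5, 5, 5, 5))
    assert r.ror == pytest.approx(1.0)
    assert not r.is_signal


def test_compute_ror_zero_cell_undefined():
    r = compute_ror(TwoByTwo(3, 0, 5, 100))
    assert r.status == "undefined"
    assert math.isnan(r.ror) and not r.is_signal
    r = compute_ror(TwoByTwo(0, 10, 5, 100))
    assert r.status == "undefined" and not r.is_signal


def test_signal_criterion_boundaries():
    def fake(a, ci_low):
        return RorResult(TwoByTwo(a, 1, 1, 1), 2.0, 0.1, ci_low, 9.0, False, "ok")
    assert apply_signal_criterion(fake(3, 1.01))
    assert not apply_signal_criterion(fake(2, 50.0))   # count rule
    assert not apply_signal_criterion(fake(100, 1.0))  # strict CI rule


def test_ror_oracle_agreement_random_tables():
    """1e-9 relative agreement with the independent closed form on random tables."""
    rng = np.random.default_rng(2024)
    cells = rng.integers(1, 5000, size=(2000, 4))
    for a, b, c, d in cells:
        r = compute_ror(TwoByTwo(int(a), int(b), int(c), int(d)))
        ror, lo, hi = oracle_ror(a, b, c, d)
        assert r.ror == pytest.approx(ror, rel=1e-9)
        assert r.ci_low == pytest.approx(lo, rel=1e-9)
        assert r.ci_high == pytest.approx(hi, rel=1e-9)


def test_ror_reciprocal_symmetry():
    rng = np.random.default_rng(99)
    cells = rng.integers(1, 2000, size=(500, 4))
    for a, b, c, d in cells:
        fwd = compute_ror(TwoByTwo(int(a), int(b), int(c), int(d)))
        swap = compute_ror(TwoByTwo(int(c), int(d), int(a), int(b)))
        assert fwd.ror * swap.ror == pytest.approx(1.0, rel=1e-9)


def test_ror_monotone_in_a():
    prev = None
    for a in range(1, 40):
        r = compute_ror(TwoByTwo(a, 50, 60, 4000))
        if prev is not None:
            assert r.ror > prev.ror and r.ci_low > prev.ci_low
        prev = r


def test_screen_agrees_with_scalar_path():
    rng = np.random.default_rng(5)
    universe = [str(i) for i in range(400)]
    exposure_sets = {"X": {p for p in universe if rng.random() < 0.2}}
    event_sets = {"Y": {p for p in universe if rng.random() < 0.1},
                  "Z": {p for p in universe if rng.random() < 0.05}}
    frame = screen(universe, exposure_sets, event_sets)
    for row in frame.itertuples():
        t = build_table(universe, exposure_sets[row.exposure], event_sets[row.event])
        r = compute_ror(t)
        assert (row.a, row.b, row.c, row.d) == (t.a, t.b, t.c, t.d)
        if r.status == "ok":
            assert row.ror == pytest.approx(r.ror, rel=1e-12)
            assert bool(row.is_signal) == r.is_signal


def test_rank_and_select_ordering_and_ties():
    rows = pd.DataFrame({
        "exposure": "X", "partner": "", "level": "PT", "stratum": "all",
        "event": ["e1", "e2", "e3", "e4"],
        "a": [5, 10, 4, 8], "b": [1] * 4, "c": [1] * 4, "d": [1] * 4,
        "ror": [9.0] * 4, "se_log_ror": [0.1] * 4,
        "ci_low": [5.0, 2.0, 2.0, 9.0], "ci_high": [99.0] * 4,
        "is_signal": [True, True, True, False], "status": ["ok"] * 4,
    })
    out = rank_and_select(rows, 2)
    assert list(out["ci_low"]) == [5.0, 2.0]
    # tie on ci_low broken by larger a
    out = rank_and_select(rows, 3)
    assert list(out["event"]) == ["e1", "e2", "e3"]
    # k beyond the signal count returns all signal rows
    assert len(rank_and_select(rows, 10)) == 3
    with pytest.raises(ValueError):
        rank_and_select(rows, 0)


def test_age_band_default_cutoffs():
    assert age_band(30) == "young"
    assert age_band(44.9) == "young"
    assert age_band(45) == "middle"
    assert age_band(64.9) == "middle"
    assert age_band(65) == "elderly"
    assert age_band(None) is None
    assert age_band(float("nan")) is None


def test_stratified_partition_identity():
    """Stratum cells sum to the unstratified cells over labelled reports."""
    rng = np.random.default_rng(11)
    universe = [str(i) for i in range(600)]
    strata = {p: ("M" if rng.random() < 0.5 else "F") for p in universe}
    exposure_sets = {"X": {p for p in universe if rng.random() < 0.25}}
    event_sets = {"Y": {p for p in universe if rng.random() < 0.1}}
    strat = stratified_analysis(universe, exposure_sets, event_sets, strata)
    pooled = screen(universe, exposure_sets, event_sets)
    for cell in ("a", "b", "c", "d"):
        assert strat[cell].sum() == pooled[cell].iloc[0]


def test_stratified_excludes_missing_stratum():
    universe = ["1", "2", "3"]
    strata = {"1": "M", "2": None, "3": "M"}
    out = stratified_analysis(universe, {"X": {"1"}}, {"Y": {"3"}}, strata)
    assert set(out["stratum"]) == {"SEX:M"}
    assert out[["a", "b", "c", "d"]].sum(axis=1).iloc[0] == 2


def test_sensitivity_monotherapy_identity_and_empty():
    universe = [str(i) for i in range(50)]
    exposed = {str(i) for i in range(10)}
    events = {"Y": {str(i) for i in range(5, 15)}}
    # all-monotherapy: identical to the primary screen
    full = screen(universe, {"X": exposed}, events)
    sens = sensitivity_monotherapy(universe, "X", exposed, events)
    assert (sens[["a", "b", "c", "d"]].values == full[["a", "b", "c", "d"]].values).all()
    # no monotherapy reports: exposed margin collapses to zero
    none = sensitivity_monotherapy(universe, "X", set(), events)
    assert none["a"].iloc[0] == 0 and none["status"].iloc[0] == "undefined"


def test_combination_analysis_no_cooccurrence():
    universe = [str(i) for i in range(20)]
    out = combination_analysis(universe, "X", "P", set(), {"Y": {"1", "2", "3"}})
    assert out["a"].iloc[0] == 0 and not out["is_signal"].iloc[0]
    assert (out["partner"] == "P").all()
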
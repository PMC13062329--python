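"""Generator contracts: determinism, planted-margin oracles, ledgers."""
from __future__ import annotations

import filecmp
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from neurovigil.dedup import dedup_pipeline
from neurovigil.drug_normalize import normalize_name
from neurovigil.synthetic_data import (PlantedSignal, SynthConfig,
                                       SynthConfigError, expected_table,
                                       exposed_event_prob, generate,
                                       generate_frames)
from tests.conftest import small_synth_config


def _tree_files(root: Path) -> list[Path]:
    return sorted(p for p in root.rglob("*") if p.is_file())


def test_same_seed_byte_identical_packages(tmp_path):
    config = small_synth_config(seed=42, n=3000,
                                planted_signals=(
                                    PlantedSignal("NIVOLUMAB", "Myasthenia gravis", 20.0, 150),))
    generate(config, tmp_path / "a")
    generate(config, tmp_path / "b")
    files_a = _tree_files(tmp_path / "a")
    files_b = _tree_files(tmp_path / "b")
    assert [p.name for p in files_a] == [p.name for p in files_b]
    for pa, pb in zip(files_a, files_b):
        assert filecmp.cmp(pa, pb, shallow=False), pa.name


def test_different_seed_differs(tmp_path):
    base = small_synth_config(seed=1, n=3000, planted_signals=())
    other = small_synth_config(seed=2, n=3000, planted_signals=())
    generate(base, tmp_path / "a")
    generate(other, tmp_path / "b")
    assert not filecmp.cmp(tmp_path / "a" / "2023Q1" / "DEMO.txt",
                           tmp_path / "b" / "2023Q1" / "DEMO.txt", shallow=False)


def test_exposed_event_prob_odds_identity():
    p0 = 0.01
    for ror in (0.5, 1.0, 2.0, 20.0):
        p1 = exposed_event_prob(p0, ror)
        realized = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert realized == pytest.approx(ror, rel=1e-12)


def test_expected_table_null_case():
    config = small_synth_config(
        planted_signals=(PlantedSignal("NIVOLUMAB", "Myasthenia gravis", 1.0, 1000),),
        deletion_rate=0.0)
    t = expected_table(config, config.planted_signals[0])
    # ROR target of 1: exposed and unexposed event shares agree in expectation
    assert t.a / (t.a + t.b) == pytest.approx(t.c / (t.c + t.d), abs=1e-3)


def test_expected_table_linear_in_exposed():
    base = small_synth_config(
        planted_signals=(PlantedSignal("NIVOLUMAB", "Myasthenia gravis", 4.0, 500),),
        deletion_rate=0.0)
    doubled = small_synth_config(
        planted_signals=(PlantedSignal("NIVOLUMAB", "Myasthenia gravis", 4.0, 1000),),
        deletion_rate=0.0)
    t1 = expected_table(base, base.planted_signals[0])
    t2 = expected_table(doubled, doubled.planted_signals[0])
    assert t2.a == pytest.approx(2 * t1.a, abs=1)
    assert t2.b == pytest.approx(2 * t1.b, abs=1)


def test_expected_table_matches_root_finder():
    """Cross-check the planted odds solution with a numeric root-finder."""
    config = SynthConfig(
        n_reports=10_000, deletion_rate=0.0, background_event_rate=0.01,
        planted_signals=(PlantedSignal("NIVOLUMAB", "Myasthenia gravis", 5.0, 1000),))
    signal = config.planted_signals[0]
    t = expected_table(config, signal)
    n_e, n_u = 1000, 9000
    c = n_u * 0.01

    def gap(a):
        return (a * (n_u - c)) / ((n_e - a) * c) - 5.0

    a_root = brentq(gap, 1e-6, n_e - 1e-6)
    assert t.a == round(a_root)


def test_expected_table_infeasible_raises():
    config = small_synth_config(
        planted_signals=(PlantedSignal("NIVOLUMAB", "Myasthenia gravis", 1e-4, 50),))
    with pytest.raises(SynthConfigError, match="NIVOLUMAB"):
        expected_table(config, config.planted_signals[0])


def test_config_validation_errors():
    with pytest.raises(SynthConfigError):
        SynthConfig(n_reports=0).validate()
    with pytest.raises(SynthConfigError):
        SynthConfig(sex_mix={"M": 0.9, "F": 0.9, "UNK": 0.1}).validate()
    with pytest.raises(SynthConfigError):
        SynthConfig(planted_signals=(
            PlantedSignal("WONDERDRUG", "Tremor", 2.0, 10),)).validate()
    with pytest.raises(SynthConfigError, match="distinct"):
        SynthConfig(planted_signals=(
            PlantedSignal("NIVOLUMAB", "Tremor", 2.0, 10),
            PlantedSignal("AVELUMAB", "Tremor", 2.0, 10))).validate()


def test_config_round_trip_from_mapping():
    cfg = SynthConfig.from_mapping({
        "n_reports": 5000, "seed": 3, "quarters": ["2023Q1"],
        "planted_signals": [
            {"exposure": "NIVOLUMAB", "event_pt": "Tremor",
             "target_ror": 2.5, "n_exposed": 100},
            {"exposure": ["CEMIPLIMAB", "PACLITAXEL"], "event_pt": "Syncope",
             "target_ror": 4.0, "n_exposed": 50}],
    })
    assert cfg.planted_signals[1].partner == "PACLITAXEL"
    assert cfg.planted_signals[1].exposure == ("CEMIPLIMAB", "PACLITAXEL")


def test_dedup_ledger_agreement():
    """dedup's removal counts equal the generator's ledgers exactly."""
    config = small_synth_config(seed=9, n=6000)
    tables, deleted, truth = generate_frames(config)
    dd = dedup_pipeline(tables["demo"], set().union(*deleted.values()))
    assert dd.removed_as_duplicate == truth.n_duplicate_versions
    assert dd.removed_as_deleted == truth.n_deleted
    assert len(dd.kept_primaryids) == truth.n_active


def test_no_noise_config_removes_nothing():
    config = small_synth_config(seed=4, n=3000, planted_signals=(),
                                duplicate_rate=0.0, deletion_rate=0.0)
    tables, deleted, truth = generate_frames(config)
    dd = dedup_pipeline(tables["demo"], set().union(*deleted.values()))
    assert dd.removed_as_duplicate == 0 and dd.removed_as_deleted == 0
    assert truth.n_duplicate_versions == 0 and truth.n_deleted == 0


def test_name_variants_always_recoverable(dictionary):
    """Every non-junk drug mention normalizes back to its planted ingredient."""
    config = small_synth_config(seed=6, n=4000, name_variant_rate=0.6,
                                junk_name_rate=0.05)
    tables, _, _ = generate_frames(config, dictionary=dictionary)
    names = tables["drug"]["drugname"].unique()
    for name in names:
        if name.startswith("UNVERIFIED COMPOUND"):
            assert normalize_name(name, dictionary) is None
        else:
            assert normalize_name(name, dictionary) is not None, name


def test_planted_exposure_counts_exact():
    """The exposed margin of each planted signal is reproduced exactly."""
    config = small_synth_config(seed=12, n=6000)
    tables, deleted, truth = generate_frames(config)
    dd = dedup_pipeline(tables["demo"], set().union(*deleted.values()))
    kept_cases = set(dd.kept_demo["caseid"].astype(int))
    for label, caseids in truth.exposed_caseids.items():
        assert set(caseids) <= kept_cases
        signal = next(s for s in config.planted_signals if s.label == label)
        assert len(caseids) == signal.n_exposed
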
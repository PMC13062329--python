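"""Drug-name normalization, exposure classification, monotherapy rule."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neurovigil.drug_normalize import (build_exposure, canonicalize,
                                       exposure_frame, is_monotherapy,
                                       monotherapy_ids, normalize_name,
                                       TARGET_INGREDIENTS)


def _drugs(rows):
    return pd.DataFrame(rows, columns=["primaryid", "drug_seq", "role_cod", "drugname"])


@pytest.mark.parametrize("raw,expected", [
    ("Keytruda", "PEMBROLIZUMAB"),
    ("  nivolumab 240 MG ", "NIVOLUMAB"),
    ("OPDIVO INJECTION", "NIVOLUMAB"),
    ("Levothyroxine  Sodium", "LEVOTHYROXINE"),
    ("ASPIRIN", None),                     # deliberately absent from the fixture
    ("", None),
])
def test_normalize_name(dictionary, raw, expected):
    assert normalize_name(raw, dictionary) == expected


def test_canonicalize_strips_only_known_tail_tokens():
    assert canonicalize(" keytruda 100 mg ") == "KEYTRUDA"
    assert canonicalize("TAXOL SOLUTION") == "TAXOL"
    # unknown token is retained
    assert canonicalize("KEYTRUDA SUPERDOSE") == "KEYTRUDA SUPERDOSE"


def test_normalize_idempotent_on_outputs(dictionary):
    for synonym in dictionary.entries:
        ingredient = normalize_name(synonym, dictionary)
        assert ingredient is not None
        assert normalize_name(ingredient, dictionary) == ingredient


def test_dictionary_targets_are_the_ten_icis(dictionary):
    assert dictionary.target_ingredients == set(TARGET_INGREDIENTS)
    for ingredient in TARGET_INGREDIENTS:
        assert dictionary.synonyms_for(ingredient), ingredient


def test_build_exposure_examples(dictionary):
    p = build_exposure(_drugs([("1", "1", "PS", "Keytruda"),
                               ("1", "2", "C", "Levothyroxine")]), dictionary)
    assert p.target_ingredients == {"PEMBROLIZUMAB"}
    assert p.concomitant_ingredients == {"LEVOTHYROXINE"}
    assert p.co_suspect_ingredients == frozenset()

    p = build_exposure(_drugs([("2", "1", "PS", "Opdivo"),
                               ("2", "2", "SS", "Yervoy")]), dictionary)
    assert p.target_ingredients == {"NIVOLUMAB", "IPILIMUMAB"}
    assert p.co_suspect_ingredients == frozenset()


def test_concomitant_ici_does_not_qualify_as_exposure(dictionary):
    """Exposure requires a suspect role; a concomitant ICI lands in the
    concomitant set (brute-force role filter as the oracle)."""
    records = _drugs([("3", "1", "PS", "METFORMIN"), ("3", "2", "C", "nivolumab")])
    p = build_exposure(records, dictionary)
    assert p.target_ingredients == frozenset()
    assert "NIVOLUMAB" in p.concomitant_ingredients
    # oracle: no record is both target and suspect-role
    oracle = [(normalize_name(r.drugname, dictionary), r.role_cod)
              for r in records.itertuples()]
    assert not any(i in TARGET_INGREDIENTS and role in ("PS", "SS")
                   for i, role in oracle)


def test_unnormalizable_partner_retained_raw(dictionary):
    p = build_exposure(_drugs([("4", "1", "PS", "Keytruda"),
                               ("4", "2", "SS", "Mystery Elixir")]), dictionary)
    assert "RAW:MYSTERY ELIXIR" in p.co_suspect_ingredients


def test_build_exposure_permutation_invariant(dictionary):
    rows = [("5", "1", "PS", "Tecentriq"), ("5", "2", "SS", "Taxol"),
            ("5", "3", "C", "Prilosec")]
    base = build_exposure(_drugs(rows), dictionary)
    for perm in ([rows[2], rows[0], rows[1]], [rows[1], rows[2], rows[0]]):
        assert build_exposure(_drugs(perm), dictionary) == base


def test_is_monotherapy(dictionary):
    mono = build_exposure(_drugs([("6", "1", "PS", "Keytruda"),
                                  ("6", "2", "C", "Omeprazole")]), dictionary)
    assert is_monotherapy(mono)               # concomitants ignored
    dual = build_exposure(_drugs([("7", "1", "PS", "Opdivo"),
                                  ("7", "2", "SS", "Yervoy")]), dictionary)
    assert not is_monotherapy(dual)
    combo = build_exposure(_drugs([("8", "1", "PS", "Tecentriq"),
                                   ("8", "2", "SS", "Paclitaxel")]), dictionary)
    assert not is_monotherapy(combo)
    none = build_exposure(_drugs([("9", "1", "PS", "METFORMIN")]), dictionary)
    with pytest.raises(ValueError):
        is_monotherapy(none)


def test_vectorized_frame_agrees_with_per_report_api(dictionary):
    rng = np.random.default_rng(0)
    names = ["Keytruda", "OPDIVO", "Yervoy", "Taxol", "Omeprazole",
             "Mystery Elixir", "nivolumab 240 MG"]
    roles = ["PS", "SS", "C", "I"]
    rows = [(str(pid), str(seq + 1), roles[rng.integers(0, 4)],
             names[rng.integers(0, len(names))])
            for pid in range(50) for seq in range(rng.integers(1, 4))]
    df = _drugs(rows)
    exp = exposure_frame(df, dictionary)
    for pid, group in df.groupby("primaryid"):
        profile = build_exposure(group, dictionary)
        frame_targets = set(
            exp[(exp["primaryid"] == pid) & exp["is_exposure"]]["ingredient"])
        assert frame_targets == set(profile.target_ingredients)


def test_monotherapy_ids_matches_per_report_rule(dictionary):
    df = _drugs([
        ("1", "1", "PS", "Keytruda"),                       # mono
        ("2", "1", "PS", "Keytruda"), ("2", "2", "SS", "Taxol"),   # co-suspect
        ("3", "1", "PS", "Keytruda"), ("3", "2", "SS", "Opdivo"),  # two ICIs
        ("4", "1", "PS", "Keytruda"), ("4", "2", "C", "Prilosec"),  # mono
    ])
    exp = exposure_frame(df, dictionary)
    assert monotherapy_ids(exp, "PEMBROLIZUMAB") == {"1", "4"}
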
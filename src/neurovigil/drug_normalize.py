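"""Drug-name normalization and exposure classification.

Verbatim FAERS drug strings (trade names, misspellings, dose-decorated
mentions) are mapped to standardized ingredients through a synonym dictionary.
The dictionary shipped with the package is a license-free fixture covering the
ten target immune checkpoint inhibitors (ICIs) — six anti-PD-1, three
anti-PD-L1 and one anti-CTLA-4 antibody — plus the combination partners and
common concomitants the synthetic generator emits.

A report's exposure profile separates:

* ``target_icis`` — target ICIs appearing with a suspect role (PS/SS by
  default: a drug only "counts" when the reporter suspected it),
* ``co_suspect_ingredients`` — other suspect drugs, and
* ``concomitant_ingredients`` — drugs with role C or I.

Unnormalizable names are retained verbatim with a ``RAW:`` prefix so the
combination analysis never silently loses a partner.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: Ingredients searched as target exposures.
TARGET_INGREDIENTS = frozenset({
    "PEMBROLIZUMAB", "NIVOLUMAB", "TORIPALIMAB", "TISLELIZUMAB", "CEMIPLIMAB",
    "DOSTARLIMAB", "ATEZOLIZUMAB", "AVELUMAB", "DURVALUMAB", "IPILIMUMAB",
})

ICI_CLASSES = ("PD1", "PDL1", "CTLA4")

SUSPECT_ROLES = ("PS", "SS")
ALL_ROLES = ("PS", "SS", "C", "I")

#: Fixed, versioned list of dose/form tokens stripped from the *tail* of a
#: name during canonicalization.  Unknown tokens are never stripped.
STRIP_TOKENS = frozenset({
    "MG", "MCG", "G", "ML", "L", "TABLET", "TABLETS", "TAB", "TABS",
    "CAPSULE", "CAPSULES", "CAP", "CAPS", "INJECTION", "INJ", "SOLUTION",
    "SOL", "INFUSION", "CONCENTRATE", "ORAL", "IV", "INTRAVENOUS", "FILM",
    "COATED", "VIAL", "SYRINGE", "KIT", "DOSE", "DAILY",
})

_NUMERIC_TOKEN = re.compile(r"^\d+(\.\d+)?(MG|MCG|G|ML|L|%)?$")
_WS = re.compile(r"\s+")


def canonicalize(raw: object) -> str:
    """Upper-case, trim, collapse whitespace, strip trailing dose/form tokens."""
    s = _WS.sub(" ", str(raw).strip().upper())
    if not s:
        return ""
    tokens = s.split(" ")
    while len(tokens) > 1:
        tail = tokens[-1]
        if tail in STRIP_TOKENS or _NUMERIC_TOKEN.match(tail):
            tokens.pop()
        else:
            break
    return " ".join(tokens)


@dataclass(frozen=True)
class DictEntry:
    ingredient: str
    is_target_ici: bool
    ici_class: str | None


@dataclass
class DrugDictionary:
    """Synonym -> ingredient lookup with target-ICI flags."""

    entries: dict[str, DictEntry]

    def __post_init__(self) -> None:
        targets = {e.ingredient for e in self.entries.values() if e.is_target_ici}
        if targets - TARGET_INGREDIENTS:
            raise ValueError(
                f"dictionary flags non-target ingredients as ICIs: {sorted(targets - TARGET_INGREDIENTS)}")

    @property
    def target_ingredients(self) -> set[str]:
        return {e.ingredient for e in self.entries.values() if e.is_target_ici}

    def ici_class_of(self, ingredient: str) -> str | None:
        for e in self.entries.values():
            if e.ingredient == ingredient and e.is_target_ici:
                return e.ici_class
        return None

    def synonyms_for(self, ingredient: str) -> list[str]:
        return sorted(s for s, e in self.entries.items() if e.ingredient == ingredient)


def load_drug_dictionary(path: Path | None = None) -> DrugDictionary:
    """Load the 4-column synonym CSV (synonym, ingredient, is_target_ici, ici_class)."""
    if path is None:
        source = resources.files("neurovigil.data").joinpath("drug_dictionary.csv")
        with source.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    entries: dict[str, DictEntry] = {}
    for row in df.itertuples(index=False):
        key = canonicalize(row.synonym)
        entries[key] = DictEntry(
            ingredient=str(row.ingredient).strip().upper(),
            is_target_ici=str(row.is_target_ici).strip() in {"1", "true", "True"},
            ici_class=(str(row.ici_class).strip() or None),
        )
    return DrugDictionary(entries)


def normalize_name(raw: object, dictionary: DrugDictionary) -> str | None:
    """Exact dictionary lookup after canonicalization; None when unmatched."""
    key = canonicalize(raw)
    entry = dictionary.entries.get(key)
    return entry.ingredient if entry is not None else None


@dataclass(frozen=True)
class ExposureProfile:
    """Report-level drug exposure, split by role."""

    primaryid: str
    target_icis: frozenset[tuple[str, str, str]]  # (ingredient, ici_class, role)
    co_suspect_ingredients: frozenset[str]
    concomitant_ingredients: frozenset[str]

    @property
    def target_ingredients(self) -> frozenset[str]:
        return frozenset(i for i, _, _ in self.target_icis)

    @property
    def partner_ingredients(self) -> frozenset[str]:
        return self.co_suspect_ingredients | self.concomitant_ingredients


def build_exposure(drug_records: pd.DataFrame, dictionary: DrugDictionary,
                   roles: Iterable[str] = SUSPECT_ROLES) -> ExposureProfile:
    """Classify one report's drug records into target / co-suspect / concomitant.

    ``roles`` defines which role codes qualify a target ICI as an exposure
    (PS and SS by default).  The result is invariant to record order.
    """
    pids = drug_records["primaryid"].unique()
    if len(pids) != 1:
        raise ValueError("build_exposure expects records for exactly one primaryid")
    roles = set(roles)
    targets: set[tuple[str, str, str]] = set()
    co_suspect: set[str] = set()
    concomitant: set[str] = set()
    for row in drug_records.itertuples(index=False):
        ingredient = normalize_name(row.drugname, dictionary)
        role = row.role_cod
        is_target = (ingredient is not None
                     and dictionary.entries[canonicalize(row.drugname)].is_target_ici)
        if is_target and role in roles:
            cls = dictionary.entries[canonicalize(row.drugname)].ici_class or ""
            targets.add((ingredient, cls, role))
            continue
        label = ingredient if ingredient is not None else f"RAW:{canonicalize(row.drugname)}"
        if role in SUSPECT_ROLES:
            co_suspect.add(label)
        else:
            concomitant.add(label)
    return ExposureProfile(str(pids[0]), frozenset(targets),
                           frozenset(co_suspect), frozenset(concomitant))


def is_monotherapy(profile: ExposureProfile) -> bool:
    """True iff exactly one target ICI and no other suspect drug (concomitants ignored)."""
    if not profile.target_icis:
        raise ValueError("is_monotherapy requires at least one target ICI exposure")
    return (len(profile.target_ingredients) == 1
            and not profile.co_suspect_ingredients)


# ---------------------------------------------------------------------------
# Vectorized helpers used by the pipeline (semantically identical to the
# per-report API above, exercised against it in tests).
# ---------------------------------------------------------------------------

def normalized_names(drug_df: pd.DataFrame, dictionary: DrugDictionary) -> pd.Series:
    """Ingredient per DRUG row (NaN when unmatched); fast via unique-name cache."""
    unique = drug_df["drugname"].unique()
    mapping = {u: normalize_name(u, dictionary) for u in unique}
    return drug_df["drugname"].map(mapping)


def exposure_frame(drug_df: pd.DataFrame, dictionary: DrugDictionary,
                   roles: Iterable[str] = SUSPECT_ROLES) -> pd.DataFrame:
    """Long frame (primaryid, ingredient_or_raw, role, is_target) for all drug rows."""
    df = drug_df.copy()
    ingredient = normalized_names(df, dictionary)
    canon = df["drugname"].map({u: canonicalize(u) for u in df["drugname"].unique()})
    df["ingredient"] = ingredient.fillna("RAW:" + canon)
    df["is_target"] = ingredient.map(
        lambda i: i in dictionary.target_ingredients if isinstance(i, str) else False)
    roles = set(roles)
    df["is_exposure"] = df["is_target"] & df["role_cod"].isin(roles)
    cols = ["primaryid", "ingredient", "role_cod", "is_target", "is_exposure"]
    if "drug_seq" in df.columns:
        cols.insert(1, "drug_seq")
    return df[cols]


def target_exposure_sets(exp_frame: pd.DataFrame) -> dict[str, set[str]]:
    """Per target ingredient: set of exposed primaryids."""
    exposed = exp_frame[exp_frame["is_exposure"]]
    return {ing: set(g["primaryid"]) for ing, g in exposed.groupby("ingredient")}


def monotherapy_ids(exp_frame: pd.DataFrame, ingredient: str) -> set[str]:
    """Reports whose only target ICI is ``ingredient`` and with no other suspect drug."""
    exposed = exp_frame[exp_frame["is_exposure"]]
    n_targets = exposed.groupby("primaryid")["ingredient"].nunique()
    single = set(n_targets[n_targets == 1].index)
    this_drug = set(exposed[exposed["ingredient"] == ingredient]["primaryid"])
    suspects = exp_frame[exp_frame["role_cod"].isin(SUSPECT_ROLES)]
    other_suspect = set(
        suspects[~(suspects["is_target"] & suspects["role_cod"].isin(SUSPECT_ROLES))]["primaryid"])
    return (this_drug & single) - other_suspect


def partner_ids(exp_frame: pd.DataFrame, partner: str,
                partner_roles: Iterable[str] = ALL_ROLES) -> set[str]:
    """Reports carrying ``partner`` (ingredient or RAW: label) in a partner role."""
    roles = set(partner_roles)
    sub = exp_frame[(exp_frame["ingredient"] == partner)
                    & exp_frame["role_cod"].isin(roles)]
    return set(sub["primaryid"])
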
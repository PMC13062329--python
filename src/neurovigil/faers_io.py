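"""Reading and writing quarterly spontaneous-report packages in the FAERS ASCII dialect.

FAERS distributes each quarter as a set of "$"-delimited ASCII tables (DEMO,
DRUG, REAC, OUTC, INDI, THER) with one header row, plus — since 2019Q1 — a
deleted-case list naming CASEIDs withdrawn from the database.  This module
parses those tables into typed pandas frames, applies lenient, logged coercion
(spontaneous-report data is dirty by construction), drops orphan rows whose
PRIMARYID has no DEMO record, and writes tabular outputs.

All readers are tolerant: a row that cannot be typed is counted and dropped,
never fatal.  Only a missing DEMO file or a malformed header aborts a run.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger("neurovigil")

#: FAERS field delimiter.  No quoting convention exists in the dialect; rows
#: with embedded "$" in free text therefore mis-tokenize and are dropped.
DELIMITER = "$"

SEX_CODES = frozenset({"F", "M", "UNK"})
AGE_UNITS = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
OCCUPATION_CODES = frozenset({"MD", "PH", "OT", "CN", "LW", "UNK"})

#: Required (lower-cased) columns per table.  Pre-2014 and post-2014 FAERS
#: header spellings are normalized to lower case on read, so one schema covers
#: both.
TABLE_COLUMNS: dict[str, list[str]] = {
    "demo": ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age",
             "age_cod", "occp_cod", "reporter_country"],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "pt"],
    "outc": ["primaryid", "outc_cod"],
    "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
}

TABLE_NAMES = tuple(TABLE_COLUMNS)


class DatePrecision(str, Enum):
    YEAR = "YEAR"
    MONTH = "MONTH"
    DAY = "DAY"


_DAYS_IN_MONTH = (31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


@dataclass(frozen=True)
class PartialDate:
    """A FAERS date at YEAR, MONTH or DAY precision (YYYY[MM[DD]])."""

    year: int
    month: int | None
    day: int | None
    precision: DatePrecision

    @property
    def sort_key(self) -> str:
        """8-digit key; missing month/day padded with '01' so the ordering is total."""
        return f"{self.year:04d}{self.month or 1:02d}{self.day or 1:02d}"

    def to_date(self) -> date | None:
        """Calendar date when DAY-precise, else None."""
        if self.precision is DatePrecision.DAY:
            return date(self.year, self.month, self.day)
        return None


def parse_partial_date(raw: object) -> PartialDate | None:
    """Parse a YYYYMMDD / YYYYMM / YYYY string leniently.

    Empty, non-numeric, wrong-length or calendar-invalid input yields None —
    this parser never raises, matching the dirty-data tolerance of the rest of
    the reader.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if not s.isdigit():
        return None
    if len(s) == 4:
        year = int(s)
        if 1900 <= year <= 2099:
            return PartialDate(year, None, None, DatePrecision.YEAR)
        return None
    if len(s) == 6:
        year, month = int(s[:4]), int(s[4:6])
        if 1900 <= year <= 2099 and 1 <= month <= 12:
            return PartialDate(year, month, None, DatePrecision.MONTH)
        return None
    if len(s) == 8:
        year, month, day = int(s[:4]), int(s[4:6]), int(s[6:8])
        if not (1900 <= year <= 2099 and 1 <= month <= 12 and 1 <= day <= 31):
            return None
        try:
            date(year, month, day)
        except ValueError:
            return None
        return PartialDate(year, month, day, DatePrecision.DAY)
    return None


def pad_date_key(raw: object) -> str | None:
    """8-digit comparable key for a partial date string, or None if unparseable."""
    pd_ = parse_partial_date(raw)
    return pd_.sort_key if pd_ is not None else None


@dataclass
class QuarterData:
    """One quarter's typed tables plus its deleted-case list.

    Every non-DEMO row is guaranteed to reference a PRIMARYID present in
    ``demo`` (orphans are dropped and counted in ``drop_counts``).
    """

    quarter_label: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    ther: pd.DataFrame
    deleted_caseids: set[str] = field(default_factory=set)
    drop_counts: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


class FaersFormatError(ValueError):
    """Fatal dialect problem: missing file or malformed header."""


def _read_text(path: Path) -> str:
    """UTF-8 with Latin-1 fallback; real FAERS mixes encodings per file."""
    data = Path(path).read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def read_table(path: Path, table: str) -> tuple[pd.DataFrame, int]:
    """Read one "$"-delimited table.

    Returns (frame, n_bad_rows).  Rows with the wrong field count (e.g. an
    embedded "$" in free text) are dropped and counted.  A header lacking a
    required column raises :class:`FaersFormatError` naming that column.
    """
    text = _read_text(Path(path))
    lines = text.splitlines()
    if not lines:
        raise FaersFormatError(f"{path}: empty file (no header row)")
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    required = TABLE_COLUMNS[table]
    for col in required:
        if col not in header:
            raise FaersFormatError(f"{path}: header is missing column {col!r}")
    ncol = len(header)
    rows: list[list[str]] = []
    bad = 0
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split(DELIMITER)
        if len(fields) != ncol:
            bad += 1
            continue
        rows.append(fields)
    df = pd.DataFrame(rows, columns=header, dtype=str)
    df = df[required].copy()
    for col in required:
        df[col] = df[col].str.strip()
    if bad:
        log.warning("%s: dropped %d mis-tokenized row(s)", path, bad)
    return df, bad


def read_deleted_list(path: Path) -> set[str]:
    """Deleted-case list: one CASEID per line (blank lines ignored)."""
    text = _read_text(Path(path))
    return {line.strip() for line in text.splitlines() if line.strip()}


def _coerce_demo(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Lenient typing of the DEMO table; returns (frame, n_coercion_failures)."""
    failures = 0
    out = df.copy()
    sex = out["sex"].str.upper()
    out["sex"] = sex.where(sex.isin(["F", "M"]), "UNK")
    age = pd.to_numeric(out["age"], errors="coerce")
    bad_age = out["age"].ne("") & age.isna()
    failures += int(bad_age.sum())
    age = age.where(age >= 0)
    unit = out["age_cod"].str.upper()
    out["age_cod"] = unit.where(unit.isin(AGE_UNITS), "")
    out["age"] = age
    occ = out["occp_cod"].str.upper()
    out["occp_cod"] = occ.where(occ.isin(OCCUPATION_CODES - {"UNK"}), "")
    # dates kept as raw strings; parse_partial_date is applied downstream
    return out, failures


def read_quarter(paths: Mapping[str, Path], quarter_label: str) -> QuarterData:
    """Read one quarterly package.

    ``paths`` maps table names ('demo', 'drug', 'reac', 'outc', 'indi',
    'ther', optionally 'deleted') to file locations.  DEMO is mandatory;
    any other missing table yields an empty frame.  Orphan non-DEMO rows
    (PRIMARYID absent from DEMO) are dropped and counted.
    """
    if "demo" not in paths or not Path(paths["demo"]).exists():
        raise FaersFormatError(f"{quarter_label}: DEMO table is required")
    drops: dict[str, int] = {}
    demo, bad = read_table(paths["demo"], "demo")
    demo = demo[demo["primaryid"] != ""]
    demo = demo[demo["caseid"] != ""]
    demo, coerce_failures = _coerce_demo(demo)
    dup_pid = demo["primaryid"].duplicated(keep="first")
    if dup_pid.any():
        log.warning("%s: %d duplicate PRIMARYID row(s) in DEMO dropped",
                    quarter_label, int(dup_pid.sum()))
    demo = demo[~dup_pid].reset_index(drop=True)
    drops["demo"] = bad + coerce_failures
    known = set(demo["primaryid"])

    tables: dict[str, pd.DataFrame] = {"demo": demo}
    for name in ("drug", "reac", "outc", "indi", "ther"):
        if name in paths and Path(paths[name]).exists():
            df, bad = read_table(paths[name], name)
        else:
            df, bad = pd.DataFrame(columns=TABLE_COLUMNS[name], dtype=str), 0
        n_in = len(df)
        df = df[df["primaryid"].isin(known)]
        if name == "reac":
            df = df[df["pt"].str.strip() != ""]
        if name == "drug":
            role = df["role_cod"].str.upper()
            df = df.assign(role_cod=role)[role.isin(ROLE_CODES)]
        if name == "outc":
            code = df["outc_cod"].str.upper()
            df = df.assign(outc_cod=code)[code.isin(OUTCOME_CODES)]
        dropped = n_in - len(df) + bad
        if dropped:
            log.info("%s/%s: dropped %d row(s) (orphan or invalid)",
                     quarter_label, name, dropped)
        drops[name] = dropped
        tables[name] = df.reset_index(drop=True)

    deleted: set[str] = set()
    if "deleted" in paths and Path(paths["deleted"]).exists():
        deleted = read_deleted_list(paths["deleted"])

    return QuarterData(quarter_label=quarter_label, deleted_caseids=deleted,
                       drop_counts=drops, **tables)


def quarter_paths(directory: Path) -> dict[str, Path]:
    """Conventional file layout of one quarter directory: DEMO.txt … DELETED.txt."""
    directory = Path(directory)
    paths = {name: directory / f"{name.upper()}.txt" for name in TABLE_NAMES}
    paths["deleted"] = directory / "DELETED.txt"
    return paths


def read_quarters(root: Path) -> list[QuarterData]:
    """Read every quarter subdirectory under ``root`` (sorted by label)."""
    root = Path(root)
    quarters = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        quarters.append(read_quarter(quarter_paths(sub), sub.name))
    if not quarters:
        raise FaersFormatError(f"{root}: no quarter subdirectories found")
    return quarters


def write_table(df: pd.DataFrame, destination: Path) -> Path:
    """Write rows as UTF-8 CSV with header, preserving column and row order."""
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(destination, index=False, encoding="utf-8",
              quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    return destination


def write_faers_table(df: pd.DataFrame, destination: Path) -> Path:
    """Write a "$"-delimited FAERS-dialect table (used by the generator)."""
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    cols = list(df.columns)
    with open(destination, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(DELIMITER.join(cols) + "\n")
        for row in df.itertuples(index=False):
            fh.write(DELIMITER.join("" if v is None else str(v) for v in row) + "\n")
    return destination


def load_country_map() -> dict[str, str]:
    """Country-string normalization fixture (verbatim value -> display name)."""
    with resources.files("neurovigil.data").joinpath("country_map.csv").open(
            "r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype=str)
    return dict(zip(df["raw"].str.upper(), df["normalized"]))


def normalize_country(raw: str, mapping: dict[str, str] | None = None) -> str:
    """Map a verbatim country string through the fixture; unknown values pass through."""
    if mapping is None:
        mapping = load_country_map()
    key = str(raw).strip().upper()
    if not key:
        return ""
    return mapping.get(key, str(raw).strip())
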
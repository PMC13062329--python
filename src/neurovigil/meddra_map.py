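"""MedDRA-slice mapping: PT -> HLGT -> SOC, and nervous-system event selection.

The full MedDRA terminology is licensed; the package ships a small slice
covering roughly fifty nervous-system preferred terms (PTs) across twelve
high-level group terms (HLGTs) under the "Nervous system disorders" system
organ class (SOC), plus non-nervous decoy PTs.  Every PT the synthetic
generator can emit is present in the slice.  One primary HLGT per PT
(no multi-axiality); PTs absent from the slice are excluded from signal
analysis but counted, never guessed.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

NERVOUS_SOC = "Nervous system disorders"

_WS = re.compile(r"\s+")


def canonical_pt(raw: object) -> str:
    """Upper-case, trim, collapse inner whitespace."""
    return _WS.sub(" ", str(raw).strip().upper())


@dataclass
class MedDraSlice:
    """PT -> (HLGT, SOC) lookup table with case-insensitive canonical keys."""

    frame: pd.DataFrame  # columns pt, hlgt, soc (display case)
    version_label: str = "28.0-slice"
    _lookup: dict[str, tuple[str, str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        canon = self.frame["pt"].map(canonical_pt)
        if canon.duplicated().any():
            dupes = sorted(canon[canon.duplicated()].unique())
            raise ValueError(f"duplicate PTs in slice: {dupes}")
        self._lookup = {
            c: (row.hlgt, row.soc)
            for c, row in zip(canon, self.frame.itertuples(index=False))
        }

    @property
    def pts(self) -> set[str]:
        return set(self._lookup)

    def pts_in_soc(self, soc: str) -> set[str]:
        return {c for c, (_, s) in self._lookup.items() if s == soc}

    def hlgt_of(self, pt: str) -> str | None:
        hit = self._lookup.get(canonical_pt(pt))
        return hit[0] if hit else None


def load_meddra_slice(path: Path | None = None,
                      version_label: str = "28.0-slice") -> MedDraSlice:
    """Load the 3-column slice CSV (pt, hlgt, soc)."""
    if path is None:
        source = resources.files("neurovigil.data").joinpath("meddra_slice.csv")
        with source.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return MedDraSlice(df[["pt", "hlgt", "soc"]], version_label)


def map_pt(pt: object, slice_: MedDraSlice) -> tuple[str, str] | None:
    """(HLGT, SOC) for a PT, or None when the slice does not contain it."""
    return slice_._lookup.get(canonical_pt(pt))


@dataclass(frozen=True)
class EventProfile:
    """One report's reaction terms, with the nervous-system subset singled out."""

    primaryid: str
    pts: frozenset[str]
    nervous_pts: frozenset[str]
    hlgts: tuple[str, ...]  # HLGT per nervous PT (multiset, sorted)
    unmapped: frozenset[str]


def build_event_profile(reactions: pd.DataFrame, slice_: MedDraSlice,
                        target_soc: str = NERVOUS_SOC) -> EventProfile:
    """Collapse one report's reaction rows into an event profile.

    Identical PTs within a report collapse to one; the nervous subset is
    selected by SOC equality through the slice.
    """
    pids = reactions["primaryid"].unique()
    if len(pids) != 1:
        raise ValueError("build_event_profile expects records for exactly one primaryid")
    pts = frozenset(canonical_pt(p) for p in reactions["pt"])
    nervous, unmapped, hlgts = set(), set(), []
    for pt in pts:
        hit = slice_._lookup.get(pt)
        if hit is None:
            unmapped.add(pt)
        elif hit[1] == target_soc:
            nervous.add(pt)
            hlgts.append(hit[0])
    return EventProfile(str(pids[0]), pts, frozenset(nervous),
                        tuple(sorted(hlgts)), frozenset(unmapped))


# ---------------------------------------------------------------------------
# Vectorized helpers for the pipeline.
# ---------------------------------------------------------------------------

def mapped_reactions(reac_df: pd.DataFrame, slice_: MedDraSlice) -> tuple[pd.DataFrame, int]:
    """Canonicalize and map all reaction rows.

    Returns (frame with columns primaryid, pt, hlgt, soc — unmapped rows
    excluded, duplicates within a report collapsed) and the count of unmapped
    distinct (primaryid, pt) pairs.
    """
    df = reac_df.copy()
    unique = df["pt"].unique()
    canon_map = {u: canonical_pt(u) for u in unique}
    df["pt"] = df["pt"].map(canon_map)
    df = df.drop_duplicates(["primaryid", "pt"])
    hit = df["pt"].map(slice_._lookup)
    unmapped = int(hit.isna().sum())
    df = df[hit.notna()].copy()
    df["hlgt"] = [h[0] for h in hit.dropna()]
    df["soc"] = [h[1] for h in hit.dropna()]
    return df.reset_index(drop=True), unmapped


def event_ids_by_pt(mapped: pd.DataFrame, soc: str = NERVOUS_SOC) -> dict[str, set[str]]:
    """Per nervous PT: set of primaryids reporting it."""
    sub = mapped[mapped["soc"] == soc]
    return {pt: set(g["primaryid"]) for pt, g in sub.groupby("pt")}


def event_ids_by_hlgt(mapped: pd.DataFrame, soc: str = NERVOUS_SOC) -> dict[str, set[str]]:
    """Per HLGT (within the SOC): set of primaryids reporting any PT under it."""
    sub = mapped[mapped["soc"] == soc]
    return {h: set(g["primaryid"]) for h, g in sub.groupby("hlgt")}
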
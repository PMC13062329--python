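"""FDA-recommended deduplication of multi-version FAERS cases.

A spontaneous-report case (CASEID) accrues a new version (PRIMARYID) each time
it is amended, and the same case can appear in several quarterly packages.
The FDA rule keeps, per CASEID, the version with the largest FDA_DT (receipt
date), breaking ties by the largest PRIMARYID.  Cases named in any quarter's
deleted-case list are then removed from the kept set.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

from .faers_io import pad_date_key


@dataclass
class DedupResult:
    """Outcome of deduplication (+ optional deletion) over a DEMO table."""

    kept_primaryids: set[str]
    removed_as_duplicate: int
    removed_as_deleted: int
    kept_demo: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def _sort_frame(demo: pd.DataFrame) -> pd.DataFrame:
    df = demo.copy()
    # MONTH/YEAR-precision receipt dates are right-padded ('01'/'0101') so the
    # comparator is total; unparseable dates sort first (never preferred).
    df["_fda_key"] = df["fda_dt"].map(lambda s: pad_date_key(s) or "00000000")
    pid_num = pd.to_numeric(df["primaryid"], errors="coerce")
    # numeric comparison when the id is fully numeric, lexicographic fallback
    df["_pid_num"] = pid_num.fillna(-1.0)
    return df.sort_values(
        ["caseid", "_fda_key", "_pid_num", "primaryid"],
        kind="mergesort",
    )


def deduplicate(demo: pd.DataFrame) -> DedupResult:
    """Keep one current version per CASEID: max (FDA_DT, PRIMARYID).

    Input row order never affects the outcome.
    """
    if demo.empty:
        return DedupResult(set(), 0, 0, demo.copy())
    df = _sort_frame(demo)
    kept = df.drop_duplicates(subset="caseid", keep="last")
    kept = kept.drop(columns=["_fda_key", "_pid_num"]).reset_index(drop=True)
    kept = kept.sort_values("primaryid", kind="mergesort").reset_index(drop=True)
    return DedupResult(
        kept_primaryids=set(kept["primaryid"]),
        removed_as_duplicate=len(demo) - len(kept),
        removed_as_deleted=0,
        kept_demo=kept,
    )


def apply_deletions(result: DedupResult, deleted_caseids: Iterable[str]) -> DedupResult:
    """Remove kept cases named in the union of all quarters' deletion lists.

    Applied after deduplication, to the kept set only; unknown CASEIDs are a
    no-op.
    """
    deleted = set(deleted_caseids)
    if not deleted:
        return replace(result)
    keep_mask = ~result.kept_demo["caseid"].isin(deleted)
    kept = result.kept_demo[keep_mask].reset_index(drop=True)
    n_removed = len(result.kept_demo) - len(kept)
    return DedupResult(
        kept_primaryids=set(kept["primaryid"]),
        removed_as_duplicate=result.removed_as_duplicate,
        removed_as_deleted=result.removed_as_deleted + n_removed,
        kept_demo=kept,
    )


def dedup_pipeline(demo: pd.DataFrame, deleted_caseids: Iterable[str]) -> DedupResult:
    """Deduplicate then delete — the full data-cleaning step over pooled quarters."""
    return apply_deletions(deduplicate(demo), deleted_caseids)
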
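"""Synthetic FAERS-dialect data with known ground truth.

The generator emits quarterly "$"-delimited packages (DEMO/DRUG/REAC/OUTC/
INDI/THER plus deleted-case lists) whose statistical structure mirrors what
the analysis assumes: multi-version cases across quarters, deletion lists,
trade-name/misspelling drug mentions, partial dates, multi-drug and
multi-reaction reports, outcome codes — and, critically, *planted*
drug-event disproportionality signals with a known reporting odds ratio.

Planting solves for the exposed-arm event probability under fixed margins:
for background event probability p0 and target ROR rho,

    p1 / (1 - p1) = rho * p0 / (1 - p0)

so the odds ratio of the sampling process equals rho exactly, and the
expected 2x2 table is available in closed form as an oracle
(:func:`expected_table`).  Event indicators are then drawn independently per
report (Bernoulli), i.e. cells are multinomial around their expectation.

All randomness flows from one seeded generator and table construction is
fully vectorized; emission order is sorted, so a fixed seed yields
byte-identical packages.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .drug_normalize import TARGET_INGREDIENTS, DrugDictionary, load_drug_dictionary
from .faers_io import TABLE_COLUMNS, write_faers_table
from .meddra_map import MedDraSlice, canonical_pt, load_meddra_slice
from .signal_detection import TwoByTwo


class SynthConfigError(ValueError):
    """Invalid or infeasible generator configuration."""


@dataclass(frozen=True)
class PlantedSignal:
    """One planted drug-event disproportionality.

    ``exposure`` is a single target ingredient, or an (ICI, partner) pair for
    a combination signal.  ``n_exposed`` reports receive the exposure; their
    event probability is raised so the odds ratio against the background
    equals ``target_ror``.
    """

    exposure: str | tuple[str, str]
    event_pt: str
    target_ror: float
    n_exposed: int

    @property
    def ici(self) -> str:
        return self.exposure[0] if isinstance(self.exposure, tuple) else self.exposure

    @property
    def partner(self) -> str | None:
        return self.exposure[1] if isinstance(self.exposure, tuple) else None

    @property
    def label(self) -> str:
        return f"{self.ici}+{self.partner}" if self.partner else self.ici


#: Default study conditions: three single-drug signals spanning weak to strong
#: disproportionality plus one combination signal, against a 1% per-PT
#: background reporting rate.
DEFAULT_PLANTED: tuple[PlantedSignal, ...] = (
    PlantedSignal("NIVOLUMAB", "Myasthenia gravis", 20.0, 1500),
    PlantedSignal("PEMBROLIZUMAB", "Neuropathy peripheral", 5.0, 2000),
    PlantedSignal("ATEZOLIZUMAB", "Guillain-Barre syndrome", 2.0, 1500),
    PlantedSignal(("CEMIPLIMAB", "PACLITAXEL"), "Hypoaesthesia", 8.0, 600),
)

#: Non-ICI suspect drugs for background reports.
BACKGROUND_SUSPECTS = ("METFORMIN", "ATORVASTATIN", "LISINOPRIL", "IBUPROFEN",
                       "AMLODIPINE", "PEMETREXED", "CISPLATIN", "CARBOPLATIN")

#: Concomitant pool (role C).
CONCOMITANTS = ("LEVOTHYROXINE", "OMEPRAZOLE", "PANTOPRAZOLE", "PREDNISONE",
                "GABAPENTIN", "FUROSEMIDE", "ONDANSETRON", "DEXAMETHASONE")

#: Indication mix (Table-1-like marginal shares; remainder = Other neoplasm).
INDICATION_MIX = {
    "Lung cancer": 0.177, "Malignant melanoma": 0.175,
    "Renal cell carcinoma": 0.086, "Breast cancer": 0.036,
    "Hepatocellular carcinoma": 0.034, "Gastric cancer": 0.020,
    "Endometrial cancer": 0.019, "Bladder cancer": 0.011,
    "Oesophageal carcinoma": 0.010, "Head and neck cancer": 0.009,
    "Other neoplasm": 0.423,
}

REPORTER_MIX = {"MD": 0.4323, "CN": 0.2752, "PH": 0.1812, "OT": 0.0998,
                "LW": 0.0005, "": 0.0110}

COUNTRY_MIX = {"US": 0.358, "JP": 0.221, "FR": 0.066, "DE": 0.049,
               "CN": 0.038, "CA": 0.033, "GB": 0.025, "IT": 0.023,
               "AU": 0.017, "ES": 0.015, "BR": 0.155}

#: Outcome-code probabilities conditional on the report being serious
#: (codes are not mutually exclusive; a serious report with no draw gets OT).
OUTCOME_MIX_SERIOUS = {"LT": 0.1053, "HO": 0.5586, "DS": 0.0607, "DE": 0.1863,
                       "CA": 0.0003, "RI": 0.0030, "OT": 0.8152}


def _default_sex_mix() -> dict[str, float]:
    return {"M": 0.535, "F": 0.378, "UNK": 0.087}


@dataclass
class SynthConfig:
    """Generator parameters; the defaults are the package's study conditions."""

    n_reports: int = 50_000
    quarters: tuple[str, ...] = ("2023Q1", "2023Q2", "2023Q3", "2023Q4",
                                 "2024Q1", "2024Q2", "2024Q3", "2024Q4")
    seed: int = 0
    sex_mix: dict[str, float] = field(default_factory=_default_sex_mix)
    age_mean_sd: tuple[float, float] = (65.1, 12.76)
    age_missing_rate: float = 0.234
    duplicate_rate: float = 0.10
    deletion_rate: float = 0.02
    name_variant_rate: float = 0.30
    junk_name_rate: float = 0.02
    background_event_rate: float = 0.01
    ici_background_rate: float = 0.15
    cosuspect_rate: float = 0.30
    concomitant_rate: float = 0.8
    planted_signals: tuple[PlantedSignal, ...] = DEFAULT_PLANTED
    outcome_none_rate: float = 0.0877
    outcome_mix: dict[str, float] = field(
        default_factory=lambda: dict(OUTCOME_MIX_SERIOUS))
    tto_lognormal: tuple[float, float] = (math.log(30.0), 1.65)
    event_missing_rate: float = 0.40
    event_month_rate: float = 0.10
    start_missing_rate: float = 0.15
    start_month_rate: float = 0.05

    def validate(self) -> None:
        if self.n_reports < 1:
            raise SynthConfigError("n_reports must be positive")
        if not self.quarters:
            raise SynthConfigError("at least one quarter label required")
        if abs(sum(self.sex_mix.values()) - 1.0) > 1e-6 or min(self.sex_mix.values()) < 0:
            raise SynthConfigError("sex_mix must be probabilities summing to 1")
        for rate_name in ("duplicate_rate", "deletion_rate", "name_variant_rate",
                          "junk_name_rate", "background_event_rate",
                          "ici_background_rate", "cosuspect_rate",
                          "age_missing_rate", "outcome_none_rate",
                          "event_missing_rate", "event_month_rate",
                          "start_missing_rate", "start_month_rate"):
            v = getattr(self, rate_name)
            if not 0.0 <= v <= 1.0:
                raise SynthConfigError(f"{rate_name} must lie in [0, 1]")
        pts = [canonical_pt(s.event_pt) for s in self.planted_signals]
        if len(set(pts)) != len(pts):
            raise SynthConfigError("planted signals must use distinct event PTs")
        for s in self.planted_signals:
            if s.target_ror <= 0:
                raise SynthConfigError(f"signal {s.label}: target_ror must be > 0")
            if s.n_exposed < 1:
                raise SynthConfigError(f"signal {s.label}: n_exposed must be >= 1")
            if s.ici not in TARGET_INGREDIENTS:
                raise SynthConfigError(f"signal {s.label}: {s.ici} is not a target ICI")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "SynthConfig":
        kwargs = dict(data)
        if "planted_signals" in kwargs:
            sigs = []
            for item in kwargs["planted_signals"]:
                exposure = item["exposure"]
                if isinstance(exposure, (list, tuple)):
                    exposure = tuple(exposure)
                sigs.append(PlantedSignal(exposure, item["event_pt"],
                                          float(item["target_ror"]),
                                          int(item["n_exposed"])))
            kwargs["planted_signals"] = tuple(sigs)
        if "quarters" in kwargs:
            kwargs["quarters"] = tuple(kwargs["quarters"])
        for key in ("age_mean_sd", "tto_lognormal"):
            if key in kwargs:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: Path) -> "SynthConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)


@dataclass
class GroundTruth:
    """What the generator actually planted, for oracle-style tests."""

    seed: int
    n_reports: int
    n_active: int
    n_deleted: int
    n_duplicate_versions: int
    signals: list[dict]
    exposed_caseids: dict[str, list[int]] = field(default_factory=dict)
    deleted_caseids: list[int] = field(default_factory=list)

    def to_json(self, path: Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def exposed_event_prob(p0: float, target_ror: float) -> float:
    """Exposed-arm event probability giving odds ratio ``target_ror`` vs p0."""
    if not 0.0 < p0 < 1.0:
        raise SynthConfigError("background event rate must lie strictly in (0, 1)")
    odds = target_ror * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


def _n_deleted(config: SynthConfig) -> int:
    return int(round(config.deletion_rate * config.n_reports))


def expected_table(config: SynthConfig, signal: PlantedSignal) -> TwoByTwo:
    """Deterministic expected-margin 2x2 used for planting (pre-sampling).

    a and c are rounded half-away-from-zero; b and d take the margin
    remainders.  Raises when the target is infeasible for the margins.
    """
    if signal not in config.planted_signals:
        raise SynthConfigError(f"signal {signal.label} not present in config")
    n_active = config.n_reports - _n_deleted(config)
    n_exposed = signal.n_exposed
    if n_exposed >= n_active:
        raise SynthConfigError(
            f"signal {signal.label}: n_exposed {n_exposed} exceeds active universe")
    p0 = config.background_event_rate
    p1 = exposed_event_prob(p0, signal.target_ror)
    a = int(math.floor(n_exposed * p1 + 0.5))
    c = int(math.floor((n_active - n_exposed) * p0 + 0.5))
    b = n_exposed - a
    d = (n_active - n_exposed) - c
    if a < 1 or b < 1 or c < 1 or d < 1:
        raise SynthConfigError(
            f"signal {signal.label}: infeasible target_ror {signal.target_ror} "
            f"for the configured margins (expected cell < 1)")
    return TwoByTwo(a, b, c, d)


# ---------------------------------------------------------------------------
# Universe construction (one row per case)
# ---------------------------------------------------------------------------

def _quarter_bounds(label: str) -> tuple[int, int]:
    """(first, last) day ordinals of a 'YYYYQn' quarter."""
    year, q = int(label[:4]), int(label[5])
    start = date(year, 3 * (q - 1) + 1, 1)
    end = (date(year + 1, 1, 1) if q == 4 else date(year, 3 * q + 1, 1)) - timedelta(days=1)
    return start.toordinal(), end.toordinal()


def _fmt_day(ordinals: np.ndarray) -> np.ndarray:
    """Vectorized YYYYMMDD formatting of day ordinals."""
    days = ordinals.astype("int64") - date(1970, 1, 1).toordinal()
    dt = days.astype("datetime64[D]")
    return np.char.replace(np.datetime_as_string(dt, unit="D"), "-", "")


def _choice(rng: np.random.Generator, mix: Mapping[str, float], n: int) -> np.ndarray:
    labels = np.array(sorted(mix), dtype=object)
    probs = np.array([mix[k] for k in sorted(mix)], dtype=float)
    return labels[rng.choice(len(labels), n, p=probs / probs.sum())]


@dataclass
class _Universe:
    """Internal per-case arrays (pre-duplication)."""

    caseid: np.ndarray
    sex: np.ndarray
    age_years: np.ndarray        # NaN = missing
    fda_ord: np.ndarray
    start_ord: np.ndarray
    tto_days: np.ndarray
    reporter: np.ndarray
    country: np.ndarray
    indication: np.ndarray
    outcome_matrix: np.ndarray   # bool (n, len(outcome_order))
    outcome_order: tuple[str, ...]
    suspect_first: np.ndarray    # object; always present (role PS)
    suspect_second: np.ndarray   # object or None (role SS)
    k_conc: np.ndarray           # concomitant count per case
    conc_flat: np.ndarray        # concatenated concomitant names
    events: np.ndarray           # bool (n, n_vocab)
    vocab: list[str]
    deleted_mask: np.ndarray
    dup_extra: np.ndarray        # extra versions per case (0, 1 or 2)


def _build_universe(config: SynthConfig, rng: np.random.Generator,
                    slice_: MedDraSlice) -> tuple[_Universe, GroundTruth]:
    config.validate()
    n = config.n_reports
    vocab = list(slice_.frame["pt"])
    vocab_canon = [canonical_pt(p) for p in vocab]
    vocab_index = {c: i for i, c in enumerate(vocab_canon)}
    for s in config.planted_signals:
        if canonical_pt(s.event_pt) not in vocab_index:
            raise SynthConfigError(
                f"signal {s.label}: event PT {s.event_pt!r} not in the MedDRA slice")

    n_deleted = _n_deleted(config)
    n_bg_ici = int(round(config.ici_background_rate * n))
    n_planted = sum(s.n_exposed for s in config.planted_signals)
    n_background = n - n_planted - n_bg_ici
    if n_background < 0:
        raise SynthConfigError("planted n_exposed plus ICI background exceeds n_reports")
    if n_background < n_deleted:
        raise SynthConfigError(
            "deletion_rate too high: not enough background reports to delete")

    # --- block assignment over a random permutation -----------------------
    perm = rng.permutation(n)
    cursor = 0
    signal_rows: dict[str, np.ndarray] = {}
    for s in config.planted_signals:
        signal_rows[s.label] = perm[cursor:cursor + s.n_exposed]
        cursor += s.n_exposed
    bg_ici_rows = perm[cursor:cursor + n_bg_ici]
    cursor += n_bg_ici
    background_rows = perm[cursor:]

    planted_icis = {s.ici for s in config.planted_signals}
    ici_pool = sorted(TARGET_INGREDIENTS - planted_icis)

    # --- suspect drug assignment ------------------------------------------
    suspect_first = np.empty(n, dtype=object)
    suspect_second = np.full(n, None, dtype=object)
    bg_pool = np.array(BACKGROUND_SUSPECTS, dtype=object)
    for s in config.planted_signals:
        rows = signal_rows[s.label]
        suspect_first[rows] = s.ici
        if s.partner is not None:
            suspect_second[rows] = s.partner
        else:
            cos = rows[rng.random(len(rows)) < config.cosuspect_rate]
            suspect_second[cos] = bg_pool[rng.integers(0, len(bg_pool), len(cos))]
    if len(bg_ici_rows):
        pool = np.array(ici_pool, dtype=object) if ici_pool else bg_pool
        suspect_first[bg_ici_rows] = pool[rng.integers(0, len(pool), len(bg_ici_rows))]
    if len(background_rows):
        suspect_first[background_rows] = bg_pool[
            rng.integers(0, len(bg_pool), len(background_rows))]

    k_conc = rng.poisson(config.concomitant_rate, n)
    conc_pool = np.array(CONCOMITANTS, dtype=object)
    conc_flat = conc_pool[rng.integers(0, len(conc_pool), int(k_conc.sum()))]

    # --- deletions: sampled from plain-background rows only, so planted
    # margins stay exact on the active universe ----------------------------
    deleted_mask = np.zeros(n, dtype=bool)
    if n_deleted:
        chosen = background_rows[rng.permutation(len(background_rows))[:n_deleted]]
        deleted_mask[chosen] = True

    # --- events -----------------------------------------------------------
    p0 = config.background_event_rate
    events = rng.random((n, len(vocab))) < p0
    signal_meta = []
    for s in config.planted_signals:
        rows = signal_rows[s.label]
        col = vocab_index[canonical_pt(s.event_pt)]
        p1 = exposed_event_prob(p0, s.target_ror)
        events[rows, col] = rng.random(len(rows)) < p1
        exp = expected_table(config, s)
        signal_meta.append({
            "exposure": s.ici, "partner": s.partner,
            "event_pt": canonical_pt(s.event_pt),
            "target_ror": s.target_ror, "n_exposed": s.n_exposed,
            "p0": p0, "p1": p1,
            "expected": {"a": exp.a, "b": exp.b, "c": exp.c, "d": exp.d},
        })
    # every report carries at least one reaction; the forced fallback draws
    # from non-nervous decoys so planted and nervous margins stay untouched
    decoy_cols = np.array([i for i, p in enumerate(vocab_canon)
                           if slice_._lookup[p][1] != "Nervous system disorders"])
    empty = ~events.any(axis=1)
    if empty.any():
        forced = decoy_cols[rng.integers(0, len(decoy_cols), int(empty.sum()))]
        events[np.nonzero(empty)[0], forced] = True

    # --- demographics ------------------------------------------------------
    sex = _choice(rng, config.sex_mix, n)
    mean, sd = config.age_mean_sd
    age = np.clip(rng.normal(mean, sd, n), 0.0, 100.0)
    age[rng.random(n) < config.age_missing_rate] = np.nan
    reporter = _choice(rng, REPORTER_MIX, n)
    country = _choice(rng, COUNTRY_MIX, n)
    indication = _choice(rng, INDICATION_MIX, n)

    serious = rng.random(n) >= config.outcome_none_rate
    outcome_order = tuple(sorted(config.outcome_mix))
    probs = np.array([config.outcome_mix[c] for c in outcome_order])
    outcome_matrix = rng.random((n, len(outcome_order))) < probs
    outcome_matrix &= serious[:, None]
    none_drawn = serious & ~outcome_matrix.any(axis=1)
    if none_drawn.any():  # serious reports always carry at least one code
        ot_col = outcome_order.index("OT") if "OT" in outcome_order else 0
        outcome_matrix[none_drawn, ot_col] = True

    # --- dates --------------------------------------------------------------
    quarter_idx = rng.integers(0, len(config.quarters), n)
    bounds = [_quarter_bounds(q) for q in config.quarters]
    q_start = np.array([b[0] for b in bounds])[quarter_idx]
    q_end = np.array([b[1] for b in bounds])[quarter_idx]
    fda_ord = q_start + (rng.random(n) * (q_end - q_start + 1)).astype(int)
    log_mu, log_sigma = config.tto_lognormal
    tto = np.minimum(np.round(rng.lognormal(log_mu, log_sigma, n)), 5000).astype(int)
    lag = rng.integers(0, 60, n)
    start_ord = fda_ord - tto - lag

    # --- duplicate versions -------------------------------------------------
    dup_extra = np.zeros(n, dtype=np.int64)
    n_dup_cases = int(round(config.duplicate_rate * n))
    if n_dup_cases:
        dup_cases = rng.permutation(n)[:n_dup_cases]
        dup_extra[dup_cases] = rng.integers(1, 3, n_dup_cases)

    universe = _Universe(
        caseid=np.arange(10_000_001, 10_000_001 + n, dtype=np.int64),
        sex=sex, age_years=age, fda_ord=fda_ord, start_ord=start_ord,
        tto_days=tto, reporter=reporter, country=country,
        indication=indication, outcome_matrix=outcome_matrix,
        outcome_order=outcome_order, suspect_first=suspect_first,
        suspect_second=suspect_second, k_conc=k_conc, conc_flat=conc_flat,
        events=events, vocab=vocab, deleted_mask=deleted_mask,
        dup_extra=dup_extra,
    )
    truth = GroundTruth(
        seed=config.seed, n_reports=n, n_active=n - n_deleted,
        n_deleted=n_deleted, n_duplicate_versions=int(dup_extra.sum()),
        signals=signal_meta,
        exposed_caseids={s.label: sorted(int(c) for c in
                                         universe.caseid[signal_rows[s.label]])
                         for s in config.planted_signals},
        deleted_caseids=sorted(int(c) for c in universe.caseid[deleted_mask]),
    )
    return universe, truth


# ---------------------------------------------------------------------------
# Frame assembly (FAERS-dialect tables), fully vectorized
# ---------------------------------------------------------------------------

def _date_strings(ordinals: np.ndarray, rng: np.random.Generator,
                  missing_rate: float, month_rate: float) -> np.ndarray:
    """YYYYMMDD strings, degraded to YYYYMM or '' at the configured rates."""
    full = _fmt_day(ordinals)
    u = rng.random(len(ordinals))
    out = full.astype(object)
    out[u < missing_rate] = ""
    month = (u >= missing_rate) & (u < missing_rate + month_rate)
    out[month] = [s[:6] for s in full[month]]
    return out


def _apply_name_variants(names: pd.Series, is_target: np.ndarray,
                         dictionary: DrugDictionary, rng: np.random.Generator,
                         variant_rate: float, junk_rate: float) -> pd.Series:
    """Swap ingredient mentions for synonyms (any row) or junk (non-target only)."""
    out = names.to_numpy(dtype=object).copy()
    u = rng.random(len(names))
    use_variant = u < variant_rate
    use_junk = (~is_target) & (u >= variant_rate) & (u < variant_rate + junk_rate)
    arr = names.to_numpy(dtype=object)
    for ingredient in sorted(set(arr[use_variant])):
        syns = dictionary.synonyms_for(ingredient)
        if not syns:
            continue
        mask = use_variant & (arr == ingredient)
        idx = rng.integers(0, len(syns), int(mask.sum()))
        out[mask] = np.array(syns, dtype=object)[idx]
    n_junk = int(use_junk.sum())
    if n_junk:
        out[use_junk] = np.array(
            [f"UNVERIFIED COMPOUND {k}" for k in rng.integers(100, 999, n_junk)],
            dtype=object)
    return pd.Series(out, index=names.index, name=names.name)


def _within_group_offsets(counts: np.ndarray) -> np.ndarray:
    """[0,1,...,k0-1, 0,1,...,k1-1, ...] for group sizes ``counts``."""
    total = int(counts.sum())
    starts = np.cumsum(counts) - counts
    return np.arange(total) - np.repeat(starts, counts)


def generate_frames(config: SynthConfig,
                    rng: np.random.Generator | None = None,
                    dictionary: DrugDictionary | None = None,
                    slice_: MedDraSlice | None = None,
                    ) -> tuple[dict[str, pd.DataFrame], dict[str, set[str]], GroundTruth]:
    """Generate all tables in memory.

    Returns (tables, deleted_by_quarter, ground_truth).  ``tables`` holds one
    pooled frame per FAERS table (with an extra ``quarter`` column on DEMO);
    ``deleted_by_quarter`` maps quarter label -> deleted CASEID strings.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if dictionary is None:
        dictionary = load_drug_dictionary()
    if slice_ is None:
        slice_ = load_meddra_slice()
    uni, truth = _build_universe(config, rng, slice_)
    n = config.n_reports

    # version layout: primaryid = caseid*10 + version; the kept version is the
    # last one (largest FDA_DT, ties broken by the larger PRIMARYID)
    n_versions = uni.dup_extra + 1
    case_rep = np.repeat(np.arange(n), n_versions)
    version_no = _within_group_offsets(n_versions) + 1
    is_kept = version_no == n_versions[case_rep]
    caseid_v = uni.caseid[case_rep]
    primaryid_v = caseid_v * 10 + version_no
    pid_str = primaryid_v.astype(str)

    # earlier versions: receipt date pulled back 0-120 days (0 exercises the
    # PRIMARYID tie-break)
    back = np.where(is_kept, 0, rng.integers(0, 121, len(case_rep)))
    first_q_start = min(_quarter_bounds(q)[0] for q in config.quarters)
    fda_ord_v = np.maximum(uni.fda_ord[case_rep] - back, first_q_start)

    # quarter of each version = quarter containing its receipt date (clamped)
    bounds = [_quarter_bounds(q) for q in config.quarters]
    starts = np.array([b[0] for b in bounds])
    order = np.argsort(starts)
    qi = np.clip(np.searchsorted(starts[order], fda_ord_v, side="right") - 1,
                 0, len(bounds) - 1)
    quarter_v = np.array(config.quarters, dtype=object)[order][qi]

    # ages carried identically across versions; unit noise exercises DEC/MON
    unit_u = rng.random(n)
    age_unit_case = np.where(unit_u < 0.05, "DEC",
                             np.where(unit_u < 0.07, "MON", "YR")).astype(object)
    age_str_case = np.empty(n, dtype=object)
    for i in range(n):
        a = uni.age_years[i]
        if math.isnan(a):
            age_str_case[i] = ""
            age_unit_case[i] = ""
        elif age_unit_case[i] == "DEC":
            age_str_case[i] = f"{a / 10.0:.1f}"
        elif age_unit_case[i] == "MON":
            age_str_case[i] = str(int(round(a * 12)))
        else:
            age_str_case[i] = str(int(round(a)))

    event_ord_v = uni.start_ord[case_rep] + uni.tto_days[case_rep]
    demo = pd.DataFrame({
        "primaryid": pid_str,
        "caseid": caseid_v.astype(str),
        "fda_dt": _fmt_day(fda_ord_v),
        "event_dt": _date_strings(event_ord_v, rng, config.event_missing_rate,
                                  config.event_month_rate),
        "sex": uni.sex[case_rep],
        "age": age_str_case[case_rep],
        "age_cod": age_unit_case[case_rep],
        "occp_cod": uni.reporter[case_rep],
        "reporter_country": uni.country[case_rep],
        "quarter": quarter_v,
    })

    # versions frame used to fan case-level payload rows out to every version
    versions = pd.DataFrame({"case_row": case_rep, "primaryid": pid_str})

    def fan_out(case_level: pd.DataFrame) -> pd.DataFrame:
        out = versions.merge(case_level, on="case_row", how="inner")
        return out.drop(columns="case_row")

    # --- DRUG + THER (case-level first) ------------------------------------
    has_second = np.array([s is not None for s in uni.suspect_second])
    n_susp = 1 + has_second.astype(int)
    ps = pd.DataFrame({"case_row": np.arange(n), "drug_seq": 1,
                       "role_cod": "PS", "drugname": uni.suspect_first})
    ss = pd.DataFrame({"case_row": np.nonzero(has_second)[0], "drug_seq": 2,
                       "role_cod": "SS",
                       "drugname": uni.suspect_second[has_second]})
    conc = pd.DataFrame({
        "case_row": np.repeat(np.arange(n), uni.k_conc),
        "drug_seq": np.repeat(n_susp, uni.k_conc) + _within_group_offsets(uni.k_conc) + 1,
        "role_cod": "C",
        "drugname": uni.conc_flat,
    })
    drug_case = pd.concat([ps, ss, conc], ignore_index=True)
    drug_case = drug_case.sort_values(["case_row", "drug_seq"],
                                      kind="mergesort").reset_index(drop=True)
    is_target_row = drug_case["drugname"].isin(TARGET_INGREDIENTS).to_numpy()
    drug_case["drugname"] = _apply_name_variants(
        drug_case["drugname"], is_target_row, dictionary, rng,
        config.name_variant_rate, config.junk_name_rate)

    suspect_case = drug_case[drug_case["role_cod"].isin(["PS", "SS"])].copy()
    start_case = _date_strings(uni.start_ord[suspect_case["case_row"].to_numpy()],
                               rng, config.start_missing_rate,
                               config.start_month_rate)
    end_blank = rng.random(len(suspect_case)) < 0.5
    end_ord = (uni.start_ord[suspect_case["case_row"].to_numpy()]
               + rng.integers(1, 180, len(suspect_case)))
    end_case = _fmt_day(end_ord).astype(object)
    end_case[end_blank] = ""
    ther_case = pd.DataFrame({
        "case_row": suspect_case["case_row"].to_numpy(),
        "dsg_drug_seq": suspect_case["drug_seq"].to_numpy(),
        "start_dt": start_case, "end_dt": end_case,
    })

    drug = fan_out(drug_case)
    drug["drug_seq"] = drug["drug_seq"].astype(str)
    drug = drug[TABLE_COLUMNS["drug"]]
    ther = fan_out(ther_case)
    ther["dsg_drug_seq"] = ther["dsg_drug_seq"].astype(str)
    ther = ther[TABLE_COLUMNS["ther"]]

    # --- REAC ---------------------------------------------------------------
    ev_case, ev_col = np.nonzero(uni.events)
    vocab_arr = np.array(uni.vocab, dtype=object)
    reac = fan_out(pd.DataFrame({"case_row": ev_case, "pt": vocab_arr[ev_col]}))
    reac = reac[TABLE_COLUMNS["reac"]]

    # --- OUTC / INDI --------------------------------------------------------
    oc_case, oc_col = np.nonzero(uni.outcome_matrix)
    code_arr = np.array(uni.outcome_order, dtype=object)
    outc = fan_out(pd.DataFrame({"case_row": oc_case, "outc_cod": code_arr[oc_col]}))
    outc = outc[TABLE_COLUMNS["outc"]]
    indi = fan_out(pd.DataFrame({"case_row": np.arange(n), "indi_drug_seq": "1",
                                 "indi_pt": uni.indication}))
    indi = indi[TABLE_COLUMNS["indi"]]

    # deleted cases: each assigned to one quarter's deletion list
    deleted_by_quarter: dict[str, set[str]] = {q: set() for q in config.quarters}
    deleted_cases = uni.caseid[uni.deleted_mask]
    if len(deleted_cases):
        qpick = rng.integers(0, len(config.quarters), len(deleted_cases))
        for cid, qidx in zip(deleted_cases, qpick):
            deleted_by_quarter[config.quarters[qidx]].add(str(cid))

    # deterministic emission order
    demo = demo.sort_values("primaryid", kind="mergesort").reset_index(drop=True)
    tables = {"demo": demo}
    for name, df in (("drug", drug), ("reac", reac), ("outc", outc),
                     ("indi", indi), ("ther", ther)):
        tables[name] = (df.sort_values("primaryid", kind="mergesort")
                        .reset_index(drop=True))
    return tables, deleted_by_quarter, truth


def generate(config: SynthConfig, out_dir: Path,
             dictionary: DrugDictionary | None = None,
             slice_: MedDraSlice | None = None) -> GroundTruth:
    """Emit quarterly FAERS-dialect packages plus ground_truth.json under ``out_dir``."""
    out_dir = Path(out_dir)
    tables, deleted_by_quarter, truth = generate_frames(
        config, dictionary=dictionary, slice_=slice_)
    demo = tables["demo"]
    for q in config.quarters:
        qdir = out_dir / q
        qdir.mkdir(parents=True, exist_ok=True)
        q_demo = demo[demo["quarter"] == q]
        pids = set(q_demo["primaryid"])
        write_faers_table(q_demo[TABLE_COLUMNS["demo"]], qdir / "DEMO.txt")
        for name in ("drug", "reac", "outc", "indi", "ther"):
            df = tables[name]
            write_faers_table(df[df["primaryid"].isin(pids)][TABLE_COLUMNS[name]],
                              qdir / f"{name.upper()}.txt")
        with open(qdir / "DELETED.txt", "w", encoding="utf-8", newline="\n") as fh:
            for cid in sorted(deleted_by_quarter[q]):
                fh.write(cid + "\n")
    truth.to_json(out_dir / "ground_truth.json")
    return truth
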
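# Methods

## Setting and unit of analysis

The package analyses spontaneous adverse-event reports in the FAERS ASCII
dialect.  A *case* (CASEID) may appear as several versions (PRIMARYID)
within and across quarterly packages; the cleaning step keeps, per case, the
version with the largest receipt date FDA_DT, breaking ties by the largest
PRIMARYID, and then removes cases named in the union of all quarters'
deleted-case lists.  Receipt dates at YEAR/MONTH precision are right-padded
("0101"/"01") so the comparator is total; PRIMARYIDs are compared numerically
when fully numeric, lexicographically otherwise.  Deletion lists are applied
globally (a case deleted in one quarter must not resurface from an earlier
package) and to the kept set, since deletion follows deduplication.

The unit of analysis everywhere — contingency cells, cohort denominators —
is the deduplicated report ("one report = one patient row").  A second,
record-level count (report × nervous-system PT pairs) is emitted in the run
manifest, because spontaneous-report studies commonly quote both and the two
differ whenever a report carries several nervous-system terms.  Counting
records in the 2×2 cells would double-count multi-PT reports in the b/d
margins, so the report is the cell unit.

## Exposure, events, and the screened statistic

Exposure to a target immune checkpoint inhibitor requires a *suspect* role
(PS or SS) on the report; concomitant (C) or interacting (I) mentions do not
qualify.  This is standard disproportionality practice; the role set is a
config switch (`roles`).  Verbatim drug strings are canonicalized
(upper-case, whitespace collapse, trailing dose/form tokens from a fixed
versioned list stripped) and looked up in a synonym dictionary.  The shipped
dictionary is a license-free fixture of ~80 synonyms (generics, major trade
names, misspellings the generator emits); it is *not* the licensed WHO Drug
Dictionary, whose role it plays behind the same interface.  Unmatched names
are retained verbatim with a `RAW:` prefix so combination partners are never
silently lost.

Events are MedDRA preferred terms (PTs) mapped through a shipped slice
(pt → HLGT → SOC, one primary HLGT per PT, no multi-axiality) covering ~50
nervous-system PTs across 12 HLGTs plus ~30 non-nervous decoys.  PTs absent
from the slice are excluded from the signal analysis and counted in the
manifest; nothing is guessed.  Nervous-system events are all PTs whose SOC
is "Nervous system disorders".

For each (exposure, event) pair over a universe of deduplicated reports the
2×2 table (a, b, c, d) is formed, each report counted exactly once, and

    ROR = ad/bc,   SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d),
    95% CI = exp(ln ROR ± 1.96·SE).

A pair is a signal when a ≥ 3 and the CI lower bound (ROR_025) is strictly
above 1.  No continuity correction is applied: a zero cell yields an
"undefined" result (the a ≥ 3 rule already excludes sparse numerators, and
an invented estimate would be worse than an absent one).  No
multiple-testing adjustment is made; the manifest reports the number of
tests performed.  Ranked selections sort by ROR_025 descending with
deterministic tie-breaks (a descending, then event label ascending).

Analyses built on that statistic:

* per-drug and pooled ("ANY_ICI") PT-level screens; for the pooled screen
  the comparator automatically excludes all ICI reports, for per-drug
  screens other-ICI reports stay in the comparator unless
  `exclude_other_icis` is set (the choice is explicit per analysis);
* HLGT-level screens (event = any PT under the HLGT);
* sex and age stratification (age bands: young < 45, middle 45–64,
  elderly ≥ 65; config-overridable since no standard cutoffs exist), with
  missing-stratum reports excluded from that dimension;
* monotherapy sensitivity analysis: exposure restricted to reports with
  exactly one target ICI and no other suspect drug (concomitants ignored);
* combination analysis: exposure = ICI suspect AND partner among
  partner-role ingredients (default PS/SS/C/I, a config switch, since
  plausible partners such as levothyroxine are often concomitant); pairs are
  discovered at a minimum co-occurrence count (default 10 reports).

## Cohort description

The cohort is every deduplicated report with at least one target-ICI
exposure and at least one nervous-system PT.  All percentages use the
report-level cohort size as denominator and are rounded half-up to two
decimals, only at presentation.  Outcome percentages may sum above 100
because a report can carry several outcome codes; a report is *serious* iff
it has at least one outcome record.  Ages convert to years by unit
(decades ×10, months /12, weeks /52.143, days /365.25, hours /8766);
values above 120 years are treated as implausible and set missing.  Time to
onset is the day count from the earliest DAY-precision therapy start of a
target-ICI drug record to the DAY-precision event date; partial dates or
negative intervals yield missing.  Quartiles use the median-of-halves
convention excluding the median at odd n (deterministic, integer-friendly;
an approximation relative to interpolating definitions).  Countries and
indications are ranked by count, ties alphabetical, and country strings pass
through a small normalization map (e.g. "US"/"USA" → "United States of
America").

One published-table inconsistency is documented rather than chased: in the
HLGT share block, the four explicit groups (9,168 + 3,007 + 2,822 + 1,606)
plus a printed remainder of "5,638 (24.43%)" do not reach the stated 21,971
total — 5,368 does, and 5,368/21,971 = 24.43%, so the remainder count is a
transposition typo.  Similarly the published indication percentages imply a
slightly different denominator than the sex block; the package applies one
report-level denominator throughout.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
defaults chosen as the package's study conditions: n = 50,000 cases over
eight quarters; sex mix 0.535/0.378/0.087 (M/F/unknown); age ~
Normal(65.1, 12.76) truncated to [0, 100] with 23.4% missing; reporter,
country and indication mixes matching a large ICI-neurotoxicity cohort;
8.77% non-serious reports and overlapping outcome codes; onset days ~
LogNormal(ln 30, 1.65) — median-and-quartile matched, so its mean is heavier
than a real cohort's; 10% duplicate cases (2–3 versions, occasional
receipt-date ties to exercise the PRIMARYID tie-break), 2% deleted cases,
30% trade-name/misspelling mentions, 2% junk drug names, and partial-date
noise on event and therapy-start dates.

Disproportionality is planted by solving the exposed-arm event probability
p1 from the background rate p0 (1% per PT) and the target ROR ρ:
p1/(1−p1) = ρ·p0/(1−p0).  Event indicators are then drawn per report, so
cells are binomial around a closed-form expected table
(`expected_table`, the oracle used in tests), and the odds ratio of the
generating process equals ρ exactly.  Default planted signals: ROR 20
(nivolumab–myasthenia gravis, 1,500 exposed), ROR 5 (pembrolizumab–
peripheral neuropathy, 2,000), ROR 2 (atezolizumab–Guillain-Barré, 1,500),
and one combination signal (cemiplimab+paclitaxel–hypoaesthesia, ROR 8,
600).  To keep the planted margins exact, drugs carrying planted signals are
excluded from the background-ICI pool, deleted cases are sampled from the
plain-background block only, and junk names are never applied to target-ICI
mentions (synonym variants, which normalize back, are applied everywhere).
Duplicate versions replicate the kept version's payload, so deduplication
leaves the planted 2×2 unchanged.

All randomness flows from a single seeded `numpy` generator and emission
order is sorted by PRIMARYID, giving byte-identical packages per seed.
Outputs of the analysis pipeline carry no wall-clock timestamps for the same
reason; the manifest records the effective config and counts instead.

What the generator does *not* model: reporting-delay dynamics, drug
market-share trends, correlated events within drug classes, real FAERS
marginal distributions beyond the configured mixes, and free-text noise
other than the fixed synonym/junk scheme.  Tests that pass on these data
therefore validate the pipeline's correctness and calibration under the
stated generating process, not the clinical findings obtainable from the
real database.

## Verification strategy and problem sizes

* Engine: 10,000 random all-positive tables against an independently
  assembled closed form (log-odds difference, CI by multiplication) at 1e-9
  relative error; reciprocal symmetry under exposure swap; strict behaviour
  at the a = 3 / ROR_025 = 1 boundary.
* Dedup: exact equivalence with a brute-force max-key oracle on 1,000
  randomized multi-version cases; idempotence; order-invariance;
  conservation (read = kept + duplicates + deleted).
* Calibration: 200 seeded replicates at n = 50,000 per planted ROR in
  {2, 5, 20}; the planted value falls in the estimated 95% CI at the nominal
  rate within a 3-SD binomial band.  Null replicates (no planted signals,
  uniform background) match a brute-force Monte-Carlo estimate of the
  criterion's false-positive rate within 3 SD.
* End-to-end: two generator+pipeline runs with one seed/config are
  byte-identical; generated packages re-read with zero dropped rows.

The replicate suites run the in-memory pipeline (generate → dedup →
normalize → map → screen); file round-tripping is exercised separately, once,
since CSV serialization does not alter counts.

## Known limitations

* Exact-match normalization only — no edit-distance matching, ATC classes
  or dose parsing; unmatched names reach the combination analysis as `RAW:`
  labels.
* One primary HLGT per PT; no SMQs, no LLT→PT recoding.
* The Wald (log-scale normal) interval undercovers slightly for very sparse
  cells; with the a ≥ 3 criterion in place this is immaterial at the tested
  margins but matters for rare-event extrapolation.
* "Young/middle/elderly" age cutoffs are conventions, not published
  definitions.
* The published cohort's absolute counts are not reproducible here by
  design: they require the licensed dictionaries and the real FAERS
  download, both outside this package's scope.
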
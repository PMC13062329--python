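# neurovigil

Pharmacovigilance disproportionality analysis of **neurological adverse
events under immune checkpoint inhibitors (ICIs)** over spontaneous-report
data in the FAERS ASCII dialect, together with a synthetic-data generator
that makes every pipeline stage testable without the real download.

Spontaneous-report databases such as the FDA Adverse Event Reporting System
(FAERS) collect case reports of suspected drug–event associations.  Because
there is no denominator of treated patients, association is screened by
*disproportionality*: for an exposure E (here, one of ten ICIs — six
anti-PD-1, three anti-PD-L1, one anti-CTLA-4 antibody) and an event Y (a
MedDRA preferred term under the "Nervous system disorders" system organ
class), the reports are cross-classified as

|             | event Y | no event Y |
|-------------|---------|-----------|
| exposed     | a       | b         |
| not exposed | c       | d         |

and the **reporting odds ratio** is

```
ROR = (a/c) / (b/d) = ad / bc
SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d)
95% CI     = exp( ln ROR ± 1.96 · SE )
```

A pair is flagged as a *signal* when `a ≥ 3` and the CI lower bound
(`ROR_025`) exceeds 1.  The package implements the full analysis around that
statistic:

* **faers_io** — "$"-delimited quarterly packages (DEMO/DRUG/REAC/OUTC/INDI/
  THER + deleted-case lists), lenient typed parsing, partial dates;
* **dedup** — the FDA rule: per CASEID keep max (FDA_DT, PRIMARYID), then
  remove cases named in any deletion list;
* **drug_normalize** — synonym-dictionary normalization of verbatim drug
  strings; exposure = target ICI in a suspect role (PS/SS);
  monotherapy/combination classification;
* **meddra_map** — PT → HLGT → SOC slice lookup, nervous-system event
  selection;
* **descriptives** — the cohort table: sex, age, year, reporter, country,
  seriousness, outcomes, indications, time to onset;
* **signal_detection** — PT- and HLGT-level ROR screens, top-k ranking by
  ROR_025, sex/age stratification, monotherapy sensitivity analysis and
  ICI+partner combination analysis;
* **synthetic_data** — generator with *planted* signals of known ROR,
  duplicate case versions, deletion lists, trade-name/misspelling variants
  and partial dates;
* **cli** — `pv-synth` and `pv-signal` console scripts orchestrating the
  whole run with a JSON manifest and conservation audit.

## Worked example

```bash
pv-synth --out /tmp/faers --seed 1          # 50,000 synthetic cases
pv-signal run --input /tmp/faers --out /tmp/analysis
```

The first command prints

```
wrote 8 quarter(s) to /tmp/faers (50000 cases, 7526 duplicate versions, 1000 deleted)
```

and the second prints the manifest counts, e.g.

```
"reports_read": 57526, "reports_kept": 49000,
"removed_as_duplicate": 7526, "removed_as_deleted": 1000,
"cohort_reports": 6181, "nirae_records": 8288
```

— 57,526 report versions collapse to 49,000 current reports (7,526 duplicate
versions and 1,000 deleted cases removed, matching the generator's ledger
exactly), of which 6,181 reports carry both an ICI exposure and at least one
nervous-system PT.  In `/tmp/analysis/signals_pt.csv` the three planted
single-drug signals are recovered with their planted ROR inside the 95% CI:

```
NIVOLUMAB     MYASTHENIA GRAVIS       a=277  ROR=22.42 [19.13, 26.28]  (planted 20)
PEMBROLIZUMAB NEUROPATHY PERIPHERAL   a=103  ROR=5.57  [4.47, 6.93]    (planted 5)
ATEZOLIZUMAB  GUILLAIN-BARRE SYNDROME a=26   ROR=1.72  [1.16, 2.57]    (planted 2)
```

`table1.csv` holds the cohort description and `signals_*.csv` the HLGT,
stratified, sensitivity and combination screens.

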
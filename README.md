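# pvsignals

Disproportionality signal detection and descriptive analytics for
spontaneous adverse-event reporting systems (SRS), built around the study
design used in pharmacovigilance analyses of immune checkpoint inhibitors
(ICIs) and neurological immune-mediated adverse events (NAEs) in FAERS and
JADER.

It is a library for pharmacoepidemiologists and biostatisticians who work
with raw SRS table dumps: it ingests FAERS-style `$`-delimited quarters and
JADER-style CSV exports, deduplicates report versions, normalizes drug
names and MedDRA preferred terms (PTs) into composite event groups, and
computes the standard battery of signal-detection statistics together with
the descriptive analyses that accompany them (demographics, annual trend,
time to onset, mortality, severity association). A ground-truthed
synthetic-database generator makes the whole pipeline testable without
access to the regulatory bulk downloads.

## The statistics

For each drug–event pair over the deduplicated cases, the 2×2 table

|            | event | no event |
|------------|-------|----------|
| drug       | a     | b        |
| no drug    | c     | d        |

with `N = a+b+c+d` and expected count `E = (a+b)(a+c)/N` yields:

- **ROR** = ad/bc with Woolf CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
- **PRR** = `[a/(a+b)] / [c/(c+d)]` with Pearson χ²;
- **BCPNN IC** = `log2((a+½)/(E+½))` with the Norén credibility bound
  `IC − 3.3(a+½)^−½ − 2.0(a+½)^−¾` (an EBGM-coupled convention
  `IC = log2(EBGM)` is also available);
- **MGPS EBGM/EB05**: the DuMouchel gamma-Poisson shrinker — a
  two-component gamma mixture prior on the reporting-rate ratio λ, fitted
  by maximum marginal likelihood over the whole drug×event grid (negative
  binomial marginals), with EBGM the posterior geometric mean and EB05 the
  exact 5th posterior percentile.

A pair is a **signal** when at least one algorithm meets its criterion
(ROR: a ≥ 3 and CI lower bound > 1; PRR: a ≥ 3, PRR ≥ 2, χ² ≥ 4; BCPNN:
IC025 > 0; MGPS: EB05 > 2). All thresholds and conventions are
configuration, not constants.

## Worked example

`examples/simulate_and_detect.py` plants one signal (atezolizumab ×
myasthenia gravis, relative risk 10) in a 20,000-case synthetic database,
writes it as raw FAERS-dialect files, re-ingests them, and ranks drugs
against the myasthenia-gravis spectrum:

```
raw demo rows: 22021, deduplicated cases: 20000
         drug   a   ror  prr    chi2  ebgm  ebgm05  ic025  overall_signal
 atezolizumab 431 10.51 8.39 1550.20  4.88    4.67   2.11            True
    nivolumab 170  0.51 0.52   62.55  0.63    0.56  -1.00           False
pembrolizumab  87  0.58 0.59   23.51  0.66    0.56  -1.09           False
   ipilimumab  38  0.49 0.50   18.65  0.61    0.48  -1.58           False
   durvalumab  31  0.58 0.59    8.69  0.69    0.54  -1.45           False
```

The planted pair is recovered with every algorithm flagging (note the EBGM
shrinkage relative to the raw ROR); the 10% injected duplicate report
versions are collapsed back to exactly 20,000 cases. The other examples
cover raw-table ingestion (`ingest_raw_tables.py`), the descriptive
analyses (`descriptive_analytics.py`), and consistency checks of the
shipped published reference tables (`published_table_checks.py`), e.g.:

```
annual NAE trend: Spearman r = 0.9855 (p = 9.3e-14)
MG_SPECTRUM  404/1319 -> 30.63%
NAE share of all reports: 3999/170053 -> 2.35%
```

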
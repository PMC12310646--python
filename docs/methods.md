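# Methods

This note records the models, conventions and design choices behind
`pvsignals`, in the spirit of a statistical methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Case model and deduplication

A spontaneous reporting system is modelled as a set of *cases*, each
observed as one or more *report versions*. A version carries a
demographic row plus child rows: drugs (with role codes PS/SS/C/I),
coded reactions (MedDRA preferred terms), outcomes (DE/LT/HO/DS/CA/RI/OT),
and indications. Deduplication keeps, per case identifier, the version
with the maximal `(receipt date, report sequence)` key — the standard
latest-version convention; exact ties fall back to last-read order and are
counted. The rule is idempotent, and the surviving case count equals the
number of distinct case identifiers with a demographic row. Child rows
without a demographic parent are orphans: dropped and counted rather than
guessed at.

Partial dates (`YYYYMM`, `YYYY`) are zero-padded for version ordering but
treated as unknown wherever day precision would be fabricated (event
dates, drug start dates, time-to-onset). FAERS age units
(YR/DEC/MON/WK/DY/HR) are converted to years; an unrecognized unit maps to
unknown rather than to a wrong magnitude. Age bands are `<18`, `18–64`,
`65–84` (ages below 85), `≥85`, `UNK`. The reporting country is the
reporter-country field, falling back to the occurrence country. Column
dialects across FAERS eras (e.g. `isr`/`case` in legacy quarters) are
handled by a configurable alias map; the same mechanism adapts the JADER
reader to user-supplied headers, including Japanese column names.

## Vocabularies

Drug strings are resolved to ingredients by exact lookup after cleaning
(case-fold, punctuation to whitespace, dosage-token stripping), first on
the whole string and then token-wise when all matching tokens agree (the
`"OPDIVO (NIVOLUMAB)"` pattern). No fuzzy matching: spelling variants
belong in the synonym table, which users can extend via TSV. The shipped
dictionary covers the seven target checkpoint inhibitors plus
tremelimumab with common brand names; it is deliberately minimal because
no authoritative synonym list accompanies published analyses.

PTs map to composite event groups (the NAE categories: AIE, the GBS
spectrum, CIDP, the MG spectrum, immune-mediated myopathy, myelitis,
NMOSD, MOGAD, multiple sclerosis, ADEM, aseptic meningitis, CNS
vasculitis) by exact normalized lookup; each PT belongs to exactly one
group. Groups that published analyses found signal-free (myelitis as
noninfectious PT, ADEM, multiple sclerosis) remain in the map so null
findings stay testable. The HLT-style clustering used in forest plots is
the same mechanism with a second grouping file, not a licensed MedDRA
hierarchy traversal.

Severity follows the outcome-code rule used for SRS mortality analyses:
SERIOUS iff the outcome set contains death (DE), NON_SERIOUS for any other
non-empty set, UNKNOWN when no outcome was filed.

**Counting unit.** Everywhere, the unit is the deduplicated case: a case
with two PTs of one group contributes one to that group's count, and the
2×2 background for every pair is the full deduplicated store of the same
database.

## Disproportionality

ROR, PRR and Pearson χ² are the textbook closed forms (χ² without
continuity correction by default; Yates available). Zero cells leave
ROR/PRR undefined rather than silently Haldane-corrected: the a ≥ 3
minimum-count criterion makes corrected micro-signals irrelevant, and a
`haldane=True` switch exists for comparability with other software.
Undefined statistics always fail their signal flag.

### MGPS

The gamma-Poisson shrinker puts a two-component gamma mixture prior
Γ(α₁,β₁)/Γ(α₂,β₂) with weight w on the rate ratio λ = a/E. The marginal
count is negative binomial, and the five parameters are fitted by bounded
L-BFGS-B maximum likelihood from the canonical start (0.2, 0.1, 2.0, 4.0,
⅓) over the full drug×event grid, zero cells included (a truncated a ≥ 1
variant is available). Parameter box: 1e−4…1e4 for shapes/rates,
1e−4…1−1e−4 for w; if the likelihood is non-finite at the canonical start,
a fixed log-spaced grid of restarts is tried in deterministic order. The
posterior is conjugate (mixture of Γ(αᵢ+a, βᵢ+E) with Bayes-updated
weight); EBGM = exp(E[log λ]) via digamma, and EB05 is the exact mixture
quantile found by root bracketing between the two component quantiles
(relative tolerance 1e−8). A log-normal approximation
EBGM·exp(−1.645/√a) is provided because published EBGM05 columns are often
computed that way; the shipped reference table matches it to within 1.5%
on the FAERS rows but visibly not on the JADER rows, so the convention is
configurable and never silently assumed.

### Information component

Two conventions, selected by `ic_convention`:

- `noren` (default for signal flags): IC = log2((a+½)/(E+½)), lower bound
  IC − 3.3(a+½)^−½ − 2.0(a+½)^−¾. Self-contained and well-calibrated
  (≈2.5% of null pairs exceed 0).
- `ebgm_coupled`: IC = log2(EBGM) with lower bound IC − 1.96/(√a·ln 2).
  Published ICI signal tables satisfy IC = log2(EBGM) row-by-row, which is
  what this convention encodes; their printed IC025 columns do not match
  any single standard formula exactly (the JADER rows sit at a constant
  offset), so no claim is made that this reproduces the original bounds.

### Signal rule

`overall_signal` is the OR of the four per-algorithm flags (ROR: a ≥ 3 and
ROR CI lower bound > 1; PRR: a ≥ 3, PRR ≥ 2, χ² ≥ 4; BCPNN: IC025 > 0
strictly; MGPS: EB05 > 2 strictly). All thresholds live in
`SignalCriteria`. Requiring all four flags instead of any is strictly more
conservative, which the tests verify as an operating-characteristic
direction.

## Descriptive analyses

- **Annual trend**: cases per calendar year of the retained report
  version (the year of the version-selection key — whether original
  analyses used event year or report year is not stated anywhere, so the
  choice is documented here). Spearman correlation with mid-ranks for
  ties; exact permutation p by full enumeration for ≤ 10 years,
  t-approximation otherwise.
- **Time to onset**: onset date of the earliest qualifying reaction minus
  the drug start date, per target drug and pooled (earliest start among
  the case's matched exposures). Only fully dated, non-negative intervals
  enter; exclusions are counted so that usable + negative + undated =
  candidates. Quartiles by linear interpolation between order statistics
  (median of {10,20,30,40,50} is 30, quartiles 20 and 40), stated in the
  output. Histogram at a 30-day default bin width.
- **Mortality**: per event group, deaths (DE) over case reports, as a
  percentage to 2 dp. Denominators are case counts per group.
- **Severity association**: per group, a 2×2 of (in-group vs other
  NAE cases) × (serious vs non-serious) over cases with known outcome;
  Pearson χ² without correction, with Fisher's exact test substituted
  (and recorded) when any expected cell is below 5. The universe
  definition — all NAE cases with known outcome — is an assumption made
  explicit because published severity tables do not print their totals.
- **Demographics**: per-drug counts and column percentages for sex, age
  band, weight band, reporter, outcome, country, indication and year.
  When a case carries several outcome codes, the tabulated one is chosen
  by clinical priority (DE > LT > DS > HO > RI > CA > OT), since published
  demographic tables assign one outcome per case without stating a rule.

## Synthetic databases

The generator emulates the *structure* that the pipeline must survive,
with defaults set to the study conditions the analyses describe: one
suspect drug per case from power-law popularity weights; events included
independently with background probabilities (rare neurological PTs
against common general PTs), multiplied by planted relative risks and
capped at 1, redrawing until each case has ≥ 1 event; log-normal onset
days (μ = ln 30, σ = 0.8, i.e. a 30-day median as reported for NAE time
to onset); demographics drawn from published marginal shapes (59% male,
dominant 65–84 age band, physician-dominated reporters); event-specific
death probabilities shaped like published NAE mortality (≈0.30
myasthenia, ≈0.02 CIDP); a 10% duplicate-version rate; optional
concomitant role-C rows, same-group second PTs (to exercise the
count-once rule), and brand-name injection (to exercise normalization).
Earlier duplicate versions are written with degraded content (unknown
sex, no outcomes) so a wrong version choice is detectable field-by-field.

Everything is deterministic given the config seed, down to byte-identical
output files. The FAERS dialect has no per-reaction onset column, so the
generator draws one onset per case and all reactions inherit it; dialect
round-trips are therefore exact. What the generator does **not** emulate:
pharmacological correlation between events, reporting-rate secular
trends, free-text narratives, or the true marginal distributions of any
real database — so passing pipeline tests demonstrates correctness of the
machinery, not real-world operating characteristics.

A note on planted-signal recovery: a planted relative risk RR on a drug
with popularity share w realizes an observed-to-expected ratio of about
RR/(wRR + 1 − w), because the drug's own excess inflates the event
margin. Parameter-recovery tests therefore plant signals on
low-popularity drugs, where the attenuation is small.

## Problem sizes

The operating-characteristic suite runs the full file → parse → dedup →
annotate → signal pipeline on 20 databases of 20,000 cases each (planted
RR = 10 at background probability 0.01 and drug weight 0.1), which keeps
the whole run near a minute on one CPU while giving the planted pair an
expected count well above the E ≥ 5 regime. Prior fits in tests use
5,000-cell grids; Monte-Carlo quantile checks use 10⁶ draws.

## Known limitations

- Version selection beyond the identifier rule (probabilistic duplicate
  detection) is out of scope.
- The drug dictionary is minimal; real FAERS verbatim names need a much
  larger synonym table, supplied by the user.
- Stratified or adjusted disproportionality (age/sex-stratified expected
  counts) is not implemented.
- Published signal tables computed on multi-million-report extracts are
  not reproducible from printed totals alone; the package verifies their
  internal arithmetic (IC vs EBGM, mortality ratios, trend correlation)
  rather than their absolute denominators, which printed information
  cannot reconstruct.
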
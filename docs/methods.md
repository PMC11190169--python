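# Methods

## Problem setting

Spontaneous-report databases record drug–event co-occurrences without an
exposure denominator, so absolute risks are not estimable. Disproportionality
analysis instead asks whether a pair is reported more often than expected if
drug and event were independent across the database. The unit of analysis is
the deduplicated case report; the comparator is every other report in the
study window (full-database background, not an active comparator — matching
how published FAERS analyses define their b+d margin).

## Report model and ingestion

A case (`caseid`) may be submitted repeatedly; each submission carries a new
`primaryid` and an incremented `caseversion`. Deduplication keeps, per case,
the report maximal in `(receipt_date, case_version, primary_id)`
lexicographic order — the FDA-recommended "latest version wins" rule; the
published description of duplicate removal ("ISR coding") is under-specified,
so this concrete rule is adopted and stated here. The operation is idempotent
and never invents or renames cases, and the store records both the pre- and
post-deduplication counts because published denominators do not always state
which convention they use.

Drug-name normalization lowercases, strips punctuation and applies a
user-editable synonym TSV (brand → ingredient). This plays the functional
role of an RxNorm concept mapping without the external service; unknown
names pass through normalized. Country → continent uses a small static
ISO-3166 lookup; unknown countries and all missing demographics are explicit
`UNK`/missing categories, never imputed. Quarters are `YYYYQn` with
`n = ceil(month/3)`; dates are ISO-8601.

The dollar-delimited parser is a plain line-splitter rather than a CSV
reader: the dialect has no quoting or escaping, and malformed (ragged) lines
must be reported by line number. MedDRA itself is licensed, so PT → SOC
mapping is a user-supplied TSV validated to give each PT exactly one primary
SOC; the bundled fixture map covers the terms used in the examples and the
simulator (its PT codes are synthetic placeholders). Unknown PTs aggregate
to an `UNMAPPED` pseudo-SOC rather than erroring.

## Contingency tables

Exposure is ingredient + role filter; the default role filter is primary
suspect only (`{PS}`), the convention under which the bundled published
count tables are internally consistent (every row shares the same a+b
margin), and it is configurable. Event occurrence is report-level presence:
if an exposed report lists the event, it counts in `a` even when another
drug on the report is co-suspect, and only reaction PTs are counted
(indication PTs never enter the event margin). At SOC level a report counts
once per SOC with at least one mapped PT. Every table satisfies
`a+b+c+d = N` with `N` the store size. The conventional minimum-case filter
`a >= n_min` (default 3, inclusive) is applied before screening.

## Estimators

Point estimates and intervals are the classical closed forms (see README
table). Numerical choices:

- **χ²** is the uncorrected Pearson statistic
  `(ad−bc)²N / [(a+b)(a+c)(b+d)(c+d)]`; the p-value is the upper tail at one
  degree of freedom. Yates' correction is deliberately omitted — the
  published values this package reproduces use the uncorrected form.
  p-values below 1e-300 are displayed as `0.00E+00`.
- **IC025**: the published form of the interval is `E(IC) ± 2√V(IC)` without
  a variance formula. We use the closed-form posterior moments of Bate et
  al. (1998) with the customary priors (γ₁₁ = α₁ = β₁ = 1, α = β = 2). The
  IC *point* estimate is the maximum-likelihood `log₂[aN/((a+b)(a+c))]`, so
  the identity `IC = log₂ EBGM` holds exactly; the credibility bound is
  validated against an independently coded evaluation of the same moments.
  Published IC025 values for the bundled tables are not exactly reproducible
  under any standard variance we evaluated (the source's variance is
  unrecoverable); IC025 therefore drives screening but is oracle-validated,
  not compared to printed values.
- **EBGM** here is the closed-form relative reporting ratio, not the full
  DuMouchel gamma-Poisson shrinkage; its lower bound uses the same log-scale
  standard error as the ROR. This matches the published tables exactly.
- **Zero cells**: the Haldane–Anscombe +0.5 correction is applied to all
  four cells only when some cell is zero, and the result is flagged
  `corrected`. The Bayesian IC moments use the raw counts (the priors
  regularize them); `a = 0` is an error — no statistic is defined for a pair
  never reported together.
- **Criteria** are applied exactly as stated, with strict/inclusive
  boundaries as printed: ROR lower bound strictly > 1; PRR ≥ 2 and χ² ≥ 4
  inclusive; p strictly < 0.05; IC025 strictly > 0; EBGM05 strictly > 2; the
  minimum case count a ≥ 3 is inclusive. Ranking is by EBGM05 descending,
  ties by `a` descending then event name, so output order is deterministic.
- No multiple-comparison adjustment is applied (none is conventional in this
  screening setting).

### Known inconsistency in the bundled published tables

The bundled PT-level table prints, for 41 of 46 rows, a PRR (and PRR CI)
irreconcilable with the PRR formula applied to the row's own a/b/c/d cells
(e.g. the reflux row prints PRR 2.97 where the formula gives ≈ 39.9), while
ROR, IC, EBGM and EBGM05 are consistent for every row and all SOC-level rows
are fully consistent. The implementation follows the formulas; tests compare
printed PRR values only on the five consistent PT rows and all SOC rows, and
one PT row's printed χ² (off by ~0.9, a rounding slip) is likewise excluded.

## Synthetic data generator

The generator emulates the *structure* of a FAERS extract: multi-drug
reports (1–4 background drugs from a Zipf-weighted vocabulary via Gumbel
top-k sampling, exactly one primary-suspect role per report, others SS/C/I),
independent per-PT event sampling, study-drug exposure with configurable
probability, duplicate case versions (identical content, incremented
version), demographic missingness (defaults: 15% sex, 64% age), a
US-dominated country mix, serious-outcome codes at low marginal rates, and
uniform quarterly batching over 2022Q2–2023Q3. Planted signals multiply an
event's baseline per-report probability by a rate ratio λ among reports
exposed to the planted drug; λ is, up to the exposed reports' contribution
to the event margin (≈ 9% dilution at 1% exposure and λ = 10), exactly what
EBGM estimates. One `numpy` generator keyed by the config seed drives the
whole run, so output is byte-identical across repeats.

What the generator does **not** emulate: within-report event correlation
(events are independent given exposure), temporal reporting trends,
real-world marginal frequencies of drugs or PTs, per-drug indication links
(indications are report-level, which is also why the profile module counts
report-level indications), and content-conflicting duplicate versions.
Passing recovery tests therefore demonstrate estimator and plumbing
correctness under a clean reporting model, not robustness to the biases of
real spontaneous data.

## Problem sizes and tolerances

Recovery uses 200,000 reports with λ = 10 at baseline event probability
0.005 and exposure 0.01 (expected co-occurrence count ≈ 100), asserting the
EBGM within 25% of λ — the binomial sampling error at that count plus the
margin dilution. The null check uses 20 replicates of 20,000 reports with
all pairs at λ = 1 and asserts that at most 1% of pairs with a ≥ 3 pass the
all-four rule; the joint criteria are stringent enough that the observed
rate is typically zero. Round-trip checks (simulate → write quarters →
ingest → deduplicate) assert exact equality of reports and of every
contingency table at 3,000 reports. Closed-form identities (IC = log₂ EBGM,
χ² against the Σ(O−E)²/E formulation) are checked to 1e-9 on 1,000 random
tables.

## Limitations

- The EBGM is the unshrunk relative reporting ratio; for very small counts
  it overstates the signal relative to MGPS shrinkage (the IC025 criterion
  compensates in the joint rule).
- No stratified (age/sex/quarter) tables; the comparator is always the full
  window.
- The profile module replicates the convention of using the exposed-report
  count as denominator even for multi-valued blocks (outcomes, indications),
  so those blocks need not sum to 100%.
- Real FAERS ingestion at full scale (tens of millions of rows) would want a
  columnar fast path; the current assembly is row-wise Python, adequate for
  the hundreds of thousands of reports used here.
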
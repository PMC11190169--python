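# faerspv

Disproportionality signal detection for spontaneous adverse-event reports.

Post-marketing safety surveillance databases such as the FDA Adverse Event
Reporting System (FAERS) collect voluntarily submitted case reports — a
patient, the drugs they took, the adverse events observed — with no
denominator of exposed patients. Pharmacovigilance screens such data by
*disproportionality*: for a drug–event pair, compare how often the pair is
reported against its expectation under independence across the whole
database. `faerspv` implements that pipeline for FAERS-style quarterly
extracts, and ships a synthetic report generator with planted associations
so the whole pipeline is testable without downloading anything.

## The statistics

For a drug–event 2×2 table with `a` = reports with drug and event, `b` =
drug without event, `c` = event without drug, `d` = neither, and
`N = a+b+c+d`:

| Statistic | Point estimate | Interval | Positive-signal criterion |
|---|---|---|---|
| ROR | `ad/(bc)` | `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` | lower bound > 1 and a ≥ 3 |
| PRR | `[a/(a+b)] / [c/(c+d)]` | Pearson χ² (df=1, no Yates correction) | PRR ≥ 2, χ² ≥ 4, a ≥ 3, p < 0.05 |
| BCPNN IC | `log₂[aN/((a+b)(a+c))]` | IC025 = E(IC) − 2·√V(IC), Bate (1998) posterior moments | IC025 > 0 |
| EBGM | `aN/((a+b)(a+c))` | EBGM05 = `exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d))` | EBGM05 > 2 |

IC and EBGM share one point-estimate formula on two scales
(`IC = log₂ EBGM`). Requiring all four criteria simultaneously
(`rule="all_four"`) is a deliberately stringent screen; ranking is by
EBGM05 descending. Tables with a zero cell get the Haldane–Anscombe +0.5
correction and are flagged.

## Worked example

The desk calculator takes a bare 2×2 table. For the most-reported
tirzepatide adverse event in the bundled published counts ("Incorrect dose
administered", a=5,752 co-occurrence reports out of N=1,904,481):

```
$ faerspv stats 5752 14291 18587 1865851
a=5752 b=14291 c=18587 d=1865851 N=1904481
ROR  40.40 (95% CI 39.06–41.79)
PRR  29.10  chi2 120715.28  p 0.00E+00
IC   4.49 (IC025 4.44)
EBGM 22.46 (EBGM05 21.71)
positive: ROR=True PRR=True BCPNN=True EBGM=True all_four=True
```

The pair is reported 22.5× more often than expected under independence
(EBGM), with the lower bounds of all four statistics clearing their
thresholds — a strong signal by every criterion. A rare-event table with a
zero cell shows the continuity correction and the stringency of the joint
rule:

```
$ faerspv stats 3 0 5 992
a=3 b=0 c=5 d=992 N=1000 (0.5 correction)
ROR  1263.18 (95% CI 58.09–27470.29)
PRR  158.77  chi2 338.37  p 1.44E-75
IC   6.61 (IC025 -0.30)
EBGM 97.42 (EBGM05 4.48)
positive: ROR=True PRR=True BCPNN=False EBGM=True all_four=False
```

The Bayesian IC shrinks the tiny count toward independence and withholds
the signal even though the frequentist estimators fire.

Full-pipeline usage on synthetic data:

```sh
faerspv simulate --seed 3 --n-reports 20000 --out quarters/
faerspv ingest --quarters-dir quarters/ --out store/ --start 2022Q2 --end 2023Q3
faerspv signals --store store/ --drug tirzepatide --roles PS,SS,C,I \
    --level PT --rule all_four --out signals.tsv
faerspv profile --store store/ --drug tirzepatide --roles PS,SS,C,I --out profile
```

`signals --counts table.tsv` is a counts mode that scores a TSV of
`event,a,b,c,d` rows directly, so published contingency tables can be
re-analysed without the underlying reports.

## Layout

- `faerspv.io` — dollar-delimited FAERS-dialect parsing, report assembly,
  case-version deduplication, quarter windowing, TSV store persistence
- `faerspv.meddra` — PT → primary SOC mapping (user-supplied TSV; small
  bundled fixture map)
- `faerspv.contingency` — 2×2 table construction at PT or SOC level
- `faerspv.stats` — the four estimators, intervals, criteria, ranking
- `faerspv.profiles` — clinical-characteristics summaries (sex, age bins,
  geography, indications, serious outcomes, quarters)
- `faerspv.synth` — synthetic report generator with planted signals and
  exact ground truth
- `faerspv.cli` — `ingest`, `signals`, `profile`, `simulate`, `stats`

See `docs/methods.md` for the modelling assumptions and design choices.
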
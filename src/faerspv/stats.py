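"""Disproportionality statistics and positive-signal criteria.

Four estimators of reporting disproportionality for a 2x2 table
(a, b, c, d) with N = a+b+c+d:

* **ROR** (reporting odds ratio) ``ad/(bc)`` with the log-normal 95% CI
  ``exp(ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``.
* **PRR** (proportional reporting ratio) ``[a/(a+b)] / [c/(c+d)]`` screened
  with the Pearson chi-square of independence (no Yates correction) and its
  upper-tail p-value at one degree of freedom.
* **BCPNN information component** ``IC = log2[a N / ((a+b)(a+c))]`` with the
  lower credibility bound IC025 = E(IC) - 2*sqrt(V(IC)) from the closed-form
  Bayesian approximation of Bate et al. (1998) with the customary priors
  (gamma11 = alpha1 = beta1 = 1, alpha = beta = 2).
* **EBGM**, here the closed-form relative reporting ratio
  ``a N / ((a+b)(a+c))`` (not the full MGPS shrinkage), with EBGM05 the
  log-normal lower 95% bound using the same standard error as the ROR.

The IC and EBGM point estimates share one formula on two scales, so
``ic == log2(ebgm)`` identically.

Joint screening applies the four customary thresholds: ROR lower bound > 1
with a >= 3; PRR >= 2 with chi2 >= 4, a >= 3 and p < 0.05; IC025 > 0;
EBGM05 > 2.  Requiring all four is a deliberately stringent rule.

Tables with a zero cell get the Haldane-Anscombe +0.5 correction (flagged);
tables with a = 0 have no defined statistics and raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats as sps

from .contingency import ContingencyTable

Z95 = 1.96

# Bate et al. (1998) prior hyperparameters
_ALPHA1 = _BETA1 = _GAMMA11 = 1.0
_ALPHA = _BETA = 2.0


class UndefinedStatisticError(ValueError):
    """The table has a zero cell and continuity correction is disabled."""


@dataclass(frozen=True)
class SignalStats:
    """All four estimators, intervals and the chi-square test for one table."""

    table: ContingencyTable
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    p_value: float
    ic: float
    ic_low: float
    ebgm: float
    ebgm_low: float
    corrected: bool


@dataclass(frozen=True)
class SignalCriteria:
    ror_positive: bool
    prr_positive: bool
    bcpnn_positive: bool
    ebgm_positive: bool

    @property
    def all_four(self) -> bool:
        return (self.ror_positive and self.prr_positive
                and self.bcpnn_positive and self.ebgm_positive)

    @property
    def any(self) -> bool:
        return (self.ror_positive or self.prr_positive
                or self.bcpnn_positive or self.ebgm_positive)


def _cells(t: ContingencyTable, zero_correction: bool
           ) -> tuple[float, float, float, float, bool]:
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        if not zero_correction:
            raise UndefinedStatisticError(
                f"table for {t.event!r} has a zero cell; enable the "
                "Haldane-Anscombe correction or drop the table")
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return float(a), float(b), float(c), float(d), False


def _log_se(a: float, b: float, c: float, d: float) -> float:
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def ror_with_ci(t: ContingencyTable, zero_correction: bool = True
                ) -> tuple[float, float, float]:
    """Reporting odds ratio with its log-normal 95% CI."""
    a, b, c, d, _ = _cells(t, zero_correction)
    ror = (a * d) / (b * c)
    half = Z95 * _log_se(a, b, c, d)
    return ror, ror * math.exp(-half), ror * math.exp(half)


def prr_with_chi2(t: ContingencyTable, zero_correction: bool = True
                  ) -> tuple[float, float, float]:
    """PRR plus the uncorrected Pearson chi-square and its df=1 p-value."""
    a, b, c, d, _ = _cells(t, zero_correction)
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    chi2 = (a * d - b * c) ** 2 * n / ((a + b) * (a + c) * (b + d) * (c + d))
    p = float(sps.chi2.sf(chi2, df=1))
    return prr, chi2, p


def bcpnn_ic(t: ContingencyTable, zero_correction: bool = True
             ) -> tuple[float, float]:
    """Information component and its lower 95% credibility bound (IC025).

    The point estimate is the maximum-likelihood IC.  The bound uses the
    Bate (1998) closed-form posterior moments, which are defined for any
    table with a > 0 (the priors regularize the margins, so the raw counts
    are used even when the other cells are zero).
    """
    if t.a == 0:
        raise UndefinedStatisticError(
            f"IC undefined for {t.event!r}: no co-occurrence reports (a=0)")
    a, b, c, d, _ = _cells(t, zero_correction)
    n = a + b + c + d
    ic = math.log2(a * n / ((a + b) * (a + c)))

    # posterior moments on the raw counts
    a0, ab, ac = float(t.a), float(t.a + t.b), float(t.a + t.c)
    n0 = float(t.a + t.b + t.c + t.d)
    gamma = _GAMMA11 * (n0 + _ALPHA) * (n0 + _BETA) / ((ab + _ALPHA1) * (ac + _BETA1))
    e_ic = math.log2((a0 + _GAMMA11) * (n0 + _ALPHA) * (n0 + _BETA)
                     / ((n0 + gamma) * (ab + _ALPHA1) * (ac + _BETA1)))
    v_ic = ((n0 - a0 + gamma - _GAMMA11) / ((a0 + _GAMMA11) * (1 + n0 + gamma))
            + (n0 - ab + _ALPHA - _ALPHA1) / ((ab + _ALPHA1) * (1 + n0 + _ALPHA))
            + (n0 - ac + _BETA - _BETA1) / ((ac + _BETA1) * (1 + n0 + _BETA))
            ) / math.log(2) ** 2
    return ic, e_ic - 2 * math.sqrt(v_ic)


def ebgm_with_ci(t: ContingencyTable, zero_correction: bool = True
                 ) -> tuple[float, float]:
    """Relative reporting ratio aN/((a+b)(a+c)) with its lower 95% bound."""
    a, b, c, d, _ = _cells(t, zero_correction)
    n = a + b + c + d
    ebgm = a * n / ((a + b) * (a + c))
    return ebgm, ebgm * math.exp(-Z95 * _log_se(a, b, c, d))


def compute_stats(t: ContingencyTable, zero_correction: bool = True) -> SignalStats:
    """All four estimators for one table."""
    _, _, _, _, corrected = _cells(t, zero_correction)
    ror, ror_low, ror_high = ror_with_ci(t, zero_correction)
    prr, chi2, p = prr_with_chi2(t, zero_correction)
    ic, ic_low = bcpnn_ic(t, zero_correction)
    ebgm, ebgm_low = ebgm_with_ci(t, zero_correction)
    return SignalStats(table=t, ror=ror, ror_low=ror_low, ror_high=ror_high,
                       prr=prr, chi2=chi2, p_value=p, ic=ic, ic_low=ic_low,
                       ebgm=ebgm, ebgm_low=ebgm_low, corrected=corrected)


def evaluate_criteria(s: SignalStats) -> SignalCriteria:
    """Apply the four positive-signal thresholds (strict as stated)."""
    a = s.table.a
    return SignalCriteria(
        ror_positive=s.ror_low > 1 and a >= 3,
        prr_positive=s.prr >= 2 and s.chi2 >= 4 and a >= 3 and s.p_value < 0.05,
        bcpnn_positive=s.ic_low > 0,
        ebgm_positive=s.ebgm_low > 2,
    )


_RULE_FIELDS = {"ror": "ror_positive", "prr": "prr_positive",
                "bcpnn": "bcpnn_positive", "ebgm": "ebgm_positive"}


def _rule_predicate(rule: str | Iterable[str]):
    if rule == "all_four":
        return lambda c: c.all_four
    if rule == "any":
        return lambda c: c.any
    if rule == "none":
        return lambda c: True
    names = [rule] if isinstance(rule, str) else list(rule)
    fields = []
    for name in names:
        if name not in _RULE_FIELDS:
            raise ValueError(f"unknown criteria rule {name!r}")
        fields.append(_RULE_FIELDS[name])
    return lambda c: all(getattr(c, f) for f in fields)


def detect_signals(tables: list[ContingencyTable],
                   rule: str | Iterable[str] = "all_four",
                   zero_correction: bool = True,
                   ) -> list[tuple[SignalStats, SignalCriteria]]:
    """Score every table, keep those passing ``rule``, rank by EBGM05.

    Ties broken by a (descending) then event name, so the ranking is
    deterministic.  ``rule`` is ``"all_four"``, ``"any"``, ``"none"`` (keep
    everything), or a subset of {"ror", "prr", "bcpnn", "ebgm"}.
    """
    keep = _rule_predicate(rule)
    scored = []
    for t in tables:
        s = compute_stats(t, zero_correction)
        c = evaluate_criteria(s)
        if keep(c):
            scored.append((s, c))
    scored.sort(key=lambda sc: (-sc[0].ebgm_low, -sc[0].table.a, sc[0].table.event))
    return scored


def signals_to_frame(results: list[tuple[SignalStats, SignalCriteria]]
                     ) -> pd.DataFrame:
    """Flatten ranked signals into the export table."""
    rows = []
    for s, c in results:
        t = s.table
        rows.append({
            "level": t.level, "event": t.event,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": s.ror, "ror_low": s.ror_low, "ror_high": s.ror_high,
            "prr": s.prr, "chi2": s.chi2, "p_value": s.p_value,
            "ic": s.ic, "ic_low": s.ic_low,
            "ebgm": s.ebgm, "ebgm_low": s.ebgm_low,
            "ror_positive": c.ror_positive, "prr_positive": c.prr_positive,
            "bcpnn_positive": c.bcpnn_positive, "ebgm_positive": c.ebgm_positive,
            "all_four": c.all_four,
        })
    cols = ["level", "event", "a", "b", "c", "d", "ror", "ror_low", "ror_high",
            "prr", "chi2", "p_value", "ic", "ic_low", "ebgm", "ebgm_low",
            "ror_positive", "prr_positive", "bcpnn_positive", "ebgm_positive",
            "all_four"]
    return pd.DataFrame(rows, columns=cols)


def format_signal_frame(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Round the ratio/statistic columns for display (p-value kept as is,
    printed in scientific notation; values below 1e-300 display as 0)."""
    out = df.copy()
    num = ["ror", "ror_low", "ror_high", "prr", "chi2", "ic", "ic_low",
           "ebgm", "ebgm_low"]
    out[num] = out[num].astype(float).round(decimals)
    out["p_value"] = [
        "0.00E+00" if p < 1e-300 else f"{p:.2E}" for p in out["p_value"]]
    return out


__all__ = ["SignalStats", "SignalCriteria", "UndefinedStatisticError",
           "ror_with_ci", "prr_with_chi2", "bcpnn_ic", "ebgm_with_ci",
           "compute_stats", "evaluate_criteria", "detect_signals",
           "signals_to_frame", "format_signal_frame", "Z95"]
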
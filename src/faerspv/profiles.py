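"""Clinical-characteristics profiling of a drug's report set.

Summarises the reports exposed to a target drug (under a role filter) as
count/percentage blocks: sex, age bins, continents, top-k countries, top-k
indications, serious-outcome codes, and reporting quarters.  Percentages in
every block use the number of exposed reports as denominator, so
multi-valued blocks (outcomes, indications) need not sum to 100%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .io import ReportStore, OUTCOME_CODES

logger = logging.getLogger(__name__)

AGE_BIN_LABELS = ["<18", "18–29", "30–39", "40–49", "50–59",
                  "60–69", "70–79", "80–89", "≥90", "Unknown"]

OUTCOME_LABELS = {
    "DE": "Death", "LT": "Life-threatening", "DS": "Disability",
    "HO": "Hospitalization", "CA": "Congenital anomaly",
    "RI": "Required intervention", "OT": "Other serious"}


def age_bin(age_years: float | None) -> str:
    """Decade bin of an age in years; missing -> 'Unknown'."""
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return "Unknown"
    if age_years < 0:
        raise ValueError("age must be nonnegative")
    if age_years < 18:
        return "<18"
    if age_years < 30:
        return "18–29"
    if age_years >= 90:
        return "≥90"
    lo = int(age_years // 10) * 10
    return f"{lo}–{lo + 9}"


@dataclass
class ProfileReport:
    """Count/percentage blocks for one drug's exposed reports."""

    drug: str
    n_reports: int
    blocks: dict[str, pd.Series] = field(default_factory=dict)

    def percentages(self, block: str) -> pd.Series:
        if self.n_reports == 0:
            return self.blocks[block] * 0.0
        return 100.0 * self.blocks[block] / self.n_reports

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, counts in self.blocks.items():
            pct = self.percentages(name)
            rows += [{"block": name, "label": lbl, "count": int(n),
                      "percent": round(float(p), 2)}
                     for lbl, n, p in zip(counts.index, counts, pct)]
        return pd.DataFrame(rows, columns=["block", "label", "count", "percent"])

    def to_text(self) -> str:
        lines = [f"Characteristics of reports associated with {self.drug}",
                 f"Number of reports\t{self.n_reports}"]
        for name, counts in self.blocks.items():
            lines.append(name)
            pct = self.percentages(name)
            for lbl in counts.index:
                lines.append(f"  {lbl}\t{int(counts[lbl])}\t{pct[lbl]:.2f}")
        return "\n".join(lines)


def profile(store: ReportStore, drug: str,
            roles: tuple[str, ...] = ("PS",), k: int = 10) -> ProfileReport:
    """Tabulate the characteristic blocks for reports exposed to ``drug``."""
    role_set = set(roles)
    exposed = [r for r in store.reports
               if any(e.ingredient == drug and e.role in role_set
                      for e in r.drugs)]
    if not exposed:
        logger.warning("drug %r absent from store under roles %s", drug, roles)

    def count(values, order=None, top=None) -> pd.Series:
        s = pd.Series(values, dtype=object).value_counts()
        if order is not None:
            s = s.reindex(order, fill_value=0)
        if top is not None:
            s = s.sort_values(ascending=False, kind="stable")
            # deterministic tie-break: count desc, then name
            s = s.iloc[sorted(range(len(s)),
                              key=lambda i: (-s.iloc[i], str(s.index[i])))][:top]
        return s.astype(int)

    outcome_counts = count([oc for r in exposed for oc in r.outcomes],
                           order=list(OUTCOME_CODES))
    outcome_counts.index = [OUTCOME_LABELS[c] for c in outcome_counts.index]

    blocks = {
        "Sex": count([r.sex for r in exposed], order=["M", "F", "UNK"]),
        "Age": count([age_bin(r.age_years) for r in exposed],
                     order=AGE_BIN_LABELS),
        "Continent": count([r.continent for r in exposed], top=7),
        "Country": count([r.country for r in exposed], top=k),
        "Indications": count([pt for r in exposed for pt in r.indications],
                             top=k),
        "Serious outcomes": outcome_counts,
        "Quarter": count([r.quarter for r in exposed],
                         order=sorted({r.quarter for r in exposed})),
    }
    return ProfileReport(drug=drug, n_reports=len(exposed), blocks=blocks)


__all__ = ["age_bin", "profile", "ProfileReport", "AGE_BIN_LABELS",
           "OUTCOME_LABELS"]
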
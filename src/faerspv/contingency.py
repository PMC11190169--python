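"""Drug-event 2x2 contingency tables over a deduplicated report store.

For a target drug and every event term occurring in at least one exposed
report, the classic pharmacovigilance table is::

                event   no event
    drug          a        b
    no drug       c        d

with N = a+b+c+d the total number of reports in the store (the comparator is
the whole database window, not an active comparator).  Exposure is defined
by the drug's ingredient name and a role filter (default: primary suspect
only).  Event occurrence is report-level presence of the PT — or, at SOC
level, of at least one PT whose primary SOC is the event — regardless of
which drug on the report the reporter blamed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import ReportStore, ROLE_CODES
from .meddra import MedDRAMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """The (a, b, c, d) counts for one drug-event pair."""

    drug: str
    event: str
    level: str  # "PT" | "SOC"
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if self.level not in ("PT", "SOC"):
            raise ValueError(f"invalid level {self.level!r}")
        for cell in (self.a, self.b, self.c, self.d):
            if not isinstance(cell, int) or cell < 0:
                raise ValueError("cells must be nonnegative integers")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


def build_tables(store: ReportStore,
                 drug: str,
                 roles: tuple[str, ...] = ("PS",),
                 level: str = "PT",
                 meddra: MedDRAMap | None = None) -> list[ContingencyTable]:
    """One table per event term observed in >=1 exposed report.

    A report contributes once per distinct event term however many times the
    term repeats; at SOC level it contributes once per SOC with >=1 mapped
    PT.  Every table satisfies a+b+c+d == store.n_total.
    """
    for r in roles:
        if r not in ROLE_CODES:
            raise ValueError(f"invalid role {r!r}")
    if level == "SOC" and meddra is None:
        raise ValueError("SOC-level tables require a MedDRA map")

    role_set = set(roles)
    n_total = store.n_total
    event_totals: dict[str, int] = {}
    exposed_counts: dict[str, int] = {}
    n_exposed = 0
    for report in store.reports:
        if level == "PT":
            events = set(report.reactions)
        else:
            events = {meddra.pt_to_soc(pt)[1] for pt in report.reactions}
        exposed = any(e.ingredient == drug and e.role in role_set
                      for e in report.drugs)
        if exposed:
            n_exposed += 1
        for ev in events:
            event_totals[ev] = event_totals.get(ev, 0) + 1
            if exposed:
                exposed_counts[ev] = exposed_counts.get(ev, 0) + 1

    if n_exposed == 0:
        logger.warning("drug %r absent from store under roles %s", drug, roles)
        return []

    tables = []
    for ev in sorted(exposed_counts):
        a = exposed_counts[ev]
        b = n_exposed - a
        c = event_totals[ev] - a
        d = n_total - a - b - c
        tables.append(ContingencyTable(drug=drug, event=ev, level=level,
                                       a=a, b=b, c=c, d=d))
    return tables


def min_case_filter(tables: list[ContingencyTable],
                    n_min: int) -> list[ContingencyTable]:
    """Keep tables with at least ``n_min`` co-occurrence reports (a >= n_min)."""
    if n_min < 0:
        raise ValueError("n_min must be >= 0")
    return [t for t in tables if t.a >= n_min]


def tables_to_frame(tables: list[ContingencyTable]) -> pd.DataFrame:
    """Export tables as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [{"level": t.level, "event": t.event, "a": t.a, "b": t.b,
          "c": t.c, "d": t.d, "n_total": t.n_total} for t in tables],
        columns=["level", "event", "a", "b", "c", "d", "n_total"])


def tables_from_counts(df: pd.DataFrame, drug: str = "drug",
                       level: str = "PT") -> list[ContingencyTable]:
    """Build tables directly from a counts frame with event,a,b,c,d columns.

    This "counts mode" lets published 2x2 tables be analysed without the
    underlying report store.
    """
    needed = {"event", "a", "b", "c", "d"}
    if not needed <= set(df.columns):
        raise ValueError(f"counts frame needs columns {sorted(needed)}")
    return [ContingencyTable(drug=drug, event=str(r.event),
                             level=str(getattr(r, "level", level)),
                             a=int(r.a), b=int(r.b), c=int(r.c), d=int(r.d))
            for r in df.itertuples(index=False)]


__all__ = ["ContingencyTable", "build_tables", "min_case_filter",
           "tables_to_frame", "tables_from_counts"]
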
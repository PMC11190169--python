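"""Ingestion of FAERS-dialect quarterly report tables.

FAERS quarterly extracts are dollar-sign-delimited ASCII tables: one header
line naming the columns, one record per line, no quoting.  Five child tables
(DEMO, DRUG, REAC, OUTC, INDI) share a ``primaryid`` key.  This module parses
that dialect, joins the child tables into :class:`SafetyReport` objects,
normalizes drug names through a synonym dictionary (a stand-in for a full
RxNorm concept mapping), removes duplicate case versions, and restricts a
store to a reporting window of calendar quarters.

The case/version model mirrors FAERS: a *case* (``caseid``) is one patient
event which may be reported several times; each submission gets a fresh
``primaryid`` and an incremented ``caseversion``.  Deduplication keeps, per
case, the report with the greatest ``(receipt_date, case_version,
primary_id)`` in lexicographic order — the FDA-recommended "latest version
wins" rule.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "DS", "HO", "CA", "RI", "OT")
SEX_CODES = ("M", "F", "UNK")

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")

# Minimal ISO-3166 alpha-2 -> continent lookup; anything absent maps to UNK.
COUNTRY_TO_CONTINENT: dict[str, str] = {
    **dict.fromkeys(
        ["US", "CA", "MX", "PR", "GT", "CU", "DO", "HN", "PA", "CR", "JM"],
        "North America"),
    **dict.fromkeys(
        ["BR", "AR", "CL", "CO", "PE", "VE", "EC", "UY", "BO", "PY"],
        "South America"),
    **dict.fromkeys(
        ["GB", "DE", "FR", "IT", "ES", "NL", "SE", "DK", "NO", "FI", "PL",
         "CH", "AT", "BE", "IE", "PT", "GR", "CZ", "HU", "RO", "UA", "RU"],
        "Europe"),
    **dict.fromkeys(
        ["JP", "CN", "IN", "KR", "TH", "IL", "TR", "AE", "SA", "SG", "MY",
         "PH", "VN", "ID", "PK", "TW", "HK", "KW", "QA", "JO", "LB"],
        "Asia"),
    **dict.fromkeys(
        ["ZA", "EG", "NG", "KE", "MA", "TN", "DZ", "GH", "ET"], "Africa"),
    **dict.fromkeys(["AU", "NZ"], "Oceania"),
}


class FormatError(ValueError):
    """A FAERS-dialect file violates the expected layout."""


def quarter_of(date: dt.date) -> str:
    """Quarter label ``YYYYQn`` of a calendar date (n = ceil(month/3))."""
    return f"{date.year}Q{(date.month + 2) // 3}"


def validate_quarter(label: str) -> str:
    if not _QUARTER_RE.match(label):
        raise ValueError(f"invalid quarter label: {label!r} (expected YYYYQn)")
    return label


@dataclass(frozen=True)
class DrugEntry:
    """One drug row of a report: verbatim name, normalized ingredient, role."""

    verbatim_name: str
    ingredient: str
    role: str  # PS | SS | C | I

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"invalid drug role {self.role!r}")
        if not self.ingredient or self.ingredient != self.ingredient.lower():
            raise ValueError("ingredient must be non-empty and lowercase")


@dataclass
class SafetyReport:
    """One (possibly not yet deduplicated) spontaneous safety report."""

    primary_id: str
    case_id: str
    case_version: int
    receipt_date: dt.date
    sex: str = "UNK"
    age_years: float | None = None
    country: str = "UNK"
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.case_version < 0:
            raise ValueError("case_version must be >= 0")
        if self.sex not in SEX_CODES:
            raise ValueError(f"invalid sex code {self.sex!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be nonnegative")
        # a PT may be reported on several lines of one case; keep one
        self.reactions = list(dict.fromkeys(self.reactions))
        self.outcomes = list(dict.fromkeys(self.outcomes))
        for oc in self.outcomes:
            if oc not in OUTCOME_CODES:
                raise ValueError(f"invalid outcome code {oc!r}")

    @property
    def quarter(self) -> str:
        return quarter_of(self.receipt_date)

    @property
    def continent(self) -> str:
        return COUNTRY_TO_CONTINENT.get(self.country, "UNK")


@dataclass
class ReportStore:
    """A deduplicated collection of reports restricted to a quarter window.

    ``n_total`` (the number of retained reports) is the database denominator
    N of all disproportionality statistics.  ``n_raw`` additionally records
    how many report versions were seen before deduplication, since published
    analyses do not always state which convention their denominator uses.
    """

    reports: list[SafetyReport] = field(default_factory=list)
    window: tuple[str, str] | None = None
    n_raw: int | None = None

    @property
    def n_total(self) -> int:
        return len(self.reports)

    def __post_init__(self) -> None:
        case_ids = [r.case_id for r in self.reports]
        if len(set(case_ids)) != len(case_ids):
            raise ValueError("ReportStore requires unique case_ids; deduplicate first")
        if self.window is not None:
            lo, hi = map(validate_quarter, self.window)
            for r in self.reports:
                if not lo <= r.quarter <= hi:
                    raise ValueError(
                        f"report {r.primary_id} quarter {r.quarter} outside window")


# ---------------------------------------------------------------------------
# parsing

def parse_dollar_table(path: str | Path,
                       expected_columns: list[str] | None = None) -> pd.DataFrame:
    """Parse one dollar-delimited FAERS-dialect table into a string DataFrame.

    The dialect has no quoting or escaping, so the reader is a plain
    line-splitter; this also lets ragged lines be reported by line number.
    Empty fields become ``pd.NA``.  Column order follows the file header.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
        if not header:
            raise FormatError(f"{path}: empty file, expected a header line")
        columns = header.split("$")
        if expected_columns:
            missing = [c for c in expected_columns if c not in columns]
            if missing:
                raise FormatError(
                    f"{path}: missing mandatory column(s): {', '.join(missing)}")
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) != len(columns):
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {len(columns)}")
            rows.append(fields)
    df = pd.DataFrame(rows, columns=columns, dtype="string")
    return df.replace("", pd.NA)


def normalize_drug_name(verbatim: str, synonyms: dict[str, str] | None = None) -> str:
    """Normalize a verbatim drug name to a canonical lowercase ingredient.

    Lowercases, strips punctuation, collapses whitespace, then applies the
    synonym dictionary (brand -> ingredient).  Unknown names pass through in
    normalized form.
    """
    if not verbatim or not verbatim.strip():
        raise ValueError("empty drug name")
    cleaned = verbatim.lower().translate(
        str.maketrans({p: " " for p in string.punctuation}))
    cleaned = " ".join(cleaned.split())
    if synonyms:
        return synonyms.get(cleaned, cleaned)
    return cleaned


def load_synonyms_tsv(path: str | Path) -> dict[str, str]:
    """Load a two-column (variant, ingredient) TSV synonym dictionary."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["variant", "ingredient"]:
        raise FormatError(f"{path}: expected columns 'variant', 'ingredient'")
    return {v.strip().lower(): i.strip().lower()
            for v, i in zip(df["variant"], df["ingredient"])}


def _parse_date(raw: str | None) -> dt.date | None:
    if raw is None or pd.isna(raw):
        return None
    s = str(raw).strip()
    try:
        if "-" in s:
            return dt.date.fromisoformat(s)
        return dt.datetime.strptime(s, "%Y%m%d").date()
    except ValueError:
        return None


def assemble_reports(demo: pd.DataFrame,
                     drug: pd.DataFrame,
                     reac: pd.DataFrame,
                     outc: pd.DataFrame,
                     indi: pd.DataFrame,
                     synonyms: dict[str, str] | None = None,
                     ) -> tuple[list[SafetyReport], dict[str, int]]:
    """Join the five FAERS child tables into reports keyed by ``primaryid``.

    Child rows whose ``primaryid`` is absent from DEMO are orphans: they are
    logged and dropped, and their counts per table are returned alongside
    the reports.  Reports with no reaction rows are retained with an empty
    reactions list.
    """
    known = set(demo["primaryid"].dropna())
    orphans: dict[str, int] = {}

    def grouped(df: pd.DataFrame, name: str) -> dict[str, pd.DataFrame]:
        if df.empty:
            orphans[name] = 0
            return {}
        orphan_mask = ~df["primaryid"].isin(known)
        orphans[name] = int(orphan_mask.sum())
        if orphans[name]:
            logger.warning("%s: dropped %d orphan row(s) with unknown primaryid",
                           name, orphans[name])
        return {pid: g for pid, g in df[~orphan_mask].groupby("primaryid")}

    drug_by, reac_by = grouped(drug, "DRUG"), grouped(reac, "REAC")
    outc_by, indi_by = grouped(outc, "OUTC"), grouped(indi, "INDI")

    reports: list[SafetyReport] = []
    for row in demo.itertuples(index=False):
        pid = row.primaryid
        if pd.isna(pid):
            continue
        date = _parse_date(getattr(row, "fda_dt", None))
        if date is None:
            logger.warning("DEMO %s: missing/invalid date, row skipped", pid)
            continue
        sex = getattr(row, "sex", None)
        sex = sex if (not pd.isna(sex) and sex in ("M", "F")) else "UNK"
        age_raw = getattr(row, "age_yrs", None)
        age = None if pd.isna(age_raw) else float(age_raw)
        country_raw = getattr(row, "occr_country", None)
        country = "UNK" if pd.isna(country_raw) else str(country_raw).upper()

        drugs = []
        for d in drug_by.get(pid, pd.DataFrame()).itertuples(index=False):
            verbatim = d.drugname if not pd.isna(d.drugname) else ""
            if not verbatim.strip():
                continue
            role = d.role_cod if d.role_cod in ROLE_CODES else "C"
            drugs.append(DrugEntry(verbatim_name=verbatim,
                                   ingredient=normalize_drug_name(verbatim, synonyms),
                                   role=role))
        reactions = [str(p) for p in
                     reac_by.get(pid, pd.DataFrame({"pt": []}))
                     .get("pt", pd.Series(dtype="string")).dropna()]
        outcomes = [str(o) for o in
                    outc_by.get(pid, pd.DataFrame({"outc_cod": []}))
                    .get("outc_cod", pd.Series(dtype="string")).dropna()
                    if o in OUTCOME_CODES]
        indications = [str(i) for i in
                       indi_by.get(pid, pd.DataFrame({"indi_pt": []}))
                       .get("indi_pt", pd.Series(dtype="string")).dropna()]

        reports.append(SafetyReport(
            primary_id=str(pid),
            case_id=str(row.caseid),
            case_version=int(row.caseversion),
            receipt_date=date,
            sex=sex,
            age_years=age,
            country=country,
            drugs=drugs,
            reactions=reactions,
            outcomes=outcomes,
            indications=indications,
        ))
    return reports, orphans


def deduplicate(reports: list[SafetyReport]) -> list[SafetyReport]:
    """Keep one report per case: the latest (receipt_date, version, primaryid).

    Output is sorted by case_id, so the result is a pure function of the
    input set.  Idempotent, and never invents or renames cases.
    """
    best: dict[str, SafetyReport] = {}
    for r in reports:
        key = (r.receipt_date, r.case_version, r.primary_id)
        cur = best.get(r.case_id)
        if cur is None or key > (cur.receipt_date, cur.case_version, cur.primary_id):
            best[r.case_id] = r
    return [best[cid] for cid in sorted(best)]


def filter_window(store: ReportStore, start: str, end: str) -> ReportStore:
    """Restrict a store to reports whose quarter lies in [start, end]."""
    lo, hi = validate_quarter(start), validate_quarter(end)
    if lo > hi:
        raise ValueError(f"window start {lo} after end {hi}")
    kept = [r for r in store.reports if lo <= r.quarter <= hi]
    return ReportStore(reports=kept, window=(lo, hi), n_raw=store.n_raw)


# ---------------------------------------------------------------------------
# store persistence: a directory of TSV child tables, lossless round-trip

_MISSING = ""


def save_store(store: ReportStore, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rep_rows, drug_rows, reac_rows, outc_rows, indi_rows = [], [], [], [], []
    for r in store.reports:
        rep_rows.append({
            "primary_id": r.primary_id, "case_id": r.case_id,
            "case_version": r.case_version,
            "receipt_date": r.receipt_date.isoformat(),
            "sex": r.sex,
            "age_years": _MISSING if r.age_years is None else repr(r.age_years),
            "country": r.country,
        })
        for i, d in enumerate(r.drugs):
            drug_rows.append({"primary_id": r.primary_id, "seq": i,
                              "verbatim_name": d.verbatim_name,
                              "ingredient": d.ingredient, "role": d.role})
        reac_rows += [{"primary_id": r.primary_id, "pt": p} for p in r.reactions]
        outc_rows += [{"primary_id": r.primary_id, "outc_cod": o} for o in r.outcomes]
        indi_rows += [{"primary_id": r.primary_id, "indi_pt": p} for p in r.indications]

    meta = {"window_start": store.window[0] if store.window else _MISSING,
            "window_end": store.window[1] if store.window else _MISSING,
            "n_raw": _MISSING if store.n_raw is None else store.n_raw}
    pd.DataFrame([meta]).to_csv(directory / "meta.tsv", sep="\t", index=False)
    for name, rows, cols in [
            ("reports", rep_rows, ["primary_id", "case_id", "case_version",
                                   "receipt_date", "sex", "age_years", "country"]),
            ("drugs", drug_rows, ["primary_id", "seq", "verbatim_name",
                                  "ingredient", "role"]),
            ("reactions", reac_rows, ["primary_id", "pt"]),
            ("outcomes", outc_rows, ["primary_id", "outc_cod"]),
            ("indications", indi_rows, ["primary_id", "indi_pt"])]:
        pd.DataFrame(rows, columns=cols).to_csv(
            directory / f"{name}.tsv", sep="\t", index=False)


def load_store(directory: str | Path) -> ReportStore:
    directory = Path(directory)
    read = lambda n: pd.read_csv(directory / f"{n}.tsv", sep="\t", dtype=str,
                                 keep_default_na=False)
    meta = read("meta").iloc[0]
    reps, drugs, reacs = read("reports"), read("drugs"), read("reactions")
    outcs, indis = read("outcomes"), read("indications")

    def by_pid(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
        return {pid: g for pid, g in df.groupby("primary_id")} if not df.empty else {}

    drug_by, reac_by, outc_by, indi_by = map(by_pid, (drugs, reacs, outcs, indis))
    reports = []
    for row in reps.itertuples(index=False):
        pid = row.primary_id
        dl = drug_by.get(pid)
        entries = []
        if dl is not None:
            dl = dl.assign(seq=dl["seq"].astype(int)).sort_values("seq")
            entries = [DrugEntry(d.verbatim_name, d.ingredient, d.role)
                       for d in dl.itertuples(index=False)]
        reports.append(SafetyReport(
            primary_id=pid, case_id=row.case_id,
            case_version=int(row.case_version),
            receipt_date=dt.date.fromisoformat(row.receipt_date),
            sex=row.sex,
            age_years=None if row.age_years == _MISSING else float(row.age_years),
            country=row.country,
            drugs=entries,
            reactions=list(reac_by.get(pid, pd.DataFrame({"pt": []}))["pt"]),
            outcomes=list(outc_by.get(pid, pd.DataFrame({"outc_cod": []}))["outc_cod"]),
            indications=list(indi_by.get(pid, pd.DataFrame({"indi_pt": []}))["indi_pt"]),
        ))
    window = None
    if meta["window_start"]:
        window = (meta["window_start"], meta["window_end"])
    n_raw = None if meta["n_raw"] == _MISSING else int(meta["n_raw"])
    return ReportStore(reports=reports, window=window, n_raw=n_raw)


def ingest_quarter_dirs(root: str | Path,
                        synonyms: dict[str, str] | None = None,
                        ) -> tuple[list[SafetyReport], dict[str, int]]:
    """Parse and assemble every quarter directory under ``root``.

    Each quarter directory holds DEMO/DRUG/REAC/OUTC/INDI ``.txt`` files.
    Returns the concatenated (pre-dedup) reports plus per-quarter counts.
    """
    root = Path(root)
    qdirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not qdirs:
        raise FormatError(f"{root}: no quarter directories found")
    all_reports: list[SafetyReport] = []
    per_quarter: dict[str, int] = {}
    for qdir in qdirs:
        tables = {}
        for name, cols in [("DEMO", ["primaryid", "caseid", "caseversion", "fda_dt"]),
                           ("DRUG", ["primaryid", "role_cod", "drugname"]),
                           ("REAC", ["primaryid", "pt"]),
                           ("OUTC", ["primaryid", "outc_cod"]),
                           ("INDI", ["primaryid", "indi_pt"])]:
            fp = qdir / f"{name}.txt"
            if not fp.exists():
                raise FormatError(f"{qdir}: missing {name}.txt")
            tables[name] = parse_dollar_table(fp, expected_columns=cols)
        reports, _ = assemble_reports(tables["DEMO"], tables["DRUG"],
                                      tables["REAC"], tables["OUTC"],
                                      tables["INDI"], synonyms=synonyms)
        per_quarter[qdir.name] = len(reports)
        all_reports += reports
    return all_reports, per_quarter


__all__ = [
    "DrugEntry", "SafetyReport", "ReportStore", "FormatError",
    "parse_dollar_table", "assemble_reports", "deduplicate",
    "normalize_drug_name", "load_synonyms_tsv", "filter_window",
    "quarter_of", "validate_quarter", "save_store", "load_store",
    "ingest_quarter_dirs", "COUNTRY_TO_CONTINENT", "ROLE_CODES",
    "OUTCOME_CODES",
]
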
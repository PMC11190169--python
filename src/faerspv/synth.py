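"""Synthetic FAERS-dialect report generator with planted associations.

Emulates the structure of a spontaneous-reporting extract — multi-drug
multi-event reports with role codes, duplicate case versions, heavy
demographic missingness, serious-outcome codes and quarterly batching —
while keeping exact ground truth, so every pipeline stage can be tested
end-to-end without any real data.

The reporting model: each report carries 1..max_drugs background drugs
drawn from a Zipf-like vocabulary, is additionally exposed to the study
drug with probability ``p_study_drug``, and samples each event PT
independently with its baseline per-report probability, multiplied by a
planted rate ratio ``lambda`` when the report is exposed to the planted
pair's drug.  ``lambda`` is exactly the relative reporting ratio that the
EBGM statistic estimates (up to the dilution from exposed reports'
contribution to the event margin).  Events are independent within a
report; real reports correlate them, which this v1 model does not emulate.

One pseudo-random generator keyed by the config seed drives the whole run,
so output is byte-identical across repeats.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DrugEntry, SafetyReport, OUTCOME_CODES, validate_quarter

DEFAULT_QUARTERS = ("2022Q2", "2022Q3", "2022Q4",
                    "2023Q1", "2023Q2", "2023Q3")

# marginal mixes loosely shaped like a US-dominated spontaneous-report stream
_SEX_LEVELS = ("F", "M")
_SEX_PROBS = (0.68, 0.17)  # remainder missing
_COUNTRIES = ("US", "JP", "GB", "CA", "BR", "AE")
_COUNTRY_PROBS = (0.93, 0.02, 0.015, 0.015, 0.01, 0.01)
_OUTCOME_PROBS = {"HO": 0.030, "OT": 0.038, "DE": 0.0025, "LT": 0.0017,
                  "DS": 0.0012, "RI": 0.0010, "CA": 0.0001}
_INDICATIONS = ("Product used for unknown indication",
                "Type 2 diabetes mellitus", "Weight decreased",
                "Obesity", "Insulin resistance")
_INDICATION_PROBS = (0.55, 0.20, 0.08, 0.04, 0.03)  # remainder: none


def _zipf(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


@dataclass(frozen=True)
class PlantedSignal:
    """A drug-event pair whose reporting rate is inflated by ``rate_ratio``."""

    drug: str
    event: str
    rate_ratio: float

    def __post_init__(self) -> None:
        if self.rate_ratio < 1:
            raise ValueError("rate_ratio must be >= 1")


@dataclass
class SimConfig:
    """Parameters of the synthetic report stream."""

    n_reports: int = 20_000
    seed: int = 0
    drug_vocab_size: int = 20
    event_vocab_size: int = 50
    drug_freqs: np.ndarray | None = None      # Zipf over the vocab by default
    event_freqs: np.ndarray | None = None
    mean_events_per_report: float = 2.0       # scales event_freqs to per-report probs
    study_drug: str = "tirzepatide"
    p_study_drug: float = 0.01
    planted: list[PlantedSignal] = field(default_factory=list)
    p_duplicate: float = 0.05
    missingness: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.15, "age": 0.64, "country": 0.005})
    quarters: tuple[str, ...] = DEFAULT_QUARTERS
    max_drugs_per_report: int = 4
    p_next_drug: float = 0.6                  # geometric parameter for drug count

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if self.drug_freqs is None:
            self.drug_freqs = _zipf(self.drug_vocab_size)
        if self.event_freqs is None:
            self.event_freqs = _zipf(self.event_vocab_size)
        self.drug_freqs = np.asarray(self.drug_freqs, dtype=float)
        self.event_freqs = np.asarray(self.event_freqs, dtype=float)
        for name, v in [("drug_freqs", self.drug_freqs),
                        ("event_freqs", self.event_freqs)]:
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        for p in [self.p_study_drug, self.p_duplicate,
                  *self.missingness.values()]:
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for q in self.quarters:
            validate_quarter(q)
        baselines = self.event_baselines
        for ps in self.planted:
            if ps.event not in self.event_names:
                raise ValueError(f"planted event {ps.event!r} not in vocabulary")
            base = baselines[self.event_names.index(ps.event)]
            if ps.rate_ratio * base > 1:
                raise ValueError(
                    f"infeasible planted signal {ps.drug}/{ps.event}: "
                    f"lambda*baseline = {ps.rate_ratio * base:.3f} > 1")

    @property
    def drug_names(self) -> list[str]:
        return [f"drug{i + 1:03d}" for i in range(self.drug_vocab_size)]

    @property
    def event_names(self) -> list[str]:
        return [f"Simulated event {i + 1:03d}"
                for i in range(self.event_vocab_size)]

    @property
    def event_baselines(self) -> np.ndarray:
        """Per-report baseline probability of each event PT."""
        p = self.event_freqs * self.mean_events_per_report
        if (p > 0.95).any():
            raise ValueError("event baselines exceed 0.95; lower "
                             "mean_events_per_report or flatten event_freqs")
        return p


@dataclass
class GroundTruth:
    """Exact tallies of the deduplicated synthetic report set."""

    n_reports: int
    n_exposed: dict[str, int]               # drug -> reports carrying it (any role)
    event_totals: dict[str, int]            # event -> reports carrying it
    cooccurrence: dict[tuple[str, str], int]  # (drug, event) -> a cell
    sex_counts: dict[str, int]
    quarter_counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"drug": d, "event": e, "a": n}
             for (d, e), n in sorted(self.cooccurrence.items())],
            columns=["drug", "event", "a"])


def _quarter_dates(label: str) -> tuple[dt.date, int]:
    year, q = int(label[:4]), int(label[5])
    start = dt.date(year, 3 * (q - 1) + 1, 1)
    end = (dt.date(year + 1, 1, 1) if q == 4
           else dt.date(year, 3 * q + 1, 1))
    return start, (end - start).days


def simulate_reports(cfg: SimConfig) -> tuple[list[SafetyReport], GroundTruth]:
    """Generate the report stream (including duplicate case versions).

    Returns the raw report list — duplicates and all, ready for
    :func:`faerspv.io.deduplicate` — plus ground-truth tallies computed on
    the deduplicated set (duplicate versions repeat their case's content,
    so the tallies are unaffected by which version survives).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    n_drugs, n_events = cfg.drug_vocab_size, cfg.event_vocab_size
    drug_names, event_names = cfg.drug_names, cfg.event_names

    # --- drugs: Gumbel top-k gives k distinct background drugs per report
    k = np.minimum(rng.geometric(cfg.p_next_drug, size=n),
                   cfg.max_drugs_per_report)
    gumbel = rng.gumbel(size=(n, n_drugs))
    keys = np.log(cfg.drug_freqs)[None, :] + gumbel
    order = np.argsort(-keys, axis=1)
    exposed_study = rng.random(n) < cfg.p_study_drug

    # exposure matrix over background drugs + study drug column
    exposure = np.zeros((n, n_drugs + 1), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    cols = order[:, :k.max()]
    take = np.arange(k.max())[None, :] < k[:, None]
    exposure[rows, cols[take]] = True
    exposure[:, n_drugs] = exposed_study
    all_drug_names = drug_names + [cfg.study_drug]

    # --- events: independent Bernoulli, planted pairs inflated when exposed
    prob = np.tile(cfg.event_baselines, (n, 1))
    for ps in cfg.planted:
        j = event_names.index(ps.event)
        di = all_drug_names.index(ps.drug)
        prob[exposure[:, di], j] *= ps.rate_ratio
    events = rng.random((n, n_events)) < prob

    # --- demographics
    miss = cfg.missingness
    u_sex = rng.random(n)
    sex = np.where(u_sex < miss.get("sex", 0), "UNK",
                   np.where(rng.random(n) < _SEX_PROBS[0] / sum(_SEX_PROBS),
                            "F", "M"))
    age = np.clip(rng.normal(52, 14, size=n), 18, 95).round(1)
    age_missing = rng.random(n) < miss.get("age", 0)
    country = np.array(_COUNTRIES)[
        rng.choice(len(_COUNTRIES), size=n,
                   p=np.array(_COUNTRY_PROBS) / sum(_COUNTRY_PROBS))]
    country[rng.random(n) < miss.get("country", 0)] = "UNK"

    qi = rng.integers(len(cfg.quarters), size=n)
    day_u = rng.random(n)
    outc_u = {oc: rng.random(n) for oc in OUTCOME_CODES}
    indi_probs = np.array(_INDICATION_PROBS + (1 - sum(_INDICATION_PROBS),))
    indi_idx = rng.choice(len(_INDICATIONS) + 1, size=n, p=indi_probs)
    ps_slot_u = rng.random(n)
    role_u = rng.random((n, n_drugs + 1))
    dup_mask = rng.random(n) < cfg.p_duplicate

    reports: list[SafetyReport] = []
    base_reports: list[SafetyReport] = []
    for i in range(n):
        drug_idx = np.flatnonzero(exposure[i])
        n_di = len(drug_idx)
        ps_at = int(ps_slot_u[i] * n_di)
        entries = []
        for j, di in enumerate(drug_idx):
            if j == ps_at:
                role = "PS"
            else:
                # secondary suspects are rarer than concomitants
                u = role_u[i, di]
                role = "SS" if u < 0.2 else ("I" if u > 0.97 else "C")
            name = all_drug_names[di]
            entries.append(DrugEntry(verbatim_name=name.upper(),
                                     ingredient=name, role=role))
        qlabel = cfg.quarters[qi[i]]
        qstart, qdays = _quarter_dates(qlabel)
        date = qstart + dt.timedelta(days=int(day_u[i] * qdays))
        report = SafetyReport(
            primary_id=f"{i + 1}1",
            case_id=f"C{i + 1:07d}",
            case_version=1,
            receipt_date=date,
            sex=str(sex[i]),
            age_years=None if age_missing[i] else float(age[i]),
            country=str(country[i]),
            drugs=entries,
            reactions=[event_names[j] for j in np.flatnonzero(events[i])],
            outcomes=[oc for oc in OUTCOME_CODES
                      if outc_u[oc][i] < _OUTCOME_PROBS[oc]],
            indications=([] if indi_idx[i] == len(_INDICATIONS)
                         else [_INDICATIONS[indi_idx[i]]]),
        )
        base_reports.append(report)
        reports.append(report)
        if dup_mask[i]:
            reports.append(SafetyReport(
                primary_id=f"{i + 1}2", case_id=report.case_id,
                case_version=2, receipt_date=date, sex=report.sex,
                age_years=report.age_years, country=report.country,
                drugs=list(entries), reactions=list(report.reactions),
                outcomes=list(report.outcomes),
                indications=list(report.indications)))

    a_matrix = exposure.T.astype(np.int64) @ events.astype(np.int64)
    gt = GroundTruth(
        n_reports=n,
        n_exposed={name: int(exposure[:, j].sum())
                   for j, name in enumerate(all_drug_names)},
        event_totals={event_names[j]: int(events[:, j].sum())
                      for j in range(n_events)},
        cooccurrence={(all_drug_names[dj], event_names[ej]): int(a_matrix[dj, ej])
                      for dj in range(n_drugs + 1) for ej in range(n_events)
                      if a_matrix[dj, ej] > 0},
        sex_counts={s: int((sex == s).sum()) for s in ("F", "M", "UNK")},
        quarter_counts={q: int((qi == j).sum())
                        for j, q in enumerate(cfg.quarters)},
    )
    return reports, gt


@dataclass
class RecoverySummary:
    """Estimator accuracy on the planted pairs."""

    pairs: pd.DataFrame  # drug, event, rate_ratio, a, ebgm, ror, rel_err, detected
    median_rel_err: float


def recovery_check(cfg: SimConfig, estimates: pd.DataFrame) -> RecoverySummary:
    """Compare a signal table's EBGM/ROR against the planted rate ratios.

    ``estimates`` is the frame from :func:`faerspv.stats.signals_to_frame`
    computed on data simulated under ``cfg``.  A planted pair absent from
    the frame (no co-occurrence reports) is recorded as non-detected.
    """
    rows = []
    for ps in cfg.planted:
        hit = estimates[estimates["event"] == ps.event]
        if hit.empty:
            rows.append({"drug": ps.drug, "event": ps.event,
                         "rate_ratio": ps.rate_ratio, "a": 0,
                         "ebgm": math.nan, "ror": math.nan,
                         "rel_err": math.nan, "detected": False})
            continue
        r = hit.iloc[0]
        rows.append({"drug": ps.drug, "event": ps.event,
                     "rate_ratio": ps.rate_ratio, "a": int(r["a"]),
                     "ebgm": float(r["ebgm"]), "ror": float(r["ror"]),
                     "rel_err": abs(float(r["ebgm"]) - ps.rate_ratio) / ps.rate_ratio,
                     "detected": bool(r.get("all_four", True))})
    pairs = pd.DataFrame(rows, columns=["drug", "event", "rate_ratio", "a",
                                        "ebgm", "ror", "rel_err", "detected"])
    finite = pairs["rel_err"].dropna()
    med = float(finite.median()) if len(finite) else math.nan
    return RecoverySummary(pairs=pairs, median_rel_err=med)


# ---------------------------------------------------------------------------
# FAERS-dialect serialization

_FILES = ("DEMO", "DRUG", "REAC", "OUTC", "INDI")


def write_faers_quarters(reports: list[SafetyReport], directory: str | Path
                         ) -> list[Path]:
    """Write reports as dollar-delimited DEMO/DRUG/REAC/OUTC/INDI files,
    one directory per quarter, ingestible by :mod:`faerspv.io`."""
    directory = Path(directory)
    by_quarter: dict[str, list[SafetyReport]] = {}
    for r in reports:
        by_quarter.setdefault(r.quarter, []).append(r)

    written: list[Path] = []
    for quarter in sorted(by_quarter):
        qdir = directory / quarter
        qdir.mkdir(parents=True, exist_ok=True)
        lines = {name: [] for name in _FILES}
        lines["DEMO"].append("primaryid$caseid$caseversion$fda_dt$sex$age_yrs$occr_country")
        lines["DRUG"].append("primaryid$caseid$role_cod$drugname")
        lines["REAC"].append("primaryid$caseid$pt")
        lines["OUTC"].append("primaryid$caseid$outc_cod")
        lines["INDI"].append("primaryid$caseid$indi_pt")
        for r in by_quarter[quarter]:
            sex = "" if r.sex == "UNK" else r.sex
            age = "" if r.age_years is None else repr(r.age_years)
            country = "" if r.country == "UNK" else r.country
            lines["DEMO"].append(
                f"{r.primary_id}${r.case_id}${r.case_version}$"
                f"{r.receipt_date.isoformat()}${sex}${age}${country}")
            for d in r.drugs:
                lines["DRUG"].append(
                    f"{r.primary_id}${r.case_id}${d.role}${d.verbatim_name}")
            for pt in r.reactions:
                lines["REAC"].append(f"{r.primary_id}${r.case_id}${pt}")
            for oc in r.outcomes:
                lines["OUTC"].append(f"{r.primary_id}${r.case_id}${oc}")
            for pt in r.indications:
                lines["INDI"].append(f"{r.primary_id}${r.case_id}${pt}")
        for name in _FILES:
            fp = qdir / f"{name}.txt"
            fp.write_text("\n".join(lines[name]) + "\n", encoding="utf-8")
            written.append(fp)
    return written


def load_config_yaml(path: str | Path) -> SimConfig:
    """Read a SimConfig from a YAML/JSON mapping."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    planted = [PlantedSignal(**p) for p in raw.pop("planted", [])]
    if "quarters" in raw:
        raw["quarters"] = tuple(raw["quarters"])
    return SimConfig(planted=planted, **raw)


__all__ = ["SimConfig", "PlantedSignal", "GroundTruth", "RecoverySummary",
           "simulate_reports", "recovery_check", "write_faers_quarters",
           "load_config_yaml", "DEFAULT_QUARTERS"]
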
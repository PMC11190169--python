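"""MedDRA preferred-term (PT) to system-organ-class (SOC) mapping.

MedDRA assigns every PT one *primary* SOC (plus optional secondary links);
SOC-level aggregation uses the primary link only.  The full dictionary is
licensed, so users supply their own TSV; the package bundles a small map
covering the terms used in its examples and simulator (PT codes in that
fixture are synthetic placeholders, SOC codes are the published ones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

UNMAPPED_SOC: tuple[int, str] = (0, "UNMAPPED")

_COLUMNS = ["pt_code", "pt_name", "soc_code", "soc_name", "primary_soc"]


@dataclass
class MedDRAMap:
    """Case-insensitive PT -> primary SOC lookup with secondary links kept."""

    entries: pd.DataFrame  # columns: pt_code, pt_name, soc_code, soc_name, primary_soc

    def __post_init__(self) -> None:
        df = self.entries
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"MedDRA map missing column(s): {', '.join(missing)}")
        primary = df[df["primary_soc"]]
        counts = primary.groupby(primary["pt_name"].str.lower()).size()
        bad = counts[counts > 1]
        if not bad.empty:
            raise ValueError(
                f"PT(s) with multiple primary SOCs: {', '.join(bad.index)}")
        all_pts = set(df["pt_name"].str.lower())
        orphan = all_pts - set(counts.index)
        if orphan:
            raise ValueError(
                f"PT(s) with no primary SOC: {', '.join(sorted(orphan))}")
        self._primary: dict[str, tuple[int, str]] = {
            pt.lower(): (int(code), name)
            for pt, code, name in zip(primary["pt_name"], primary["soc_code"],
                                      primary["soc_name"])}
        self._warned: set[str] = set()

    def pt_to_soc(self, pt_name: str) -> tuple[int, str]:
        """Primary SOC of a PT; unknown PTs map to the UNMAPPED pseudo-SOC."""
        hit = self._primary.get(pt_name.strip().lower())
        if hit is None:
            if pt_name not in self._warned:
                logger.warning("PT %r not in MedDRA map; assigned UNMAPPED", pt_name)
                self._warned.add(pt_name)
            return UNMAPPED_SOC
        return hit

    @property
    def soc_names(self) -> list[str]:
        return sorted({name for _, name in self._primary.values()})

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]],
                   soc_codes: dict[str, int] | None = None) -> "MedDRAMap":
        """Build a map from (pt_name, soc_name) pairs, for tests/simulations."""
        soc_codes = soc_codes or {}
        rows = [{"pt_code": 90000000 + i, "pt_name": pt,
                 "soc_code": soc_codes.get(soc, 0), "soc_name": soc,
                 "primary_soc": True}
                for i, (pt, soc) in enumerate(pairs)]
        return cls(pd.DataFrame(rows, columns=_COLUMNS))


def load_map_tsv(path: str | Path) -> MedDRAMap:
    """Load and validate a PT->SOC map from a TSV file."""
    df = pd.read_csv(path, sep="\t", dtype={"pt_code": int, "soc_code": int,
                                            "pt_name": str, "soc_name": str})
    if "primary_soc" in df.columns:
        df["primary_soc"] = df["primary_soc"].astype(str).str.lower().isin(
            ["1", "true", "yes", "y"])
    return MedDRAMap(df)


def bundled_map() -> MedDRAMap:
    """The small PT->SOC map shipped with the package."""
    with resources.as_file(
            resources.files("faerspv.data") / "meddra_map.tsv") as p:
        return load_map_tsv(p)


__all__ = ["MedDRAMap", "load_map_tsv", "bundled_map", "UNMAPPED_SOC"]
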
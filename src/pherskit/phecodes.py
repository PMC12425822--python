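"""ICD-to-phecode translation.

Phecodes group ICD-9/ICD-10 diagnosis codes into clinically meaningful
phenotypes arranged in a shallow decimal hierarchy: ``250.21`` (type 2
diabetes with ketoacidosis) is a child of ``250.2`` (type 2 diabetes),
whose three-digit parent is ``250`` (diabetes mellitus).  Each phecode
carries an *exclusion range* — an interval of phecodes too closely
related to the phenotype to serve as predictors or controls for it.

This module implements

* normalization of raw ICD strings (uppercase, strip non-alphanumerics),
* exact lookup with a truncation fallback (drop the final character and
  retry until the string is exhausted),
* rollup of any phecode to its three-digit parent, and
* the predictor-exclusion rule: a parent phecode is disallowed for a
  target disease when the parent itself, or any of its mapped children,
  falls inside the disease's exclusion range.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_NORMALIZE_RE = re.compile(r"[^A-Z0-9]")


class CodeSystem(str, Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"


def normalize_icd(raw: str) -> str:
    """Uppercase and strip every non-alphanumeric character from an ICD code."""
    return _NORMALIZE_RE.sub("", str(raw).upper())


@dataclass(frozen=True)
class IcdCode:
    """A raw diagnosis code together with its normalized lookup form."""

    system: CodeSystem
    raw: str
    normalized: str = field(default="")

    def __post_init__(self) -> None:
        if not self.normalized:
            object.__setattr__(self, "normalized", normalize_icd(self.raw))


@dataclass(frozen=True)
class Phecode:
    """A phecode entry: code string, three-digit parent, optional metadata."""

    code: str
    label: str = ""
    category: str = ""

    @property
    def parent(self) -> str:
        return rollup_to_parent(self.code)


class PhecodeMapError(ValueError):
    """Malformed phecode map file or malformed phecode string."""


def rollup_to_parent(code: str) -> str:
    """Truncate a phecode at the decimal point, e.g. ``250.21`` -> ``250``.

    Idempotent: a parent rolls up to itself.
    """
    code = str(code).strip()
    if not code or not re.fullmatch(r"\d+(\.\d+)?", code):
        raise PhecodeMapError(f"malformed phecode string: {code!r}")
    return code.split(".")[0]


def _parse_exclusion_ranges(text: str) -> list[tuple[float, float]]:
    """Parse ``"249-250.99,649.1-649.19"`` into numeric [lo, hi] intervals.

    A bare value ``"x"`` is the degenerate interval [x, x].
    """
    intervals: list[tuple[float, float]] = []
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return intervals
    for part in str(text).split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo_s, hi_s = part.split("-", 1)
            lo, hi = float(lo_s), float(hi_s)
        else:
            lo = hi = float(part)
        if lo > hi:
            raise PhecodeMapError(f"exclusion interval with lo > hi: {part!r}")
        intervals.append((lo, hi))
    return intervals


@dataclass
class PhecodeMap:
    """Deterministic ICD -> phecode lookup plus per-phecode exclusion ranges.

    ``entries`` is keyed by (code system, normalized ICD string); ICD-9 and
    ICD-10 live in separate namespaces to avoid collisions.  ``exclusion_ranges``
    maps a phecode string to a list of numeric [lo, hi] intervals.
    """

    entries: dict[tuple[CodeSystem, str], Phecode]
    exclusion_ranges: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    n_conflicts: int = 0
    n_skipped: int = 0

    def lookup(self, system: CodeSystem, normalized: str) -> Phecode | None:
        return self.entries.get((system, normalized))

    def phecodes(self) -> set[str]:
        return {p.code for p in self.entries.values()}

    def children_of(self, parent: str) -> set[str]:
        """All phecodes in the map whose three-digit parent is ``parent``."""
        return {c for c in self.phecodes() if rollup_to_parent(c) == parent}


_DIALECT_COLUMNS = {
    # column aliases, per dialect: (icd column, phecode column)
    "phewascatalog_v1_2": ("icd", "phecode"),
    "simple_two_column": ("icd", "phecode"),
}


def load_phecode_map(
    path: str | Path,
    dialect: str = "phewascatalog_v1_2",
) -> PhecodeMap:
    """Read a phecode map CSV.

    The primary dialect targets the phewascatalog v1.2 column layout
    (``icd, phecode, exclude_range`` at minimum, optionally
    ``code_system, label, category``); ``simple_two_column`` accepts a bare
    (icd, phecode) table for fixtures.  Rows with an empty phecode are
    skipped with a warning; duplicate (system, ICD) rows keep the first
    occurrence, and the number of conflicting duplicates is recorded on the
    returned map.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise PhecodeMapError(f"unknown phecode map dialect: {dialect!r}")
    df = pd.read_csv(path, dtype=str)
    if df.empty and df.columns.empty:
        raise PhecodeMapError(f"empty phecode map file: {path}")
    df.columns = [c.strip().lower() for c in df.columns]
    icd_col, phe_col = _DIALECT_COLUMNS[dialect]
    for col in (icd_col, phe_col):
        if col not in df.columns:
            raise PhecodeMapError(f"phecode map is missing required column {col!r}")

    entries: dict[tuple[CodeSystem, str], Phecode] = {}
    exclusion: dict[str, list[tuple[float, float]]] = {}
    n_conflicts = 0
    n_skipped = 0
    has_system = "code_system" in df.columns
    for row in df.itertuples(index=False):
        rec = row._asdict()
        phe_raw = rec.get(phe_col)
        if phe_raw is None or pd.isna(phe_raw) or not str(phe_raw).strip():
            n_skipped += 1
            logger.warning("skipping map row with empty phecode: icd=%r", rec.get(icd_col))
            continue
        system = CodeSystem(rec["code_system"]) if has_system and not pd.isna(rec.get("code_system")) else CodeSystem.ICD10
        norm = normalize_icd(rec[icd_col])
        phe = Phecode(
            code=str(phe_raw).strip(),
            label=str(rec.get("label") or "") if not pd.isna(rec.get("label", "")) else "",
            category=str(rec.get("category") or "") if not pd.isna(rec.get("category", "")) else "",
        )
        key = (system, norm)
        if key in entries:
            if entries[key].code != phe.code:
                n_conflicts += 1
                logger.warning(
                    "duplicate ICD %s with conflicting phecodes %s / %s; keeping first",
                    norm, entries[key].code, phe.code,
                )
            continue
        entries[key] = phe
        if dialect == "phewascatalog_v1_2" and "exclude_range" in df.columns:
            ranges = _parse_exclusion_ranges(rec.get("exclude_range"))
            if ranges and phe.code not in exclusion:
                exclusion[phe.code] = ranges
    return PhecodeMap(entries=entries, exclusion_ranges=exclusion,
                      n_conflicts=n_conflicts, n_skipped=n_skipped)


def map_icd_to_phecode(code: IcdCode, pmap: PhecodeMap) -> Phecode | None:
    """Exact lookup on the normalized ICD string, with truncation fallback.

    On a miss the final character is dropped and the lookup retried, until
    either an entry is found or the string is exhausted (returns None).
    """
    phe, _ = _map_with_steps(code, pmap)
    return phe


def _map_with_steps(code: IcdCode, pmap: PhecodeMap) -> tuple[Phecode | None, int]:
    s = code.normalized
    steps = 0
    while s:
        hit = pmap.lookup(code.system, s)
        if hit is not None:
            return hit, steps
        s = s[:-1]
        steps += 1
    return None, steps


def mapping_report(codes: Iterable[IcdCode], pmap: PhecodeMap) -> pd.DataFrame:
    """Per-code mapping audit table.

    Columns: code, normalized, matched_entry, truncation_steps, phecode,
    parent, crossed_category_boundary (ICD-10 matches shorter than three
    characters are flagged rather than rejected).
    """
    rows = []
    for code in codes:
        phe, steps = _map_with_steps(code, pmap)
        matched = code.normalized[: len(code.normalized) - steps] if phe is not None else ""
        rows.append({
            "code": code.raw,
            "normalized": code.normalized,
            "matched_entry": matched,
            "truncation_steps": steps if phe is not None else len(code.normalized),
            "phecode": phe.code if phe is not None else "",
            "parent": phe.parent if phe is not None else "",
            "crossed_category_boundary": bool(
                phe is not None
                and code.system is CodeSystem.ICD10
                and 0 < len(matched) < 3 <= len(code.normalized)
            ),
        })
    return pd.DataFrame(rows)


def _in_any_interval(value: float, intervals: Sequence[tuple[float, float]]) -> bool:
    return any(lo <= value <= hi for lo, hi in intervals)


def excluded_phecodes_for_disease(
    disease_phecode: str,
    pmap: PhecodeMap,
    observed_parents: Iterable[str],
) -> set[str]:
    """Parent phecodes disallowed as predictors for a target disease.

    A parent is excluded when its own numeric value, or the value of any of
    its child phecodes present in the map, lies inside any of the disease's
    exclusion intervals.  (Example: conditions complicating pregnancy, 649,
    is excluded for type 2 diabetes because its child 649.1 sits in the
    exclusion range of phecode 250.2 even though 649 itself does not.)
    """
    disease_phecode = str(disease_phecode)
    if disease_phecode not in pmap.phecodes() and disease_phecode not in pmap.exclusion_ranges:
        raise PhecodeMapError(
            f"disease phecode {disease_phecode!r} is absent from the map"
        )
    intervals = pmap.exclusion_ranges.get(disease_phecode, [])
    if not intervals:
        return set()
    excluded: set[str] = set()
    for parent in observed_parents:
        if _in_any_interval(float(parent), intervals):
            excluded.add(parent)
            continue
        if any(_in_any_interval(float(child), intervals) for child in pmap.children_of(parent)):
            excluded.add(parent)
    return excluded


def map_diagnoses(
    diagnoses: pd.DataFrame,
    pmap: PhecodeMap,
    code_column: str = "code",
    system_column: str = "code_system",
) -> pd.DataFrame:
    """Vectorised mapping of a long diagnosis table to parent phecodes.

    Returns a copy with ``phecode`` and ``parent`` columns; unmappable rows
    are dropped (their count is available by comparing lengths).
    """
    df = diagnoses.copy()
    systems = df[system_column].map(lambda s: CodeSystem(s))
    cache: dict[tuple[CodeSystem, str], Phecode | None] = {}
    phecodes = []
    for system, raw in zip(systems, df[code_column]):
        key = (system, normalize_icd(raw))
        if key not in cache:
            cache[key] = map_icd_to_phecode(IcdCode(system, str(raw)), pmap)
        phecodes.append(cache[key])
    df["phecode"] = [p.code if p is not None else None for p in phecodes]
    df = df[df["phecode"].notna()].copy()
    df["parent"] = [rollup_to_parent(c) for c in df["phecode"]]
    return df
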
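"""Glioma cohort identification, drug-name normalization, exposure and
bevacizumab regimen assignment.

The cohort is built by case-insensitive contiguous-substring matching of
configured tumor terms over the free-text indication and medical-history
fields.  Substring (not word-boundary) semantics are intentional:
"ASTROCYTOMA" matches "ANAPLASTIC ASTROCYTOMA", and the shipped broad
term list is closed under this, so no over-capture occurs within it.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import yaml

from .icsr_store import Report, ReportSet

BEVACIZUMAB = "BEVACIZUMAB"
TEMOZOLOMIDE = "TEMOZOLOMIDE"
LOMUSTINE = "LOMUSTINE"
CARMUSTINE = "CARMUSTINE"
DEFAULT_DRUGS = (TEMOZOLOMIDE, BEVACIZUMAB, LOMUSTINE, CARMUSTINE)


def _data_path(name: str):
    return resources.files("pvsignal.data").joinpath(name)


@dataclass(frozen=True)
class CohortDefinition:
    """A named set of uppercase free-text search terms and the report
    fields they are matched against."""

    name: str
    terms: tuple[str, ...]
    match_fields: tuple[str, ...] = ("indications", "history_text")

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("terms must be nonempty")
        object.__setattr__(self, "terms",
                           tuple(t.strip().upper() for t in self.terms))
        bad = set(self.match_fields) - {"indications", "history_text"}
        if bad:
            raise ValueError(f"unknown match fields: {sorted(bad)}")


@dataclass(frozen=True)
class ExposureDefinition:
    """Drug exposure: a set of generic names plus a role filter (any
    role, or primary-suspect only)."""

    generic_names: tuple[str, ...]
    role_filter: str = "ANY"

    def __post_init__(self) -> None:
        if not self.generic_names:
            raise ValueError("generic_names must be nonempty")
        if self.role_filter not in ("ANY", "PS_ONLY"):
            raise ValueError("role_filter must be ANY or PS_ONLY")
        object.__setattr__(self, "generic_names",
                           tuple(g.strip().upper() for g in self.generic_names))


class RegimenLabel(str, Enum):
    """Mutually exclusive bevacizumab regimen labels.  Reports carrying
    bevacizumab together with both temozolomide and lomustine fall into
    BEV_OTHER_COMBO; they only ever contribute to the comparator cells of
    the regimen analysis, never to a focal group."""

    BEV_MONO = "BEV_MONO"
    BEV_TMZ = "BEV_TMZ"
    BEV_LOM = "BEV_LOM"
    BEV_OTHER_COMBO = "BEV_OTHER_COMBO"
    NOT_BEV = "NOT_BEV"


FOCAL_REGIMENS = (RegimenLabel.BEV_MONO, RegimenLabel.BEV_TMZ,
                  RegimenLabel.BEV_LOM)


def load_cohort_definitions(path: str | Path | None = None) -> dict[str, CohortDefinition]:
    """Load the broad and strict cohort definitions from config."""
    src = Path(path) if path is not None else _data_path("cohort_terms.yaml")
    data = yaml.safe_load(src.read_text())
    defs = {name: CohortDefinition(name, tuple(terms))
            for name, terms in data.items()}
    if "broad" in defs and "strict" in defs:
        if not set(defs["strict"].terms) <= set(defs["broad"].terms):
            raise ValueError("strict terms must be a subset of broad terms")
    return defs


def load_brand_map(path: str | Path | None = None) -> dict[str, str]:
    src = Path(path) if path is not None else _data_path("brand_map.yaml")
    raw = yaml.safe_load(src.read_text()) or {}
    return {str(k).strip().upper(): str(v).strip().upper()
            for k, v in raw.items()}


def match_cohort(report: Report, definition: CohortDefinition) -> bool:
    """True iff any term occurs as a contiguous substring of the
    uppercased concatenation of the selected free-text fields."""
    parts: list[str] = []
    if "indications" in definition.match_fields:
        parts.extend(report.indications)
    if "history_text" in definition.match_fields:
        parts.append(report.history_text)
    haystack = " | ".join(p.strip().upper() for p in parts if p)
    if not haystack:
        return False
    return any(term in haystack for term in definition.terms)


def filter_cohort(report_set: ReportSet,
                  definition: CohortDefinition) -> ReportSet:
    """Subset a report set to the reports matching a cohort definition."""
    return ReportSet(report_set.database,
                     [r for r in report_set if match_cohort(r, definition)])


_WS = re.compile(r"\s+")


def normalize_drug_name(verbatim: str, brand_map: dict[str, str]) -> str:
    """Uppercase/trim a verbatim drug name and replace exact brand-token
    hits with the generic name; unknown names are returned
    normalized-verbatim."""
    token = _WS.sub(" ", (verbatim or "").strip().upper())
    return brand_map.get(token, token)


def is_exposed(report: Report, exposure: ExposureDefinition) -> bool:
    """True iff some drug entry's generic name is in the exposure set and
    satisfies the role filter."""
    targets = set(exposure.generic_names)
    for entry in report.drugs:
        if entry.generic_name in targets:
            if exposure.role_filter == "ANY" or entry.role == "PS":
                return True
    return False


def assign_regimen(report: Report) -> RegimenLabel:
    """Classify a report by its bevacizumab co-prescription pattern;
    regimen assignment always uses any-role exposure."""
    names = report.generic_names()
    if BEVACIZUMAB not in names:
        return RegimenLabel.NOT_BEV
    has_tmz = TEMOZOLOMIDE in names
    has_lom = LOMUSTINE in names
    if has_tmz and has_lom:
        return RegimenLabel.BEV_OTHER_COMBO
    if has_tmz:
        return RegimenLabel.BEV_TMZ
    if has_lom:
        return RegimenLabel.BEV_LOM
    return RegimenLabel.BEV_MONO
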
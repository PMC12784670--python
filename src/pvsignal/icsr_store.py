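"""Normalized individual case safety report (ICSR) data model and I/O.

Spontaneous adverse-event reports arrive as one case per (report_id,
version), carrying drug entries with reporter-assigned roles (primary
suspect, secondary suspect, concomitant), MedDRA preferred-term reaction
lists, free-text indications and sparsely populated demographics. A case
may be submitted several times; only the latest version is analyzable.

Two dialects are supported: the package's own normalized four-table TSV
schema, and a minimal FAERS-quarterly-style "$"-delimited DEMO/DRUG/REAC/
INDI layout.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

# category codes -------------------------------------------------------------
DATABASES = ("FAERS", "CVARD")
ROLES = ("PS", "SS", "C")
SEXES = ("M", "F", "UNK")
AGE_GROUPS = ("12-17", "18-64", "65-85", "UNK")
WEIGHT_BANDS = ("LT50", "50TO100", "GT100", "UNK")
REPORTERS = ("HCP", "NONHCP", "UNK")
SERIOUS = ("YES", "NO", "UNK")

#: FAERS occupation codes treated as health-care professionals
HCP_OCCUPATIONS = frozenset({"MD", "PH", "OT", "HP"})


class FormatError(ValueError):
    """Raised when an input file violates the expected schema."""


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report."""

    verbatim_name: str
    generic_name: str
    role: str = "C"

    def __post_init__(self) -> None:
        if not self.verbatim_name:
            raise ValueError("verbatim_name must be nonempty")
        if not self.generic_name:
            raise ValueError("generic_name must be nonempty")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass
class Report:
    """One ICSR version: drugs, reactions, indications, demographics."""

    database: str
    report_id: str
    version: int = 1
    sex: str = "UNK"
    age_group: str = "UNK"
    weight_band: str = "UNK"
    reporter: str = "UNK"
    serious: str = "UNK"
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)
    history_text: str = ""

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be nonempty")
        if self.version < 1:
            raise ValueError("version must be >= 1")
        if any(not r for r in self.reactions):
            raise ValueError("reaction strings must be nonempty")
        self.sex = _coerce(self.sex, SEXES)
        self.age_group = _coerce(self.age_group, AGE_GROUPS)
        self.weight_band = _coerce(self.weight_band, WEIGHT_BANDS)
        self.reporter = _coerce(self.reporter, REPORTERS)
        self.serious = _coerce(self.serious, SERIOUS)

    def reaction_set(self) -> frozenset[str]:
        return frozenset(pt.strip().upper() for pt in self.reactions)

    def generic_names(self) -> frozenset[str]:
        return frozenset(d.generic_name for d in self.drugs)


@dataclass
class ReportSet:
    """An ordered collection of reports from a single database."""

    database: str
    reports: list[Report] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)


def _coerce(value: str, allowed: tuple[str, ...]) -> str:
    v = (value or "").strip().upper()
    return v if v in allowed else "UNK"


def bin_age(age_years: float | None) -> str:
    """Map an age in years onto the reporting bands; out-of-band ages
    (<12 or >85) have no band and are treated as unknown."""
    if age_years is None:
        return "UNK"
    if 12 <= age_years <= 17:
        return "12-17"
    if 18 <= age_years <= 64:
        return "18-64"
    if 65 <= age_years <= 85:
        return "65-85"
    return "UNK"


def bin_weight(weight_kg: float | None) -> str:
    if weight_kg is None or weight_kg <= 0:
        return "UNK"
    if weight_kg < 50:
        return "LT50"
    if weight_kg <= 100:
        return "50TO100"
    return "GT100"


def map_occupation(occp_cod: str) -> str:
    code = (occp_cod or "").strip().upper()
    if not code:
        return "UNK"
    return "HCP" if code in HCP_OCCUPATIONS else "NONHCP"


def map_role(role_cod: str) -> str:
    """FAERS role_cod to the three-role scheme; interacting and any other
    unrecognized code is treated as concomitant."""
    code = (role_cod or "").strip().upper()
    return code if code in ROLES else "C"


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def deduplicate(report_set: ReportSet) -> ReportSet:
    """Keep only the latest version of each (database, report_id).

    Ties on (report_id, version) keep the last-read record and log a
    warning. Relative order of the surviving reports is preserved, and the
    operation is idempotent.
    """
    best: dict[str, Report] = {}
    order: list[str] = []
    for rep in report_set.reports:
        key = rep.report_id
        prev = best.get(key)
        if prev is None:
            best[key] = rep
            order.append(key)
        elif rep.version > prev.version:
            best[key] = rep
        elif rep.version == prev.version:
            if rep != prev:
                logger.warning(
                    "duplicate (report_id=%s, version=%d) with differing "
                    "content; keeping the later record", key, rep.version,
                )
            best[key] = rep
    return ReportSet(report_set.database, [best[k] for k in order])


# ---------------------------------------------------------------------------
# normalized TSV schema
# ---------------------------------------------------------------------------

_REPORT_COLS = ["database", "report_id", "version", "sex", "age_group",
                "weight_band", "reporter", "serious", "history_text"]
_DRUG_COLS = ["report_id", "version", "drug_seq", "verbatim_name",
              "generic_name", "role"]
_REAC_COLS = ["report_id", "version", "pt"]
_INDI_COLS = ["report_id", "version", "indication_text"]


def _read_table(path: str | Path, required: list[str], sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def read_normalized(reports_path, drugs_path, reactions_path,
                    indications_path) -> ReportSet:
    """Read the normalized four-table TSV schema into a (pre-dedup)
    ReportSet, one Report per row of the reports file, joined on
    (report_id, version)."""
    reports = _read_table(reports_path, _REPORT_COLS)
    drugs = _read_table(drugs_path, _DRUG_COLS)
    reacs = _read_table(reactions_path, _REAC_COLS)
    indis = _read_table(indications_path, _INDI_COLS)

    dup = drugs.duplicated(subset=["report_id", "version", "drug_seq"])
    if dup.any():
        first = drugs[dup].iloc[0]
        raise FormatError(
            f"{drugs_path}: duplicate (report_id, version, drug_seq) = "
            f"({first['report_id']}, {first['version']}, {first['drug_seq']})"
        )

    def grouped(df: pd.DataFrame) -> dict:
        return {k: g for k, g in df.groupby(["report_id", "version"], sort=False)}

    drug_groups = grouped(drugs)
    reac_groups = grouped(reacs)
    indi_groups = grouped(indis)

    database = ""
    out: list[Report] = []
    for row in reports.itertuples(index=False):
        key = (row.report_id, row.version)
        database = row.database.strip().upper() or database
        entries: list[DrugEntry] = []
        if key in drug_groups:
            g = drug_groups[key].sort_values("drug_seq", key=lambda s: s.astype(int))
            for d in g.itertuples(index=False):
                entries.append(DrugEntry(
                    verbatim_name=d.verbatim_name,
                    generic_name=d.generic_name.strip().upper(),
                    role=map_role(d.role),
                ))
        pts = list(reac_groups[key]["pt"]) if key in reac_groups else []
        inds = (list(indi_groups[key]["indication_text"])
                if key in indi_groups else [])
        out.append(Report(
            database=row.database.strip().upper(),
            report_id=row.report_id,
            version=int(row.version),
            sex=row.sex, age_group=row.age_group,
            weight_band=row.weight_band, reporter=row.reporter,
            serious=row.serious, drugs=entries, reactions=pts,
            indications=inds, history_text=row.history_text,
        ))
    return ReportSet(database or "FAERS", out)


def write_normalized(report_set: ReportSet, out_dir: str | Path) -> dict[str, Path]:
    """Write a ReportSet in the normalized TSV schema; inverse of
    :func:`read_normalized` for in-band values."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rep_rows, drug_rows, reac_rows, indi_rows = [], [], [], []
    for r in report_set:
        rep_rows.append({
            "database": r.database, "report_id": r.report_id,
            "version": r.version, "sex": r.sex, "age_group": r.age_group,
            "weight_band": r.weight_band, "reporter": r.reporter,
            "serious": r.serious, "history_text": r.history_text,
        })
        for i, d in enumerate(r.drugs, start=1):
            drug_rows.append({
                "report_id": r.report_id, "version": r.version, "drug_seq": i,
                "verbatim_name": d.verbatim_name,
                "generic_name": d.generic_name, "role": d.role,
            })
        for pt in r.reactions:
            reac_rows.append({"report_id": r.report_id, "version": r.version,
                              "pt": pt})
        for ind in r.indications:
            indi_rows.append({"report_id": r.report_id, "version": r.version,
                              "indication_text": ind})
    paths = {}
    for name, rows, cols in [
        ("reports", rep_rows, _REPORT_COLS),
        ("drugs", drug_rows, _DRUG_COLS),
        ("reactions", reac_rows, _REAC_COLS),
        ("indications", indi_rows, _INDI_COLS),
    ]:
        path = out_dir / f"{name}.tsv"
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# FAERS quarterly ASCII dialect
# ---------------------------------------------------------------------------

def _read_dollar(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if "$" not in header_line:
            raise FormatError(f"{path}: line 1: header is not '$'-delimited")
        header = header_line.split("$")
        ncol = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("$")
            if len(parts) != ncol:
                raise FormatError(
                    f"{path}: line {lineno}: expected {ncol} '$'-delimited "
                    f"fields, found {len(parts)}"
                )
            rows.append(parts)
    df = pd.DataFrame(rows, columns=header, dtype=str)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def _maybe_float(text: str) -> float | None:
    text = (text or "").strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def read_faers_ascii(demo_path, drug_path, reac_path, indi_path,
                     database: str = "FAERS",
                     brand_map: dict[str, str] | None = None) -> ReportSet:
    """Read minimal FAERS-quarterly-style '$'-delimited files.

    DEMO carries caseid/caseversion/sex/age/wt/occp_cod, DRUG carries
    caseid/drugname/prod_ai/role_cod, REAC carries caseid/pt and INDI
    carries caseid/indi_pt. Ages and weights are binned onto the
    reporting bands at ingest. ``prod_ai`` (active ingredient) is used as
    the generic name when present, else the verbatim drug name run
    through the brand map.
    """
    from .cohort import load_brand_map, normalize_drug_name

    if brand_map is None:
        brand_map = load_brand_map()
    demo = _read_dollar(demo_path, ["caseid", "caseversion", "sex", "age",
                                    "wt", "occp_cod"])
    drug = _read_dollar(drug_path, ["caseid", "drugname", "prod_ai",
                                    "role_cod"])
    reac = _read_dollar(reac_path, ["caseid", "pt"])
    indi = _read_dollar(indi_path, ["caseid", "indi_pt"])

    def group_cols(df: pd.DataFrame) -> list[str]:
        return (["caseid", "caseversion"] if "caseversion" in df.columns
                else ["caseid"])

    drug_g = {k: g for k, g in drug.groupby(group_cols(drug), sort=False)}
    reac_g = {k: g for k, g in reac.groupby(group_cols(reac), sort=False)}
    indi_g = {k: g for k, g in indi.groupby(group_cols(indi), sort=False)}

    out: list[Report] = []
    for row in demo.itertuples(index=False):
        caseid = row.caseid.strip()
        version = int(row.caseversion) if row.caseversion.strip() else 1
        drug_key = ((caseid, row.caseversion)
                    if "caseversion" in drug.columns else (caseid,))
        entries: list[DrugEntry] = []
        if drug_key in drug_g:
            for d in drug_g[drug_key].itertuples(index=False):
                verbatim = d.drugname.strip() or d.prod_ai.strip()
                generic = d.prod_ai.strip().upper() or normalize_drug_name(
                    verbatim, brand_map)
                if not verbatim:
                    continue
                entries.append(DrugEntry(verbatim, generic, map_role(d.role_cod)))
        reac_key = ((caseid, row.caseversion)
                    if "caseversion" in reac.columns else (caseid,))
        indi_key = ((caseid, row.caseversion)
                    if "caseversion" in indi.columns else (caseid,))
        pts = list(reac_g[reac_key]["pt"]) if reac_key in reac_g else []
        inds = list(indi_g[indi_key]["indi_pt"]) if indi_key in indi_g else []
        out.append(Report(
            database=database,
            report_id=caseid,
            version=version,
            sex=row.sex,
            age_group=bin_age(_maybe_float(row.age)),
            weight_band=bin_weight(_maybe_float(row.wt)),
            reporter=map_occupation(row.occp_cod),
            serious=getattr(row, "serious", "UNK") or "UNK",
            drugs=entries,
            reactions=[p for p in pts if p.strip()],
            indications=[i for i in inds if i.strip()],
        ))
    return ReportSet(database, out)
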
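"""Orchestration of the glioma signal-detection analyses.

Four surfaces mirror the study design: a main disproportionality
analysis of the prespecified drugs against the three vascular endpoints
within the broad glioma cohort, a bevacizumab regimen-stratified
analysis, sensitivity analyses swapping in the strict cohort definition
or primary-suspect-only exposure, and a baseline descriptive summary.
Databases are analyzed independently; a ReportSet carries reports of a
single database and results are never pooled across databases.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics
from .cohort import (DEFAULT_DRUGS, FOCAL_REGIMENS, BEVACIZUMAB,
                     CohortDefinition, ExposureDefinition, RegimenLabel,
                     filter_cohort, is_exposed, load_cohort_definitions)
from .endpoints import EndpointDefinition, load_endpoints
from .icsr_store import ReportSet
from .metrics import (DisproportionalityResult, GammaMixturePrior,
                      build_contingency, build_regimen_contingency,
                      default_prior, fit_gamma_mixture_prior,
                      result_from_table)

SENSITIVITY_VARIANTS = ("STRICT_COHORT", "PS_ONLY")


@dataclass
class AnalysisPlan:
    """What to analyze: cohort definition, exposure role filter, drug
    list and endpoint definitions."""

    cohort_def: CohortDefinition | None = None
    role_filter: str = "ANY"
    drugs: tuple[str, ...] = DEFAULT_DRUGS
    endpoints: dict[str, EndpointDefinition] | None = None
    run_regimen: bool = False

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError("drugs must be nonempty")
        if self.role_filter not in ("ANY", "PS_ONLY"):
            raise ValueError("role_filter must be ANY or PS_ONLY")
        if self.cohort_def is None:
            self.cohort_def = load_cohort_definitions()["broad"]
        if self.endpoints is None:
            self.endpoints = load_endpoints()


def _fit_prior(tables: list[metrics.ContingencyTable]) -> GammaMixturePrior:
    """Fit the shrinkage prior on all pairs of one analysis call; with
    too few pairs for a stable marginal-likelihood fit, fall back to the
    conventional prior flagged low-information."""
    pairs = [(t.a, max(t.expected, 1e-12)) for t in tables]
    counts = {p[0] for p in pairs}
    if len(pairs) < 10 or len(counts) < 2:
        return default_prior()
    try:
        return fit_gamma_mixture_prior(pairs)
    except metrics.ConvergenceError as err:
        return replace(err.best, low_information=True)


def run_main_analysis(report_set: ReportSet, plan: AnalysisPlan | None = None
                      ) -> list[DisproportionalityResult]:
    """One result per drug x endpoint within the plan's glioma cohort.

    The EBGM prior is fitted once per call on all of the call's (a, E)
    pairs.  Pairs with a < 3 are flagged not analyzable; their counts
    are still reported.
    """
    plan = plan or AnalysisPlan()
    cohort = filter_cohort(report_set, plan.cohort_def)
    tables, keys = [], []
    for drug in plan.drugs:
        exposure = ExposureDefinition((drug,), plan.role_filter)
        for ep in plan.endpoints.values():
            tables.append(build_contingency(cohort, exposure, ep))
            keys.append((drug, ep.name))
    prior = _fit_prior(tables)
    variant = "PS_ONLY" if plan.role_filter == "PS_ONLY" else (
        "STRICT_COHORT" if plan.cohort_def.name == "strict" else "MAIN")
    return [result_from_table(t, report_set.database, drug, ep, prior,
                              variant)
            for t, (drug, ep) in zip(tables, keys)]


def run_regimen_analysis(report_set: ReportSet,
                         plan: AnalysisPlan | None = None
                         ) -> list[DisproportionalityResult]:
    """Bevacizumab regimen stratification: each focal regimen
    (monotherapy, +temozolomide, +lomustine) contrasted against all
    other bevacizumab-containing regimens within the glioma cohort.

    Triple combinations contribute only to the comparator cells.  Focal
    groups with a < 3 are reported but flagged not analyzable.
    """
    plan = plan or AnalysisPlan()
    cohort = filter_cohort(report_set, plan.cohort_def)
    bev = ReportSet(cohort.database,
                    [r for r in cohort
                     if is_exposed(r, ExposureDefinition((BEVACIZUMAB,)))])
    if len(bev) == 0:
        raise metrics.EmptyCohortError(
            "no bevacizumab-exposed reports in the cohort")
    tables, keys = [], []
    for focal in FOCAL_REGIMENS:
        for ep in plan.endpoints.values():
            tables.append(build_regimen_contingency(bev, focal, ep))
            keys.append((focal.value, ep.name))
    prior = _fit_prior(tables)
    return [result_from_table(t, report_set.database, focal, ep, prior,
                              "REGIMEN")
            for t, (focal, ep) in zip(tables, keys)]


def run_sensitivity(report_set: ReportSet, variant: str,
                    plan: AnalysisPlan | None = None
                    ) -> list[DisproportionalityResult]:
    """Re-run the main analysis with the strict cohort definition or
    with exposure restricted to primary-suspect drug mentions."""
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(f"variant must be one of {SENSITIVITY_VARIANTS}")
    plan = plan or AnalysisPlan()
    if variant == "STRICT_COHORT":
        plan = replace(plan, cohort_def=load_cohort_definitions()["strict"])
    else:
        plan = replace(plan, role_filter="PS_ONLY")
    return run_main_analysis(report_set, plan)


def sensitivity_comparison(main: list[DisproportionalityResult],
                           sensitivity: list[DisproportionalityResult]
                           ) -> pd.DataFrame:
    """Side-by-side main-vs-sensitivity table (per drug x endpoint):
    counts, RORs with CIs and signal status under both definitions."""
    sens_by_key = {(r.drug_or_regimen, r.event): r for r in sensitivity}
    rows = []
    for r in main:
        s = sens_by_key.get((r.drug_or_regimen, r.event))
        if s is None:
            continue
        rows.append({
            "database": r.database, "drug": r.drug_or_regimen,
            "event": r.event,
            "n_main": r.table.a, "ror_main": round(r.ror, 2),
            "ror_low_main": round(r.ror_low, 2),
            "ror_high_main": round(r.ror_high, 2), "signal_main": r.signal,
            "n_sensitivity": s.table.a, "ror_sensitivity": round(s.ror, 2),
            "ror_low_sensitivity": round(s.ror_low, 2),
            "ror_high_sensitivity": round(s.ror_high, 2),
            "signal_sensitivity": s.signal, "variant": s.variant,
        })
    return pd.DataFrame(rows)


def summarize_cohort(report_set: ReportSet,
                     drugs: tuple[str, ...] = DEFAULT_DRUGS) -> pd.DataFrame:
    """Baseline descriptive table: per drug, counts and percentages of
    the sex/age/weight bands plus reporter and seriousness, computed
    over the drug's any-role exposed reports."""
    blocks = {
        "sex": ("M", "F", "UNK"),
        "age_group": ("12-17", "18-64", "65-85", "UNK"),
        "weight_band": ("LT50", "50TO100", "GT100", "UNK"),
        "reporter": ("HCP", "NONHCP", "UNK"),
        "serious": ("YES", "NO", "UNK"),
    }
    rows = []
    for drug in drugs:
        exposure = ExposureDefinition((drug,))
        exposed = [r for r in report_set if is_exposed(r, exposure)]
        total = len(exposed)
        for field_name, levels in blocks.items():
            for level in levels:
                count = sum(1 for r in exposed
                            if getattr(r, field_name) == level)
                rows.append({
                    "drug": drug, "characteristic": field_name,
                    "level": level, "n": count, "total": total,
                    "pct": round(100.0 * count / total, 1) if total else 0.0,
                })
    return pd.DataFrame(rows)


def export_forest_data(results: list[DisproportionalityResult]
                       ) -> pd.DataFrame:
    """Per-result forest-plot data (log-scale fields included); the
    rendering itself is out of scope."""
    rows = []
    for r in results:
        rows.append({
            "database": r.database, "drug_or_regimen": r.drug_or_regimen,
            "event": r.event, "a": r.table.a,
            "ror": round(r.ror, 2), "ror_low": round(r.ror_low, 2),
            "ror_high": round(r.ror_high, 2),
            "log_ror": round(float(np.log(r.ror)), 6),
            "log_ror_low": round(float(np.log(r.ror_low)), 6),
            "log_ror_high": round(float(np.log(r.ror_high)), 6),
            "signal": r.signal, "analyzable": r.analyzable,
            "variant": r.variant,
        })
    return pd.DataFrame(rows, columns=[
        "database", "drug_or_regimen", "event", "a", "ror", "ror_low",
        "ror_high", "log_ror", "log_ror_low", "log_ror_high", "signal",
        "analyzable", "variant"])
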
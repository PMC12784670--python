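"""Composite outcome endpoints as MedDRA preferred-term sets.

A report counts once toward an endpoint when at least one of its
reaction PTs belongs to the endpoint's set, irrespective of how many
matching PTs it carries and of whether the event was a first occurrence
or a recurrence.  Comparison is exact string equality after
case/whitespace normalization; no MedDRA hierarchy expansion.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .icsr_store import Report, ReportSet

ENDPOINT_NAMES = ("VTE", "CNS_BLEED", "GI_BLEED")


@dataclass(frozen=True)
class EndpointDefinition:
    name: str
    pts: frozenset[str]

    def __post_init__(self) -> None:
        if not self.pts:
            raise ValueError("pts must be nonempty")
        object.__setattr__(
            self, "pts", frozenset(p.strip().upper() for p in self.pts))


def load_endpoints(path: str | Path | None = None) -> dict[str, EndpointDefinition]:
    """Load endpoint PT sets from config; the shipped defaults are
    pairwise disjoint."""
    if path is None:
        from .cohort import _data_path
        src = _data_path("endpoints.yaml")
    else:
        src = Path(path)
    raw = yaml.safe_load(src.read_text())
    defs = {name: EndpointDefinition(name, frozenset(pts))
            for name, pts in raw.items()}
    names = list(defs)
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            overlap = defs[x].pts & defs[y].pts
            if overlap:
                raise ValueError(
                    f"endpoint PT sets {x} and {y} overlap: {sorted(overlap)}")
    return defs


def has_endpoint(report: Report, definition: EndpointDefinition) -> bool:
    """True iff the report mentions >= 1 PT of the endpoint set."""
    return bool(report.reaction_set() & definition.pts)


def endpoint_counts(report_set: ReportSet,
                    definitions: list[EndpointDefinition]) -> dict[str, int]:
    """Number of distinct reports with >= 1 matching PT per endpoint; a
    report may count toward several endpoints but never twice toward
    one."""
    counts = {d.name: 0 for d in definitions}
    for report in report_set:
        pts = report.reaction_set()
        for d in definitions:
            if pts & d.pts:
                counts[d.name] += 1
    return counts
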
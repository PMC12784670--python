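"""Synthetic spontaneous-reporting databases with known ground truth.

The generator emulates the statistical structure that disproportionality
analysis assumes: a stream of case reports, most carrying a glioma
indication, each mentioning one or more drugs (with reporter-assigned
roles and brand/generic verbatim spellings), a MedDRA-PT reaction list
mixing endpoint events with background terms, heavily missing
demographics, and occasional resubmitted versions of the same case.

Drug exposure is drawn from a log-linear joint model over the configured
drugs (marginal probabilities tilted by pairwise co-prescription odds),
and each composite endpoint fires with logistic odds

    logit p(event) = logit(baseline) + sum_exposed log(multiplier),

so the configured effect is an odds multiplier and the population
reporting odds ratio implied by the model exists in closed form
(:func:`true_odds_ratio`).  Everything is deterministic given the
config seed.

Two sampling surfaces share one probabilistic core: :func:`generate`
materializes :class:`~pvsignal.icsr_store.Report` objects (duplicates
included) for end-to-end pipeline runs, while :func:`simulate_tables`
returns the glioma-cohort 2x2 tables directly from the underlying
arrays, which keeps large replicate studies cheap.  Their agreement is
part of the test suite.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .cohort import (BEVACIZUMAB, CARMUSTINE, DEFAULT_DRUGS, LOMUSTINE,
                     TEMOZOLOMIDE, RegimenLabel)
from .endpoints import ENDPOINT_NAMES, load_endpoints
from .icsr_store import DrugEntry, Report, ReportSet
from .metrics import ContingencyTable


class ConfigError(ValueError):
    pass


_BRAND_VERBATIM = {
    BEVACIZUMAB: "Avastin",
    TEMOZOLOMIDE: "Temodar",
    LOMUSTINE: "Gleostine",
    CARMUSTINE: "Gliadel",
}

_GLIOMA_BROAD_ONLY = ("Glioma", "Astrocytoma", "Oligodendroglioma",
                      "Anaplastic oligodendroglioma")
_GLIOMA_STRICT = ("Malignant glioma", "Glioblastoma",
                  "Glioblastoma multiforme", "Anaplastic astrocytoma")
_OTHER_INDICATIONS = ("Non-small cell lung cancer", "Colorectal cancer",
                      "Breast cancer", "Ovarian cancer", "Multiple myeloma")

_BACKGROUND_DRUGS = ("DEXAMETHASONE", "LEVETIRACETAM", "OMEPRAZOLE",
                     "ONDANSETRON", "VALPROIC ACID")

#: default background (non-endpoint) reaction PTs with sampling weights
DEFAULT_BACKGROUND_PTS = (
    ("HEADACHE", 3.0), ("FATIGUE", 3.0), ("NAUSEA", 3.0), ("VOMITING", 2.0),
    ("SEIZURE", 2.0), ("THROMBOCYTOPENIA", 2.0), ("NEUTROPENIA", 2.0),
    ("DISEASE PROGRESSION", 2.0), ("PYREXIA", 1.0), ("RASH", 1.0),
    ("ANAEMIA", 1.0), ("HEMIPARESIS", 1.0), ("APHASIA", 1.0),
    ("CEREBRAL OEDEMA", 1.0), ("DIZZINESS", 1.0), ("DIARRHOEA", 1.0),
    ("CONSTIPATION", 1.0), ("ALANINE AMINOTRANSFERASE INCREASED", 1.0),
)


def _default_drug_marginals() -> dict[str, float]:
    return {BEVACIZUMAB: 0.30, TEMOZOLOMIDE: 0.35, LOMUSTINE: 0.10,
            CARMUSTINE: 0.02}


def _default_coprescription() -> dict[tuple[str, str], float]:
    return {(BEVACIZUMAB, TEMOZOLOMIDE): 2.0,
            (BEVACIZUMAB, LOMUSTINE): 1.5}


def _default_baseline() -> dict[str, float]:
    return {"VTE": 0.06, "CNS_BLEED": 0.04, "GI_BLEED": 0.025}


def _default_effects() -> dict[tuple[str, str], float]:
    # reporting-odds structure patterned on the FAERS glioma signals
    return {
        (BEVACIZUMAB, "VTE"): 2.3, (BEVACIZUMAB, "CNS_BLEED"): 1.5,
        (BEVACIZUMAB, "GI_BLEED"): 2.3,
        (TEMOZOLOMIDE, "VTE"): 1.0, (TEMOZOLOMIDE, "CNS_BLEED"): 0.8,
        (TEMOZOLOMIDE, "GI_BLEED"): 1.4,
        (LOMUSTINE, "VTE"): 1.4, (LOMUSTINE, "CNS_BLEED"): 0.35,
        (LOMUSTINE, "GI_BLEED"): 0.45,
        (CARMUSTINE, "VTE"): 1.4, (CARMUSTINE, "CNS_BLEED"): 1.75,
        (CARMUSTINE, "GI_BLEED"): 1.0,
    }


def _default_missingness() -> dict[str, float]:
    # patterned on the bevacizumab column of the baseline table
    return {"sex": 0.40, "age": 0.45, "weight": 0.71, "reporter": 0.10}


@dataclass
class SyntheticConfig:
    """Full generative specification of one simulated database."""

    database: str = "FAERS"
    n_reports: int = 20_000
    seed: int = 0
    glioma_fraction: float = 0.80
    strict_fraction_within_glioma: float = 0.60
    drug_marginals: dict[str, float] = field(
        default_factory=_default_drug_marginals)
    coprescription_odds: dict[tuple[str, str], float] = field(
        default_factory=_default_coprescription)
    role_distribution: tuple[float, float, float] = (0.5, 0.2, 0.3)
    baseline_event_probs: dict[str, float] = field(
        default_factory=_default_baseline)
    effect_matrix: dict[tuple[str, str], float] = field(
        default_factory=_default_effects)
    background_pt_pool: tuple[tuple[str, float], ...] = DEFAULT_BACKGROUND_PTS
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    duplicate_prob: float = 0.05
    serious_prob: float = 0.18

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ConfigError("n_reports must be >= 1")
        probs = ([self.glioma_fraction, self.strict_fraction_within_glioma,
                  self.duplicate_prob, self.serious_prob]
                 + list(self.drug_marginals.values())
                 + list(self.baseline_event_probs.values())
                 + list(self.missingness.values())
                 + list(self.role_distribution))
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if abs(sum(self.role_distribution) - 1.0) > 1e-9:
            raise ConfigError("role_distribution must sum to 1")
        if any(m <= 0 for m in self.effect_matrix.values()):
            raise ConfigError("effect multipliers must be positive")
        if any(o <= 0 for o in self.coprescription_odds.values()):
            raise ConfigError("co-prescription odds must be positive")
        self.drug_marginals = {k.upper(): v
                               for k, v in self.drug_marginals.items()}
        self.effect_matrix = {(d.upper(), e.upper()): v
                              for (d, e), v in self.effect_matrix.items()}
        self.coprescription_odds = {
            (min(x.upper(), y.upper()), max(x.upper(), y.upper())): v
            for (x, y), v in self.coprescription_odds.items()}

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.drug_marginals)

    @property
    def endpoints(self) -> tuple[str, ...]:
        return tuple(self.baseline_event_probs)

    def null_effects(self) -> "SyntheticConfig":
        """Copy of the config with every drug--event multiplier at 1."""
        return replace(self, effect_matrix={k: 1.0
                                            for k in self.effect_matrix})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "coprescription_odds" in raw:
            raw["coprescription_odds"] = {
                tuple(k.split("+")): float(v)
                for k, v in raw["coprescription_odds"].items()}
        if "effect_matrix" in raw:
            raw["effect_matrix"] = {
                tuple(k.split("+")): float(v)
                for k, v in raw["effect_matrix"].items()}
        if "background_pt_pool" in raw:
            raw["background_pt_pool"] = tuple(
                (str(pt), float(w)) for pt, w in raw["background_pt_pool"])
        if "role_distribution" in raw:
            raw["role_distribution"] = tuple(raw["role_distribution"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# probabilistic core
# ---------------------------------------------------------------------------

def _pattern_distribution(config: SyntheticConfig
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Exact joint distribution over drug-exposure patterns: independent
    marginals tilted by pairwise co-prescription odds, renormalized."""
    drugs = config.drugs
    k = len(drugs)
    patterns = np.array(list(itertools.product((0, 1), repeat=k)), dtype=int)
    p = np.array([config.drug_marginals[d] for d in drugs])
    logw = (patterns * np.log(np.clip(p, 1e-12, 1))
            + (1 - patterns) * np.log(np.clip(1 - p, 1e-12, 1))).sum(axis=1)
    for (x, y), odds in config.coprescription_odds.items():
        if x in drugs and y in drugs:
            i, j = drugs.index(x), drugs.index(y)
            logw = logw + patterns[:, i] * patterns[:, j] * np.log(odds)
    w = np.exp(logw - logw.max())
    return patterns, w / w.sum()


def _event_probs(config: SyntheticConfig, patterns: np.ndarray) -> np.ndarray:
    """p(event | exposure pattern) for each endpoint (patterns x events)."""
    drugs = config.drugs
    out = np.empty((len(patterns), len(config.endpoints)))
    for j, ep in enumerate(config.endpoints):
        base = config.baseline_event_probs[ep]
        logit = np.log(base / (1 - base)) + sum(
            patterns[:, i] * np.log(config.effect_matrix.get((d, ep), 1.0))
            for i, d in enumerate(drugs))
        out[:, j] = 1.0 / (1.0 + np.exp(-logit))
    return out


def true_odds_ratio(config: SyntheticConfig, drug: str,
                    endpoint: str) -> float:
    """Closed-form population odds ratio for one drug--endpoint pair,
    marginalizing the co-prescription mixture by exact enumeration.

    This is the estimand of the 2x2 reporting odds ratio: the odds of
    the event among reports mentioning the drug over the odds among
    reports not mentioning it, including any confounding contributed by
    co-prescribed drugs with their own effects.
    """
    drug = drug.upper()
    endpoint = endpoint.upper()
    drugs = config.drugs
    if drug not in drugs:
        raise ConfigError(f"unknown drug {drug!r}")
    if endpoint not in config.endpoints:
        raise ConfigError(f"unknown endpoint {endpoint!r}")
    patterns, pi = _pattern_distribution(config)
    pe = _event_probs(config, patterns)[:, config.endpoints.index(endpoint)]
    mask = patterns[:, drugs.index(drug)] == 1
    p1 = float((pi[mask] * pe[mask]).sum() / pi[mask].sum())
    p0 = float((pi[~mask] * pe[~mask]).sum() / pi[~mask].sum())
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


def _draw_arrays(config: SyntheticConfig, rng: np.random.Generator,
                 n: int) -> dict[str, np.ndarray]:
    patterns, pi = _pattern_distribution(config)
    idx = rng.choice(len(patterns), size=n, p=pi)
    exposure = patterns[idx]                       # n x K
    pe = _event_probs(config, patterns)[idx]       # n x E
    events = rng.random(pe.shape) < pe
    glioma = rng.random(n) < config.glioma_fraction
    strict = rng.random(n) < config.strict_fraction_within_glioma
    roles = rng.choice(3, size=exposure.shape,
                       p=list(config.role_distribution))  # 0=PS 1=SS 2=C
    return {"exposure": exposure, "events": events, "glioma": glioma,
            "strict": strict, "roles": roles}


def simulate_tables(config: SyntheticConfig,
                    rng: np.random.Generator | None = None,
                    role_filter: str = "ANY"
                    ) -> dict[tuple[str, str], ContingencyTable]:
    """Draw one database and return the glioma-cohort 2x2 table for
    every configured drug--endpoint pair, straight from the underlying
    arrays (no report objects; duplicates play no role post-dedup)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    arr = _draw_arrays(config, rng, config.n_reports)
    cohort = arr["glioma"]
    exposure = arr["exposure"][cohort]
    events = arr["events"][cohort]
    if role_filter == "PS_ONLY":
        exposure = exposure * (arr["roles"][cohort] == 0)
    out = {}
    for i, drug in enumerate(config.drugs):
        exp = exposure[:, i] == 1
        for j, ep in enumerate(config.endpoints):
            ev = events[:, j]
            out[(drug, ep)] = ContingencyTable(
                int((exp & ev).sum()), int((exp & ~ev).sum()),
                int((~exp & ev).sum()), int((~exp & ~ev).sum()))
    return out


def simulate_regimen_tables(config: SyntheticConfig,
                            rng: np.random.Generator | None = None
                            ) -> dict[tuple[RegimenLabel, str],
                                      ContingencyTable]:
    """Array-path regimen analysis: focal bevacizumab regimen vs all
    other bevacizumab-containing regimens, within the glioma cohort."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    arr = _draw_arrays(config, rng, config.n_reports)
    drugs = config.drugs
    cohort = arr["glioma"]
    x = arr["exposure"][cohort]
    events = arr["events"][cohort]
    bev = x[:, drugs.index(BEVACIZUMAB)] == 1
    tmz = x[:, drugs.index(TEMOZOLOMIDE)] == 1 if TEMOZOLOMIDE in drugs else np.zeros(len(x), bool)
    lom = x[:, drugs.index(LOMUSTINE)] == 1 if LOMUSTINE in drugs else np.zeros(len(x), bool)
    labels = {
        RegimenLabel.BEV_MONO: bev & ~tmz & ~lom,
        RegimenLabel.BEV_TMZ: bev & tmz & ~lom,
        RegimenLabel.BEV_LOM: bev & lom & ~tmz,
    }
    out = {}
    for focal, mask in labels.items():
        other = bev & ~mask
        for j, ep in enumerate(config.endpoints):
            ev = events[:, j]
            out[(focal, ep)] = ContingencyTable(
                int((mask & ev).sum()), int((mask & ~ev).sum()),
                int((other & ev).sum()), int((other & ~ev).sum()))
    return out


# ---------------------------------------------------------------------------
# report materialization
# ---------------------------------------------------------------------------

_SEXES = np.array(["M", "F"])
_AGES = np.array(["12-17", "18-64", "65-85"])
_WEIGHTS = np.array(["LT50", "50TO100", "GT100"])


def generate(config: SyntheticConfig) -> ReportSet:
    """Materialize the configured database as a pre-deduplication
    ReportSet: duplicated cases appear as near-copies with a higher
    version and one perturbed demographic field, directly after their
    originals."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    arr = _draw_arrays(config, rng, n)
    drugs = config.drugs
    endpoints = config.endpoints
    endpoint_defs = load_endpoints()
    ep_pts = {name: sorted(endpoint_defs[name].pts)
              for name in endpoints if name in endpoint_defs}

    sex = _SEXES[rng.choice(2, n, p=[0.65, 0.35])]
    sex[rng.random(n) < config.missingness["sex"]] = "UNK"
    age = _AGES[rng.choice(3, n, p=[0.02, 0.70, 0.28])]
    age[rng.random(n) < config.missingness["age"]] = "UNK"
    weight = _WEIGHTS[rng.choice(3, n, p=[0.07, 0.82, 0.11])]
    weight[rng.random(n) < config.missingness["weight"]] = "UNK"
    reporter = np.where(rng.random(n) < 0.65, "HCP", "NONHCP").astype(object)
    reporter[rng.random(n) < config.missingness["reporter"]] = "UNK"
    serious = np.where(rng.random(n) < config.serious_prob, "YES", "NO")
    dup = rng.random(n) < config.duplicate_prob

    pt_names = [pt for pt, _ in config.background_pt_pool]
    pt_w = np.array([w for _, w in config.background_pt_pool], float)
    pt_w = pt_w / pt_w.sum()
    n_bg = rng.integers(1, 5, size=n)
    use_brand = rng.random((n, len(drugs))) < 0.30
    strict_term_idx = rng.integers(0, len(_GLIOMA_STRICT), size=n)
    broad_term_idx = rng.integers(0, len(_GLIOMA_BROAD_ONLY), size=n)
    other_idx = rng.integers(0, len(_OTHER_INDICATIONS), size=n)
    n_bg_drugs = rng.integers(1, 3, size=n)

    role_codes = np.array(["PS", "SS", "C"])
    reports: list[Report] = []
    for i in range(n):
        entries: list[DrugEntry] = []
        for k, drug in enumerate(drugs):
            if arr["exposure"][i, k]:
                verbatim = (_BRAND_VERBATIM.get(drug, drug.title())
                            if use_brand[i, k] else drug.title())
                entries.append(DrugEntry(verbatim, drug,
                                         role_codes[arr["roles"][i, k]]))
        for b in range(n_bg_drugs[i]):
            name = _BACKGROUND_DRUGS[(i + b) % len(_BACKGROUND_DRUGS)]
            entries.append(DrugEntry(name.title(), name, "C"))

        reactions: list[str] = []
        for j, ep in enumerate(endpoints):
            if arr["events"][i, j] and ep in ep_pts:
                pts = ep_pts[ep]
                reactions.append(pts[rng.integers(0, len(pts))])
        bg = rng.choice(len(pt_names), size=n_bg[i], replace=False, p=pt_w)
        reactions.extend(pt_names[k] for k in bg)

        if arr["glioma"][i]:
            indication = (_GLIOMA_STRICT[strict_term_idx[i]]
                          if arr["strict"][i]
                          else _GLIOMA_BROAD_ONLY[broad_term_idx[i]])
        else:
            indication = _OTHER_INDICATIONS[other_idx[i]]

        report = Report(
            database=config.database, report_id=f"{config.database}-{i:07d}",
            version=1, sex=str(sex[i]), age_group=str(age[i]),
            weight_band=str(weight[i]), reporter=str(reporter[i]),
            serious=str(serious[i]), drugs=entries, reactions=reactions,
            indications=[indication],
        )
        reports.append(report)
        if dup[i]:
            perturbed = replace(report, version=2,
                                sex="UNK" if report.sex != "UNK" else "F")
            reports.append(perturbed)
    return ReportSet(config.database, reports)


# ---------------------------------------------------------------------------
# FAERS-style ASCII writer
# ---------------------------------------------------------------------------

_AGE_REP = {"12-17": "15", "18-64": "40", "65-85": "70", "UNK": ""}
_WT_REP = {"LT50": "45", "50TO100": "75", "GT100": "110", "UNK": ""}
_OCC_REP = {"HCP": "MD", "NONHCP": "CN", "UNK": ""}


def write_faers_ascii(report_set: ReportSet, out_dir: str | Path
                      ) -> dict[str, Path]:
    """Emit '$'-delimited DEMO/DRUG/REAC/INDI files readable by
    :func:`pvsignal.icsr_store.read_faers_ascii`; lossless for in-band
    fields (band-valued ages and weights are written as representative
    in-band numbers)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    demo = ["caseid$caseversion$sex$age$wt$occp_cod$serious"]
    drug = ["caseid$caseversion$drug_seq$drugname$prod_ai$role_cod"]
    reac = ["caseid$caseversion$pt"]
    indi = ["caseid$caseversion$indi_pt"]
    for r in report_set:
        sex = "" if r.sex == "UNK" else r.sex
        serious = "" if r.serious == "UNK" else r.serious
        demo.append(f"{r.report_id}${r.version}${sex}${_AGE_REP[r.age_group]}"
                    f"${_WT_REP[r.weight_band]}${_OCC_REP[r.reporter]}"
                    f"${serious}")
        for seq, d in enumerate(r.drugs, start=1):
            drug.append(f"{r.report_id}${r.version}${seq}${d.verbatim_name}"
                        f"${d.generic_name}${d.role}")
        for pt in r.reactions:
            reac.append(f"{r.report_id}${r.version}${pt}")
        for ind in r.indications:
            indi.append(f"{r.report_id}${r.version}${ind}")
    paths = {}
    for name, lines in [("DEMO", demo), ("DRUG", drug), ("REAC", reac),
                        ("INDI", indi)]:
        path = out_dir / f"{name}.txt"
        path.write_text("\n".join(lines) + "\n")
        paths[name] = path
    return paths
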
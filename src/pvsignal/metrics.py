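"""2x2 contingency construction and disproportionality statistics.

For a drug--event pair in a deduplicated report set the table cells are
report counts: a = exposed with the event, b = exposed without it,
c = unexposed with the event, d = unexposed without it.  Four measures
are computed per pair:

* reporting odds ratio ROR = (a*d)/(b*c) with a Woolf (log-normal) 95%
  confidence interval;
* proportional reporting ratio PRR = [a/(a+b)]/[c/(c+d)] with its
  log-normal interval and the Pearson chi-square statistic;
* Bayesian confidence propagation information component
  IC = log2((a+0.5)/(E+0.5)) with a closed-form lower credibility bound
  IC025, where E = (a+b)(a+c)/N is the expected count under
  independence;
* the empirical-Bayes geometric mean EBGM and its 5th posterior
  percentile EB05 under a two-component gamma-Poisson shrinkage prior
  fitted by marginal maximum likelihood across all pairs of an analysis.

A pair is flagged a positive signal when a >= 3 and the ROR interval's
lower bound exceeds 1.  Tables containing a zero cell receive the
Haldane-Anscombe +0.5 correction (all four cells) for the ratio
estimates and are flagged.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import ExposureDefinition, RegimenLabel, assign_regimen, is_exposed
from .endpoints import EndpointDefinition, has_endpoint
from .icsr_store import ReportSet

#: two-sided 95% normal quantile
Z95 = 1.959964


class EmptyCohortError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the best parameters found."""

    def __init__(self, message: str, best: "GammaMixturePrior"):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be nonnegative")
        if self.n == 0:
            raise ValueError("table must contain at least one report")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count in cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane-Anscombe half-count correction of all four cells."""
        return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class GammaMixturePrior:
    """Hyperparameters of the two-component gamma mixture prior on the
    relative reporting rate lambda (shape/rate pairs and mixture
    weight)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    low_information: bool = False

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("shape/rate hyperparameters must be positive")
        if not 0 < self.w < 1:
            raise ValueError("mixture weight must be in (0, 1)")

    @property
    def mixture_mean(self) -> float:
        return (self.w * self.alpha1 / self.beta1
                + (1 - self.w) * self.alpha2 / self.beta2)


#: conventional gamma-Poisson shrinker starting point
DEFAULT_PRIOR_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass
class DisproportionalityResult:
    """All statistics for one drug (or regimen) x endpoint pair."""

    database: str
    drug_or_regimen: str
    event: str
    table: ContingencyTable
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    prr_low: float
    prr_high: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    eb05: float
    signal: bool
    analyzable: bool
    zero_cell_corrected: bool
    variant: str = "MAIN"


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_contingency(cohort: ReportSet, exposure: ExposureDefinition,
                      endpoint: EndpointDefinition) -> ContingencyTable:
    """Cross-classify a deduplicated cohort by exposure and endpoint."""
    if len(cohort) == 0:
        raise EmptyCohortError("empty cohort")
    a = b = c = d = 0
    for report in cohort:
        exposed = is_exposed(report, exposure)
        event = has_endpoint(report, endpoint)
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def build_regimen_contingency(bev_reports: ReportSet, focal: RegimenLabel,
                              endpoint: EndpointDefinition) -> ContingencyTable:
    """Contrast one focal bevacizumab regimen against all other
    bevacizumab-containing regimens (including triple combinations).

    ``bev_reports`` must already be restricted to bevacizumab-exposed
    reports.  Cells are computed identically for every focal group; the
    monotherapy group is a reference for presentation only.
    """
    if focal == RegimenLabel.NOT_BEV:
        raise ValueError("focal regimen must be a bevacizumab-containing group")
    if len(bev_reports) == 0:
        raise EmptyCohortError("empty cohort")
    a = b = c = d = 0
    for report in bev_reports:
        label = assign_regimen(report)
        if label == RegimenLabel.NOT_BEV:
            raise ValueError(
                "bev_reports contains a report without bevacizumab")
        event = has_endpoint(report, endpoint)
        if label == focal:
            if event:
                a += 1
            else:
                b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# frequentist measures
# ---------------------------------------------------------------------------

def ror_with_ci(table: ContingencyTable,
                level: float = 0.95) -> tuple[float, float, float, bool]:
    """Reporting odds ratio with a Woolf log-normal confidence interval.

    Returns (ror, low, high, corrected) where ``corrected`` records the
    Haldane-Anscombe +0.5 adjustment applied when any cell is zero.
    """
    corrected = table.has_zero_cell()
    a, b, c, d = table.corrected() if corrected else (
        float(table.a), float(table.b), float(table.c), float(table.d))
    z = stats.norm.ppf(0.5 + level / 2) if level != 0.95 else Z95
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se), corrected


def prr_with_chi2(table: ContingencyTable) -> tuple[float, float, float, float]:
    """Proportional reporting ratio with 95% CI and the Pearson
    chi-square statistic (no continuity correction).

    The chi-square is computed on the raw table whenever its margins
    allow; ratio estimates use the Haldane-Anscombe correction when a
    cell is zero.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("undefined proportion")
    corrected = table.has_zero_cell()
    a, b, c, d = table.corrected() if corrected else (
        float(table.a), float(table.b), float(table.c), float(table.d))
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    low, high = prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se)

    ra, rb, rc, rd = (float(table.a), float(table.b), float(table.c),
                      float(table.d))
    n = ra + rb + rc + rd
    den = (ra + rb) * (rc + rd) * (ra + rc) * (rb + rd)
    if den == 0:  # a zero margin: fall back to the corrected cells
        ra, rb, rc, rd = table.corrected()
        n = ra + rb + rc + rd
        den = (ra + rb) * (rc + rd) * (ra + rc) * (rb + rd)
    chi2 = n * (ra * rd - rb * rc) ** 2 / den
    return prr, low, high, chi2


def bcpnn_ic(table: ContingencyTable) -> tuple[float, float]:
    """Information component and its closed-form 95% lower credibility
    bound (shrunk observed-over-expected on the base-2 log scale)."""
    e = table.expected
    shrunk = (table.a + 0.5) / (e + 0.5)
    ic = math.log2(shrunk)
    ic025 = (ic - 3.3 * (table.a + 0.5) ** -0.5
             - 2.0 * (table.a + 0.5) ** -1.5)
    return ic, ic025


def classify_signal(a: int, ror_low: float) -> bool:
    """Positive signal rule: a >= 3 and ROR 95% CI lower bound > 1."""
    return a >= 3 and ror_low > 1.0


# ---------------------------------------------------------------------------
# empirical-Bayes gamma-Poisson shrinkage
# ---------------------------------------------------------------------------

def _mixture_logpmf(a: np.ndarray, e: np.ndarray, alpha1, beta1, alpha2,
                    beta2, w) -> np.ndarray:
    """Marginal log-likelihood of observed counts under the mixture of
    negative binomials induced by the gamma prior and Poisson sampling."""
    def nb_logpmf(alpha, beta):
        p = beta / (beta + e)
        return (special.gammaln(alpha + a) - special.gammaln(alpha)
                - special.gammaln(a + 1) + alpha * np.log(p)
                + a * np.log1p(-p))

    l1 = np.log(w) + nb_logpmf(alpha1, beta1)
    l2 = np.log1p(-w) + nb_logpmf(alpha2, beta2)
    return np.logaddexp(l1, l2)


def fit_gamma_mixture_prior(pairs: Sequence[tuple[int, float]],
                            start: tuple[float, ...] = DEFAULT_PRIOR_START,
                            maxiter: int = 500) -> GammaMixturePrior:
    """Fit the five shrinkage hyperparameters by marginal maximum
    likelihood over all (observed count, expected count) pairs.

    Deterministic given inputs: bounded L-BFGS-B on log/logit-transformed
    parameters from the conventional start.
    """
    if len(pairs) < 10:
        raise ValueError("need >= 10 (a, E) pairs to fit the prior")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    e = np.asarray([p[1] for p in pairs], dtype=float)
    if np.unique(a).size < 2:
        raise ValueError("need >= 2 distinct observed counts")
    if (e <= 0).any():
        raise ValueError("expected counts must be positive")

    def unpack(theta):
        a1, b1, a2, b2 = np.exp(theta[:4])
        w = 1.0 / (1.0 + np.exp(-theta[4]))
        return a1, b1, a2, b2, w

    def nll(theta):
        a1, b1, a2, b2, w = unpack(theta)
        return -float(np.sum(_mixture_logpmf(a, e, a1, b1, a2, b2, w)))

    s = start
    theta0 = np.array([math.log(s[0]), math.log(s[1]), math.log(s[2]),
                       math.log(s[3]), math.log(s[4] / (1 - s[4]))])
    bounds = [(-7.0, 7.0)] * 4 + [(-7.0, 7.0)]
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter})
    a1, b1, a2, b2, w = unpack(res.x)
    prior = GammaMixturePrior(a1, b1, a2, b2, w)
    if not res.success and "MAXLS" not in str(res.message):
        raise ConvergenceError(
            f"prior fit did not converge: {res.message}", prior)
    return prior


def default_prior(low_information: bool = True) -> GammaMixturePrior:
    """The conventional starting prior, used unfitted when an analysis
    has too few pairs for a stable marginal-likelihood fit."""
    a1, b1, a2, b2, w = DEFAULT_PRIOR_START
    return GammaMixturePrior(a1, b1, a2, b2, w,
                             low_information=low_information)


def ebgm_eb05(a: int, e: float,
              prior: GammaMixturePrior) -> tuple[float, float]:
    """Posterior geometric mean of the relative reporting rate and its
    5th percentile under the fitted gamma-mixture prior.

    The posterior is Q * Gamma(alpha1+a, beta1+E) + (1-Q) *
    Gamma(alpha2+a, beta2+E); the geometric mean uses digamma moments and
    the percentile monotone root-finding on the mixture CDF.
    """
    if e <= 0:
        raise ValueError("expected count must be positive")
    av = np.asarray([float(a)])
    ev = np.asarray([float(e)])

    def nb_ll(alpha, beta):
        return float(_mixture_logpmf(av, ev, alpha, beta, alpha, beta, 0.5)[0])

    l1 = math.log(prior.w) + nb_ll(prior.alpha1, prior.beta1)
    l2 = math.log1p(-prior.w) + nb_ll(prior.alpha2, prior.beta2)
    m = max(l1, l2)
    q1 = math.exp(l1 - m) / (math.exp(l1 - m) + math.exp(l2 - m))
    s1, r1 = prior.alpha1 + a, prior.beta1 + e
    s2, r2 = prior.alpha2 + a, prior.beta2 + e

    mean_log = (q1 * (special.digamma(s1) - math.log(r1))
                + (1 - q1) * (special.digamma(s2) - math.log(r2)))
    ebgm = math.exp(mean_log)

    g1 = stats.gamma(a=s1, scale=1.0 / r1)
    g2 = stats.gamma(a=s2, scale=1.0 / r2)

    def cdf(x):
        return q1 * g1.cdf(x) + (1 - q1) * g2.cdf(x)

    lo = min(g1.ppf(1e-12), g2.ppf(1e-12))
    hi = max(g1.ppf(1 - 1e-12), g2.ppf(1 - 1e-12))
    lo = max(lo, 1e-300)
    eb05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12,
                           rtol=1e-12)
    return ebgm, eb05


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def result_from_table(table: ContingencyTable, database: str, name: str,
                      event: str, prior: GammaMixturePrior,
                      variant: str = "MAIN") -> DisproportionalityResult:
    """Compute every statistic for one pre-built table.

    A table with an empty exposure (or comparator) margin — a drug with
    no reports in the cohort — is computed on the Haldane-corrected
    cells throughout and is never analyzable.
    """
    ror, rlow, rhigh, corrected = ror_with_ci(table)
    try:
        prr, plow, phigh, chi2 = prr_with_chi2(table)
    except ValueError:  # zero margin: fall back to corrected cells
        a, b, c, d = table.corrected()
        prr = (a / (a + b)) / (c / (c + d))
        se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        plow, phigh = prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se)
        n = a + b + c + d
        chi2 = (n * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d)))
    ic, ic025 = bcpnn_ic(table)
    ebgm, eb05 = ebgm_eb05(table.a, max(table.expected, 1e-12), prior)
    analyzable = table.a >= 3
    signal = analyzable and classify_signal(table.a, rlow)
    return DisproportionalityResult(
        database=database, drug_or_regimen=name, event=event, table=table,
        ror=ror, ror_low=rlow, ror_high=rhigh, prr=prr, prr_low=plow,
        prr_high=phigh, chi2=chi2, ic=ic, ic025=ic025, ebgm=ebgm,
        eb05=eb05, signal=signal, analyzable=analyzable,
        zero_cell_corrected=corrected, variant=variant,
    )


def analyze_pair(cohort: ReportSet, exposure: ExposureDefinition,
                 endpoint: EndpointDefinition,
                 prior: GammaMixturePrior | None = None,
                 name: str | None = None,
                 variant: str = "MAIN") -> DisproportionalityResult:
    """Build the 2x2 table for one drug--endpoint pair and assemble all
    statistics.  Pairs with a < 3 are flagged not analyzable (their
    counts are still reported) and never classified as signals."""
    table = build_contingency(cohort, exposure, endpoint)
    if prior is None:
        prior = default_prior()
    label = name or "+".join(exposure.generic_names)
    return result_from_table(table, cohort.database, label, endpoint.name,
                             prior, variant)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_EXPORT_COLS = ["database", "drug_or_regimen", "event", "a", "b", "c", "d",
                "ror", "ror_low", "ror_high", "signal", "prr", "prr_low",
                "prr_high", "chi2", "ic", "ic025", "ebgm", "eb05",
                "analyzable", "zero_cell_corrected", "variant"]


def results_to_frame(results: Iterable[DisproportionalityResult],
                     digits: int = 2,
                     suppress_nonanalyzable: bool = True) -> pd.DataFrame:
    """Tabulate results, rounding to the reporting precision; metric
    columns of non-analyzable pairs are masked (counts are kept)."""
    rows = []
    for r in results:
        row = {
            "database": r.database, "drug_or_regimen": r.drug_or_regimen,
            "event": r.event, "a": r.table.a, "b": r.table.b,
            "c": r.table.c, "d": r.table.d,
            "ror": round(r.ror, digits), "ror_low": round(r.ror_low, digits),
            "ror_high": round(r.ror_high, digits), "signal": r.signal,
            "prr": round(r.prr, digits), "prr_low": round(r.prr_low, digits),
            "prr_high": round(r.prr_high, digits),
            "chi2": round(r.chi2, digits), "ic": round(r.ic, digits),
            "ic025": round(r.ic025, digits), "ebgm": round(r.ebgm, digits),
            "eb05": round(r.eb05, digits), "analyzable": r.analyzable,
            "zero_cell_corrected": r.zero_cell_corrected,
            "variant": r.variant,
        }
        if suppress_nonanalyzable and not r.analyzable:
            for col in ("ror", "ror_low", "ror_high", "prr", "prr_low",
                        "prr_high", "chi2", "ic", "ic025", "ebgm", "eb05"):
                row[col] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows, columns=_EXPORT_COLS)


def results_to_csv(results: Iterable[DisproportionalityResult],
                   path: str | Path, **kwargs) -> None:
    results_to_frame(results, **kwargs).to_csv(path, index=False)


def results_to_json(results: Iterable[DisproportionalityResult],
                    path: str | Path | None = None) -> str:
    payload = []
    for r in results:
        entry = {c: getattr(r, c) for c in
                 ("database", "drug_or_regimen", "event", "ror", "ror_low",
                  "ror_high", "prr", "prr_low", "prr_high", "chi2", "ic",
                  "ic025", "ebgm", "eb05", "signal", "analyzable",
                  "zero_cell_corrected", "variant")}
        entry.update({"a": r.table.a, "b": r.table.b, "c": r.table.c,
                      "d": r.table.d})
        payload.append(entry)
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
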
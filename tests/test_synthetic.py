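import numpy as np
import pytest

from pvsignal.cohort import BEVACIZUMAB, LOMUSTINE, TEMOZOLOMIDE
from pvsignal.icsr_store import ReportSet, deduplicate, read_faers_ascii
from pvsignal.metrics import ror_with_ci
from pvsignal.synthetic import (ConfigError, SyntheticConfig, generate,
                                simulate_tables, true_odds_ratio,
                                write_faers_ascii)

from conftest import make_report


def test_generate_deterministic():
    cfg = SyntheticConfig(n_reports=150, seed=42)
    assert generate(cfg).reports == generate(cfg).reports


def test_different_seeds_differ():
    a = generate(SyntheticConfig(n_reports=150, seed=1))
    b = generate(SyntheticConfig(n_reports=150, seed=2))
    assert a.reports != b.reports


def test_duplicate_bookkeeping():
    cfg = SyntheticConfig(n_reports=1000, seed=7, duplicate_prob=0.1)
    rs = generate(cfg)
    dup_ids = {r.report_id for r in rs if r.version > 1}
    assert len(rs) == cfg.n_reports + len(dup_ids)
    deduped = deduplicate(rs)
    assert len(deduped) == cfg.n_reports
    # the kept record for a duplicated id is the perturbed later version
    kept = {r.report_id: r for r in deduped}
    assert all(kept[i].version == 2 for i in dup_ids)


def test_config_validation():
    with pytest.raises(ConfigError):
        SyntheticConfig(n_reports=0)
    with pytest.raises(ConfigError):
        SyntheticConfig(glioma_fraction=1.5)
    with pytest.raises(ConfigError):
        SyntheticConfig(effect_matrix={("BEVACIZUMAB", "VTE"): 0.0})
    with pytest.raises(ConfigError):
        SyntheticConfig(role_distribution=(0.5, 0.5, 0.5))


# ---------------------------------------------------------------------------
# closed-form estimand
# ---------------------------------------------------------------------------

def test_true_or_single_drug_identity():
    cfg = SyntheticConfig(
        drug_marginals={"BEVACIZUMAB": 0.3},
        coprescription_odds={},
        effect_matrix={("BEVACIZUMAB", "VTE"): 2.3},
        baseline_event_probs={"VTE": 0.05},
    )
    assert true_odds_ratio(cfg, "BEVACIZUMAB", "VTE") == pytest.approx(2.3)


def test_true_or_null_everywhere():
    cfg = SyntheticConfig().null_effects()
    for drug in cfg.drugs:
        for ep in cfg.endpoints:
            assert true_odds_ratio(cfg, drug, ep) == pytest.approx(1.0)


def test_true_or_coprescription_confounding():
    """Two strongly co-prescribed drugs, each doubling the event odds:
    either drug's marginal odds ratio exceeds its own direct effect."""
    cfg = SyntheticConfig(
        drug_marginals={"A": 0.2, "B": 0.2},
        coprescription_odds={("A", "B"): 5.0},
        effect_matrix={("A", "VTE"): 2.0, ("B", "VTE"): 2.0},
        baseline_event_probs={"VTE": 0.05},
    )
    marginal = true_odds_ratio(cfg, "A", "VTE")
    assert marginal > 2.0

    # independent oracle: exact enumeration over the four patterns
    import itertools
    p, odds_ab, base, m = 0.2, 5.0, 0.05, 2.0
    weights, p_event, exposed = [], [], []
    for xa, xb in itertools.product((0, 1), repeat=2):
        w = (p if xa else 1 - p) * (p if xb else 1 - p)
        w *= odds_ab if (xa and xb) else 1.0
        odds = base / (1 - base) * (m ** xa) * (m ** xb)
        weights.append(w)
        p_event.append(odds / (1 + odds))
        exposed.append(xa)
    weights = np.array(weights) / sum(weights)
    p_event = np.array(p_event)
    exposed = np.array(exposed, bool)
    p1 = (weights[exposed] * p_event[exposed]).sum() / weights[exposed].sum()
    p0 = (weights[~exposed] * p_event[~exposed]).sum() / weights[~exposed].sum()
    oracle = (p1 / (1 - p1)) / (p0 / (1 - p0))
    assert marginal == pytest.approx(oracle, rel=1e-12)


def test_estimated_ror_recovers_configured_effect():
    """Over replicates at large n the cohort ROR estimate lands on the
    closed-form population odds ratio and the CI covers it."""
    cfg = SyntheticConfig(n_reports=200_000)
    truth = true_odds_ratio(cfg, BEVACIZUMAB, "VTE")
    rng = np.random.default_rng(17)
    rors, covered = [], 0
    for _ in range(10):
        ror, low, high, _ = ror_with_ci(
            simulate_tables(cfg, rng)[(BEVACIZUMAB, "VTE")])
        rors.append(ror)
        covered += low < truth < high
    assert 2.1 < np.mean(rors) < 2.5
    assert covered >= 8


def test_null_simulation_ror_near_one():
    """With every multiplier at 1 the point estimates of well-populated
    pairs sit near the null and at most a sampling handful of the 12
    intervals exclude it."""
    cfg = SyntheticConfig(n_reports=200_000, seed=23).null_effects()
    tabs = simulate_tables(cfg)
    excluding = 0
    for (drug, ep), t in tabs.items():
        ror, low, high, _ = ror_with_ci(t)
        if t.a >= 1000:
            assert 0.9 < ror < 1.1, (drug, ep, ror)
        excluding += (low > 1.0) or (high < 1.0)
    assert excluding <= 2


def test_monotone_in_configured_multiplier():
    base = SyntheticConfig(n_reports=100_000)
    rors = []
    for mult in (0.5, 1.0, 2.0, 4.0):
        cfg = SyntheticConfig(
            n_reports=base.n_reports, seed=31,
            effect_matrix={**base.effect_matrix,
                           (BEVACIZUMAB, "VTE"): mult})
        ror, *_ = ror_with_ci(simulate_tables(cfg)[(BEVACIZUMAB, "VTE")])
        rors.append(ror)
    assert rors == sorted(rors)


# ---------------------------------------------------------------------------
# object path vs array path
# ---------------------------------------------------------------------------

def test_array_path_matches_report_objects(cohort_defs, endpoints):
    """The fast array surface and the materialized-report surface are
    the same draw: identical 2x2 tables for every pair."""
    from pvsignal.cohort import ExposureDefinition, filter_cohort
    from pvsignal.metrics import build_contingency
    cfg = SyntheticConfig(n_reports=4000, seed=99)
    tabs = simulate_tables(cfg)
    rs = deduplicate(generate(cfg))
    cohort = filter_cohort(rs, cohort_defs["broad"])
    for drug in cfg.drugs:
        for ep_name in cfg.endpoints:
            t_obj = build_contingency(cohort, ExposureDefinition((drug,)),
                                      endpoints[ep_name])
            t_arr = tabs[(drug, ep_name)]
            assert (t_obj.a, t_obj.b, t_obj.c, t_obj.d) == \
                (t_arr.a, t_arr.b, t_arr.c, t_arr.d), (drug, ep_name)


def test_demographic_missingness_calibrated():
    cfg = SyntheticConfig(n_reports=10_000, seed=3)
    rs = generate(cfg)
    n = len(rs)
    for field_name, cfg_key in [("sex", "sex"), ("age_group", "age"),
                                ("weight_band", "weight"),
                                ("reporter", "reporter")]:
        frac = sum(1 for r in rs if getattr(r, field_name) == "UNK") / n
        assert abs(frac - cfg.missingness[cfg_key]) < 0.05, field_name


# ---------------------------------------------------------------------------
# FAERS-style writer
# ---------------------------------------------------------------------------

GOLDEN_DEMO = """caseid$caseversion$sex$age$wt$occp_cod$serious
CASE-1$1$M$40$75$MD$YES
CASE-2$1$$$45$$NO
"""
GOLDEN_DRUG = """caseid$caseversion$drug_seq$drugname$prod_ai$role_cod
CASE-1$1$1$Avastin$BEVACIZUMAB$PS
CASE-1$1$2$Temodar$TEMOZOLOMIDE$C
CASE-2$1$1$Gleostine$LOMUSTINE$SS
"""
GOLDEN_REAC = """caseid$caseversion$pt
CASE-1$1$DEEP VEIN THROMBOSIS
CASE-2$1$HEADACHE
"""
GOLDEN_INDI = """caseid$caseversion$indi_pt
CASE-1$1$Glioblastoma multiforme
CASE-2$1$Glioma
"""


def _two_case_set():
    r1 = make_report("CASE-1", [("BEVACIZUMAB", "PS")],
                     ["DEEP VEIN THROMBOSIS"],
                     ["Glioblastoma multiforme"], sex="M",
                     age_group="18-64", weight_band="50TO100",
                     reporter="HCP", serious="YES")
    r1.drugs[0] = r1.drugs[0].__class__("Avastin", "BEVACIZUMAB", "PS")
    r1.drugs.append(r1.drugs[0].__class__("Temodar", "TEMOZOLOMIDE", "C"))
    r2 = make_report("CASE-2", [("LOMUSTINE", "SS")], ["HEADACHE"],
                     ["Glioma"], weight_band="LT50", serious="NO")
    r2.drugs[0] = r2.drugs[0].__class__("Gleostine", "LOMUSTINE", "SS")
    return ReportSet("FAERS", [r1, r2])


def test_write_faers_ascii_golden(tmp_path):
    paths = write_faers_ascii(_two_case_set(), tmp_path)
    assert paths["DEMO"].read_text() == GOLDEN_DEMO
    assert paths["DRUG"].read_text() == GOLDEN_DRUG
    assert paths["REAC"].read_text() == GOLDEN_REAC
    assert paths["INDI"].read_text() == GOLDEN_INDI


def test_write_faers_ascii_empty_set(tmp_path):
    paths = write_faers_ascii(ReportSet("FAERS", []), tmp_path)
    for path in paths.values():
        lines = path.read_text().splitlines()
        assert len(lines) == 1  # header only


def test_write_read_roundtrip_two_cases(tmp_path):
    original = _two_case_set()
    write_faers_ascii(original, tmp_path)
    back = read_faers_ascii(tmp_path / "DEMO.txt", tmp_path / "DRUG.txt",
                            tmp_path / "REAC.txt", tmp_path / "INDI.txt")
    for orig, rt in zip(original, back):
        for field_name in ("report_id", "version", "sex", "age_group",
                           "weight_band", "reporter", "serious",
                           "reactions", "indications"):
            assert getattr(rt, field_name) == getattr(orig, field_name)
        assert [(d.verbatim_name, d.generic_name, d.role)
                for d in rt.drugs] == \
            [(d.verbatim_name, d.generic_name, d.role) for d in orig.drugs]
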
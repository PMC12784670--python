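import logging

import pytest
from hypothesis import given, settings, strategies as st

from pvsignal.icsr_store import (DrugEntry, FormatError, Report, ReportSet,
                                 bin_age, bin_weight, deduplicate,
                                 map_occupation, map_role, read_faers_ascii,
                                 read_normalized)
from pvsignal.synthetic import SyntheticConfig, generate, write_faers_ascii

from conftest import make_report


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

def test_drug_entry_validation():
    with pytest.raises(ValueError):
        DrugEntry("", "BEVACIZUMAB", "PS")
    with pytest.raises(ValueError):
        DrugEntry("Avastin", "", "PS")
    with pytest.raises(ValueError):
        DrugEntry("Avastin", "BEVACIZUMAB", "PRIMARY")


def test_report_validation_and_coercion():
    r = Report("FAERS", "x", sex="m", age_group="bogus", serious="yes")
    assert (r.sex, r.age_group, r.serious) == ("M", "UNK", "YES")
    with pytest.raises(ValueError):
        Report("FAERS", "")
    with pytest.raises(ValueError):
        Report("FAERS", "x", version=0)
    with pytest.raises(ValueError):
        Report("FAERS", "x", reactions=[""])


@pytest.mark.parametrize("age,band", [
    (None, "UNK"), (5, "UNK"), (12, "12-17"), (17, "12-17"), (18, "18-64"),
    (64, "18-64"), (65, "65-85"), (85, "65-85"), (86, "UNK"),
])
def test_age_binning(age, band):
    assert bin_age(age) == band


@pytest.mark.parametrize("wt,band", [
    (None, "UNK"), (49.9, "LT50"), (50, "50TO100"), (100, "50TO100"),
    (100.5, "GT100"),
])
def test_weight_binning(wt, band):
    assert bin_weight(wt) == band


def test_role_and_occupation_mapping():
    assert map_role("I") == "C"          # interacting -> concomitant
    assert map_role("ps") == "PS"
    assert map_role("") == "C"
    assert map_occupation("MD") == "HCP"
    assert map_occupation("CN") == "NONHCP"
    assert map_occupation("") == "UNK"


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def test_deduplicate_keeps_latest_version():
    rs = ReportSet("FAERS", [
        make_report("X", version=1), make_report("X", version=3),
        make_report("Y", version=1),
    ])
    out = deduplicate(rs)
    assert [(r.report_id, r.version) for r in out] == [("X", 3), ("Y", 1)]


def test_deduplicate_idempotent_on_unique_set():
    rs = ReportSet("FAERS", [make_report("A"), make_report("B")])
    assert deduplicate(rs).reports == rs.reports


def test_deduplicate_version_tie_logs_warning(caplog):
    a = make_report("X", version=2, reactions=["HEADACHE"])
    b = make_report("X", version=2, reactions=["NAUSEA"])
    with caplog.at_level(logging.WARNING, logger="pvsignal.icsr_store"):
        out = deduplicate(ReportSet("FAERS", [a, b]))
    assert len(out) == 1
    assert out.reports[0].reactions == ["NAUSEA"]  # later record kept
    assert any("differing" in m for m in caplog.messages)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.sampled_from("ABCDE"),
                          st.integers(min_value=1, max_value=5)),
                max_size=25))
def test_deduplicate_properties(entries):
    rs = ReportSet("FAERS", [make_report(i, version=v) for i, v in entries])
    once = deduplicate(rs)
    assert len(once) == len({i for i, _ in entries})
    # idempotence
    assert deduplicate(once).reports == once.reports
    # each survivor carries its id's maximal version
    best = {}
    for i, v in entries:
        best[i] = max(best.get(i, 0), v)
    assert {(r.report_id, r.version) for r in once} == set(best.items())


# ---------------------------------------------------------------------------
# normalized TSV reader
# ---------------------------------------------------------------------------

def _write_normalized_fixture(tmp_path, drugs_rows):
    (tmp_path / "reports.tsv").write_text(
        "database\treport_id\tversion\tsex\tage_group\tweight_band\t"
        "reporter\tserious\thistory_text\n"
        "FAERS\tr1\t1\tM\t18-64\tUNK\tHCP\tYES\t\n"
        "FAERS\tr2\t1\tF\tUNK\tLT50\tUNK\tNO\tglioblastoma resected\n"
        "FAERS\tr3\t1\tWEIRD\t65-85\tGT100\tNONHCP\tUNK\t\n")
    (tmp_path / "drugs.tsv").write_text(
        "report_id\tversion\tdrug_seq\tverbatim_name\tgeneric_name\trole\n"
        + drugs_rows)
    (tmp_path / "reactions.tsv").write_text(
        "report_id\tversion\tpt\n"
        "r1\t1\tDEEP VEIN THROMBOSIS\n"
        "r1\t1\tPULMONARY EMBOLISM\n"
        "r2\t1\tHEADACHE\n")
    (tmp_path / "indications.tsv").write_text(
        "report_id\tversion\tindication_text\n"
        "r1\t1\tGlioblastoma\n"
        "r2\t1\tGlioma\n"
        "r3\t1\tAstrocytoma\n")
    return [tmp_path / n for n in
            ("reports.tsv", "drugs.tsv", "reactions.tsv", "indications.tsv")]


def test_read_normalized_join(tmp_path):
    paths = _write_normalized_fixture(
        tmp_path,
        "r1\t1\t1\tAvastin\tBEVACIZUMAB\tPS\n"
        "r1\t1\t2\tTemodar\tTEMOZOLOMIDE\tC\n"
        "r2\t1\t1\tlomustine\tLOMUSTINE\tSS\n"
        "r3\t1\t1\tGliadel\tCARMUSTINE\tI\n")
    rs = read_normalized(*paths)
    assert len(rs) == 3
    assert [len(r.drugs) for r in rs] == [2, 1, 1]
    assert rs.reports[0].reactions == ["DEEP VEIN THROMBOSIS",
                                       "PULMONARY EMBOLISM"]
    assert rs.reports[2].sex == "UNK"          # unknown code maps to UNK
    assert rs.reports[2].drugs[0].role == "C"  # I -> C


def test_read_normalized_empty_drugs(tmp_path):
    paths = _write_normalized_fixture(tmp_path, "")
    rs = read_normalized(*paths)
    assert all(r.drugs == [] for r in rs)


def test_read_normalized_missing_column(tmp_path):
    paths = _write_normalized_fixture(tmp_path, "")
    (tmp_path / "reactions.tsv").write_text("report_id\tversion\n")
    with pytest.raises(FormatError, match="pt"):
        read_normalized(*paths)


def test_read_normalized_duplicate_drug_seq(tmp_path):
    paths = _write_normalized_fixture(
        tmp_path,
        "r1\t1\t1\tAvastin\tBEVACIZUMAB\tPS\n"
        "r1\t1\t1\tTemodar\tTEMOZOLOMIDE\tC\n")
    with pytest.raises(FormatError, match="drug_seq"):
        read_normalized(*paths)


# ---------------------------------------------------------------------------
# FAERS ASCII dialect
# ---------------------------------------------------------------------------

def test_faers_roundtrip(tmp_path):
    cfg = SyntheticConfig(n_reports=40, seed=11, duplicate_prob=0.2)
    original = generate(cfg)
    write_faers_ascii(original, tmp_path)
    back = read_faers_ascii(tmp_path / "DEMO.txt", tmp_path / "DRUG.txt",
                            tmp_path / "REAC.txt", tmp_path / "INDI.txt")
    assert len(back) == len(original)
    for orig, rt in zip(original, back):
        assert rt.report_id == orig.report_id
        assert rt.version == orig.version
        assert rt.sex == orig.sex
        assert rt.age_group == orig.age_group
        assert rt.weight_band == orig.weight_band
        assert rt.reporter == orig.reporter
        assert rt.serious == orig.serious
        assert rt.reactions == orig.reactions
        assert rt.indications == orig.indications
        assert [(d.generic_name, d.role) for d in rt.drugs] == \
            [(d.generic_name, d.role) for d in orig.drugs]


def test_faers_blank_sex_is_unk(tmp_path):
    (tmp_path / "DEMO.txt").write_text(
        "caseid$caseversion$sex$age$wt$occp_cod\nc1$1$$45$$MD\n")
    for name in ("DRUG", "REAC", "INDI"):
        cols = {"DRUG": "caseid$drugname$prod_ai$role_cod",
                "REAC": "caseid$pt", "INDI": "caseid$indi_pt"}[name]
        (tmp_path / f"{name}.txt").write_text(cols + "\n")
    rs = read_faers_ascii(tmp_path / "DEMO.txt", tmp_path / "DRUG.txt",
                          tmp_path / "REAC.txt", tmp_path / "INDI.txt")
    assert rs.reports[0].sex == "UNK"
    assert rs.reports[0].age_group == "18-64"
    assert rs.reports[0].reporter == "HCP"


def test_faers_undelimitable_line(tmp_path):
    (tmp_path / "DEMO.txt").write_text(
        "caseid$caseversion$sex$age$wt$occp_cod\nc1$1$M$45$70\n")
    for name, cols in [("DRUG", "caseid$drugname$prod_ai$role_cod"),
                       ("REAC", "caseid$pt"), ("INDI", "caseid$indi_pt")]:
        (tmp_path / f"{name}.txt").write_text(cols + "\n")
    with pytest.raises(FormatError, match="line 2"):
        read_faers_ascii(tmp_path / "DEMO.txt", tmp_path / "DRUG.txt",
                         tmp_path / "REAC.txt", tmp_path / "INDI.txt")
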
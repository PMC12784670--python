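import numpy as np
import pytest

from pvsignal.cohort import load_brand_map, load_cohort_definitions
from pvsignal.endpoints import load_endpoints
from pvsignal.icsr_store import DrugEntry, Report, ReportSet


def make_report(report_id, drugs=(), reactions=(), indications=("Glioblastoma",),
                version=1, database="FAERS", **kwargs):
    """Terse report constructor: drugs as (generic, role) pairs or bare
    generic names (any role)."""
    entries = []
    for d in drugs:
        if isinstance(d, tuple):
            generic, role = d
        else:
            generic, role = d, "C"
        entries.append(DrugEntry(generic.title(), generic.upper(), role))
    return Report(database=database, report_id=report_id, version=version,
                  drugs=entries, reactions=list(reactions),
                  indications=list(indications), **kwargs)


@pytest.fixture(scope="session")
def endpoints():
    return load_endpoints()


@pytest.fixture(scope="session")
def cohort_defs():
    return load_cohort_definitions()


@pytest.fixture(scope="session")
def brand_map():
    return load_brand_map()


@pytest.fixture
def micro_cohort():
    """Six glioma reports: bev+VTE, bev+other, tmz+VTE, tmz+other x2,
    lom+other."""
    return ReportSet("FAERS", [
        make_report("r1", ["BEVACIZUMAB"], ["DEEP VEIN THROMBOSIS"]),
        make_report("r2", ["BEVACIZUMAB"], ["HEADACHE"]),
        make_report("r3", ["TEMOZOLOMIDE"], ["PULMONARY EMBOLISM"]),
        make_report("r4", ["TEMOZOLOMIDE"], ["NAUSEA"]),
        make_report("r5", ["TEMOZOLOMIDE"], ["FATIGUE"]),
        make_report("r6", ["LOMUSTINE"], ["HEADACHE"]),
    ])


@pytest.fixture
def regimen_fixture():
    """Five bevacizumab reports: 2 mono (one with VTE), 2 bev+tmz (both
    VTE), 1 bev+lom without VTE."""
    return ReportSet("FAERS", [
        make_report("m1", ["BEVACIZUMAB"], ["DEEP VEIN THROMBOSIS"]),
        make_report("m2", ["BEVACIZUMAB"], ["HEADACHE"]),
        make_report("t1", ["BEVACIZUMAB", "TEMOZOLOMIDE"],
                    ["PULMONARY EMBOLISM"]),
        make_report("t2", ["BEVACIZUMAB", "TEMOZOLOMIDE"],
                    ["DEEP VEIN THROMBOSIS"]),
        make_report("l1", ["BEVACIZUMAB", "LOMUSTINE"], ["NAUSEA"]),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
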
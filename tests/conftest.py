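import textwrap

import pytest

from pafburden import (
    ExposureDistribution,
    RelativeRiskEntry,
    RiskFactorSpec,
)


def write(path, content):
    path.write_text(textwrap.dedent(content).lstrip(), encoding="utf-8")
    return path


@pytest.fixture
def smoking_spec():
    return RiskFactorSpec(
        factor_id="smoking", display_name="Tobacco smoking",
        evidence_mode="rr_based", framing="harmful",
        linked_cancer_types=frozenset({"lung"}),
        exposure_year=2008, latency_years=10)


@pytest.fixture
def smoking_dist():
    return ExposureDistribution.from_nonreference(
        "smoking", "male", [("current", 0.25), ("former", 0.25)])


@pytest.fixture
def smoking_rrs():
    return [
        RelativeRiskEntry("smoking", "lung", "male", "current", 8.0),
        RelativeRiskEntry("smoking", "lung", "male", "former", 2.0),
    ]


@pytest.fixture
def tiny_tables(tmp_path):
    """A one-factor, two-cancer input set small enough to verify by hand."""
    exposure = write(tmp_path / "exposure.csv", """
        factor_id,sex,level_id,proportion,exposure_year
        smoking,male,current,0.25,2008
        smoking,female,current,0.2,2008
    """)
    rr = write(tmp_path / "rr.csv", """
        factor_id,cancer_type_id,sex,level_id,rr,significant
        smoking,lung,male,current,9.0,true
        smoking,lung,female,current,9.0,true
        smoking,pancreas,male,current,1.7,false
        smoking,pancreas,female,current,1.7,false
    """)
    incidence = write(tmp_path / "incidence.csv", """
        cancer_type_id,subtype_of,sex,year,cases
        lung,,male,2018,2400
        lung,,female,2018,2300
        pancreas,,male,2018,500
        pancreas,,female,2018,480
    """)
    return {"exposure": str(exposure), "rr": str(rr),
            "incidence": str(incidence)}
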
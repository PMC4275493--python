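import pytest

from cvdrules.chart import synthetic_chart_set
from cvdrules.records import PatientRecord


@pytest.fixture(scope="session")
def chart():
    return synthetic_chart_set()


_BASE = dict(
    participant_id="P0001",
    assessment_date="2014-03-01",
    assessor_role="NPHW",
    village_code="V01",
    age=55,
    sex="female",
    current_smoker=False,
    hx_angina_or_mi=False,
    hx_stroke=False,
    hx_pvd=False,
    hx_diabetes=False,
    fam_hx_premature_chd_or_stroke=False,
    on_bp_lowering=False,
    on_lipid_lowering=False,
    on_antiplatelet=False,
    sbp=120,
    dbp=76,
    heart_rate=72,
    height=160,
    weight=60,
    waist=72,
    glucose_is_fasting=True,
    fasting_glucose=92,
    random_glucose=None,
    tc=180,
    ldl=100,
    hdl=55,
    tg=120,
)


def make_record(**overrides) -> PatientRecord:
    """A complete low-risk record; keyword overrides perturb single fields."""
    return PatientRecord(**{**_BASE, **overrides})


@pytest.fixture
def record():
    return make_record()
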
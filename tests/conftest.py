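import numpy as np
import pytest

from traumascores import (
    GeneratorConfig,
    InjuryRecord,
    PatientRecord,
    PhysiologyAtArrival,
    CohortTable,
    generate_cohort,
)


def make_patient(pid="p1", age=30, sex="male", mechanism="blunt", gcs=15,
                 sbp=120.0, rr=18.0, avpu="A", injuries=(), injuries_unknown=False,
                 death7=0, death30=0):
    return PatientRecord(
        patient_id=pid, age=age, sex=sex, mechanism=mechanism,
        physiology=PhysiologyAtArrival(gcs=gcs, sbp=sbp, rr=rr, avpu=avpu),
        injuries=[InjuryRecord(region=r, ais=a) for r, a in injuries],
        injuries_unknown=injuries_unknown, death7=death7, death30=death30,
    )


@pytest.fixture
def tiny_cohort():
    """Ten handmade patients spanning eligibility outcomes."""
    pts = [
        make_patient("a1", injuries=[("head_neck", 3)]),
        make_patient("a2", mechanism="penetrating", injuries=[("chest", 4)],
                     death7=1, death30=1),
        make_patient("a3", gcs=6, sbp=70, rr=30, avpu="P",
                     injuries=[("head_neck", 5), ("chest", 4)], death7=1,
                     death30=1),
        make_patient("a4", injuries=[]),
        make_patient("a5", mechanism="burn"),                      # mechanism exclusion
        make_patient("a6", mechanism="mixed"),                     # mechanism exclusion
        make_patient("a7", gcs=None),                              # missing GCS
        make_patient("a8", avpu=None),                             # missing AVPU
        make_patient("a9", injuries_unknown=True),                 # missing ISS
        make_patient("a10", age=70, mechanism="penetrating",
                     injuries=[("abdomen", 2), ("extremities", 3)], death30=1),
    ]
    return CohortTable(patients=pts, provenance="fixture")


@pytest.fixture(scope="session")
def synthetic_cohort_small():
    """Seeded default-condition cohort, small enough for fast tests."""
    return generate_cohort(GeneratorConfig(n_patients=4000, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
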
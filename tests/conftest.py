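"""Shared fixtures and factories for the test suite."""

import numpy as np
import pytest

from pedtriage.records import DiagnosisCode, PatientRecord


def make_record(patient_id="P0", year=2019, age_years=8, sex="F",
                mechanism="other_blunt", codes=("SYN0000",),
                ais_profile=None, **kwargs) -> PatientRecord:
    """A minimal valid patient record; override any field by keyword."""
    return PatientRecord(
        patient_id=patient_id, year=year, age_years=age_years, sex=sex,
        mechanism=mechanism, codes=list(codes),
        ais_profile=dict(ais_profile) if ais_profile else {"extremities": 1},
        **kwargs)


def make_code(code_id="SYN0000", p_survive=0.95, p_critcare=0.2,
              body_region="extremities", ais_severity=2) -> DiagnosisCode:
    return DiagnosisCode(code_id, p_survive, p_critcare, body_region,
                         ais_severity)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def code_factory():
    return make_code


def auc_brute(scores, labels) -> float:
    """Brute-force Mann-Whitney AUC: count concordant positive-negative
    pairs, crediting ties 1/2.  Independent oracle for roc_auc."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
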
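"""Shared fixtures: the two worked-example networks and small cohorts."""

from __future__ import annotations

import pytest

from ahinsim import AdmissionRecord, RecordSet, build_ahin, table1_fixture


def _adm(h, p, t, diagnoses, medicines):
    return AdmissionRecord(
        hospital_id=h, patient_id=p, admission_time=t,
        diagnoses=tuple(diagnoses), medicines=tuple(medicines),
    )


@pytest.fixture(scope="session")
def example_records() -> RecordSet:
    """Two patients, one disease, two drugs.

    Admissions chosen so the annotated network carries
    annotation {<P1,2>, <P2,3>} on the D-M1 edge and {<P1,3>} on D-M2 —
    the small network on which every hand-worked path score is known.
    """
    return RecordSet(
        [
            _adm("h1", "P1", 1, ["D"], ["M1", "M2"]),
            _adm("h2", "P1", 2, ["D"], ["M1", "M2"]),
            _adm("h3", "P1", 3, ["D"], ["M2"]),
            _adm("h4", "P2", 1, ["D"], ["M1"]),
            _adm("h5", "P2", 2, ["D"], ["M1"]),
            _adm("h6", "P2", 3, ["D"], ["M1"]),
        ]
    )


@pytest.fixture(scope="session")
def example_network(example_records):
    return build_ahin(example_records)


@pytest.fixture(scope="session")
def table1() -> RecordSet:
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_network(table1):
    return build_ahin(table1)


def random_recordset(rng, n_patients=4, n_diseases=3, n_drugs=3,
                     max_admissions=3) -> RecordSet:
    """Tiny random cohort for property tests; all nodes well under 12."""
    records = []
    serial = 0
    for i in range(n_patients):
        pid = f"p{i}"
        for t in range(1 + int(rng.integers(max_admissions))):
            n_diag = 1 + int(rng.integers(2))
            diag = list(rng.choice(n_diseases, size=n_diag, replace=False))
            meds = list(rng.choice(n_drugs, size=int(rng.integers(n_drugs + 1)),
                                   replace=False))
            serial += 1
            records.append(
                _adm(f"h{serial}", pid, t + 1,
                     [f"d{j}" for j in diag], [f"m{j}" for j in meds])
            )
    return RecordSet(records)
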
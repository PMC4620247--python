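from __future__ import annotations

from datetime import date

import pytest

from pmsst import default_registry, default_terminology
from pmsst.model import ConditionEntry, ObservationEntry, PatientRecord
from pmsst.synth import GeneratorConfig, generate


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def terminology():
    return default_terminology()


@pytest.fixture(scope="session")
def population():
    """Mid-sized seeded population shared across tests."""
    return generate(GeneratorConfig(n_patients=200, seed=7))


def make_patient(
    patient_id="P1",
    sex="F",
    birth=date(1950, 3, 2),
    registration=date(2000, 1, 1),
    death=None,
    transfer=None,
    conditions=(),
    observations=(),
) -> PatientRecord:
    """Hand-built canonical patient for targeted fixtures.

    ``conditions`` are (code, iso-date) pairs (warehouse ICD-9-CM codes);
    ``observations`` are (code, value, iso-date) triples."""
    conds = [
        ConditionEntry(
            entry_id=f"{patient_id}-c{i + 1}",
            code=code,
            code_system="ICD9CM",
            start_date=date.fromisoformat(d),
        )
        for i, (code, d) in enumerate(conditions)
    ]
    obs = [
        ObservationEntry(
            entry_id=f"{patient_id}-o{i + 1}",
            code=code,
            code_system="LOCAL-OBS",
            value=float(v),
            unit="u",
            obs_date=date.fromisoformat(d),
        )
        for i, (code, v, d) in enumerate(observations)
    ]
    return PatientRecord(
        patient_id=patient_id,
        sex=sex,
        birth_date=birth,
        registration_date=registration,
        death_date=death,
        transfer_out_date=transfer,
        conditions=conds,
        observations=obs,
    )
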
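import datetime as dt

import pytest

from cqmbench.ehr_tables import make_cohort
from cqmbench.measure_engine import MeasurementPeriod
from cqmbench.terminology import load_valuesets

PERIOD_2016 = MeasurementPeriod(dt.date(2016, 1, 1), dt.date(2016, 12, 31))
SCREENING_PERIOD = MeasurementPeriod(dt.date(2015, 1, 1), dt.date(2016, 12, 31))


@pytest.fixture(scope="session")
def valuesets():
    return load_valuesets()


@pytest.fixture
def cohort_builder():
    """Build a validated cohort from row dicts with compact defaults."""

    def build(patients=(), encounters=(), conditions=(), observations=(), procedures=()):
        def fill_patients(rows):
            out = []
            for i, row in enumerate(rows):
                base = dict(patient_id=f"P{i}", birth_date=dt.date(1950, 1, 1),
                            death_date=None, gender="female", race="white",
                            height_cm=None, weight_kg=None)
                base.update(row)
                out.append(base)
            return out

        def fill_encounters(rows):
            out = []
            for i, row in enumerate(rows):
                base = dict(encounter_id=f"E{i}", patient_id="P0",
                            start_date=dt.date(2016, 6, 1), stop_date=None,
                            encounter_code="AMB", principal_diagnosis=None)
                base.update(row)
                out.append(base)
            return out

        def fill(rows, **defaults):
            out = []
            for row in rows:
                base = dict(defaults)
                base.update(row)
                out.append(base)
            return out

        return make_cohort(
            patients=fill_patients(patients),
            encounters=fill_encounters(encounters),
            conditions=fill(conditions, patient_id="P0", encounter_id=None,
                            code="X", onset_date=dt.date(2016, 1, 1), end_date=None),
            observations=fill(observations, patient_id="P0", obs_date=dt.date(2016, 6, 1),
                              code="8480-6", value=120.0, units="mm[Hg]"),
            procedures=fill(procedures, patient_id="P0", proc_date=dt.date(2016, 6, 1), code="X"),
        )

    return build
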